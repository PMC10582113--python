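"""Reading/writing isotope tables and posterior summaries; packaged fixtures.

Two fixtures ship with the package:

``iznik_community``
    Group summaries (n, mean, SD of δ¹⁵N and δ¹³C) for the 19 İznik Lake
    groups: 12 fish species, the marsh frog, macrozoobenthos, phytoplankton,
    macrophytes, algae, detritus and zooplankton.  Baseline roles are
    pre-assigned: detritus as baseline 1, phyto- + zooplankton as baseline 2.

``perch_sites``
    Site-mean δ¹⁵N/δ¹³C signatures of Eurasian perch from five western
    Anatolian water bodies (two natural lakes, three reservoirs) used as
    donor populations in introduction forecasts.  SDs are not reported for
    these rows; downstream consumers must supply an assumed spread.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    CommunityDataset,
    GroupSummary,
    IsotopeMeasurement,
    summarize_measurements,
)

FIXTURES = ("iznik_community", "perch_sites")

DEFAULT_SCHEMA: dict[str, str] = {
    "taxon": "taxon",
    "delta13C": "delta13C",
    "delta15N": "delta15N",
    "group": "group",
    "status": "status",
    "total_length": "TL",
    "weight": "W",
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class IsotopeParseError(ValueError):
    """A cell that must be numeric could not be parsed."""


def read_isotope_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> CommunityDataset:
    """Read a per-individual isotope CSV into a :class:`CommunityDataset`.

    Parameters
    ----------
    path
        CSV file with a header row.  Required columns (after schema
        mapping): taxon, delta13C, delta15N.  Optional: group, status,
        TL (mm), W (g).
    schema
        Mapping from canonical field names (``taxon``, ``delta13C``,
        ``delta15N``, ``group``, ``status``, ``total_length``, ``weight``)
        to the column names used in the file.  Defaults to the canonical
        names themselves with ``TL``/``W`` for length and weight.

    Returns
    -------
    CommunityDataset
        Row order preserved in ``measurements``; ``summaries`` holds per
        taxon-group n, mean and sample (n−1) SD.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    frame = pd.read_csv(path)
    for req in ("taxon", "delta13C", "delta15N"):
        if colmap[req] not in frame.columns:
            raise SchemaError(f"required column {colmap[req]!r} is missing")

    measurements = []
    for i, row in frame.iterrows():
        vals = {}
        for fieldname in ("delta13C", "delta15N"):
            raw = row[colmap[fieldname]]
            try:
                vals[fieldname] = float(raw)
                if not np.isfinite(vals[fieldname]):
                    raise ValueError
            except (TypeError, ValueError):
                raise IsotopeParseError(
                    f"row {i}: non-numeric {fieldname} value {raw!r}"
                ) from None

        def _opt(fieldname: str, cast=float):
            col = colmap[fieldname]
            if col in frame.columns and pd.notna(row[col]):
                return cast(row[col])
            return None

        measurements.append(
            IsotopeMeasurement(
                taxon=str(row[colmap["taxon"]]),
                delta13C=vals["delta13C"],
                delta15N=vals["delta15N"],
                group=str(_opt("group", str) or ""),
                status=_opt("status", str),
                total_length=_opt("total_length"),
                weight=_opt("weight"),
            )
        )
    return CommunityDataset(
        measurements=measurements,
        summaries=summarize_measurements(measurements),
    )


def _fixture_frame(name: str) -> pd.DataFrame:
    with resources.files("isocast.data").joinpath(f"{name}.csv").open() as fh:
        return pd.read_csv(fh)


def load_fixture(name: str) -> CommunityDataset:
    """Load a packaged community fixture (``iznik_community`` or
    ``perch_sites``) as group summaries."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    frame = _fixture_frame(name)

    def _opt(row, col):
        return float(row[col]) if col in row.index and pd.notna(row[col]) else None

    summaries = [
        GroupSummary(
            taxon=row["taxon"],
            kind=row["kind"],
            status=row["status"] if pd.notna(row["status"]) else None,
            n=int(row["n"]) if "n" in row.index else 1,
            mean15N=float(row["mean15N"]),
            mean13C=float(row["mean13C"]),
            sd15N=_opt(row, "sd15N"),
            sd13C=_opt(row, "sd13C"),
            mean_TL=_opt(row, "mean_TL"),
            mean_W=_opt(row, "mean_W"),
        )
        for _, row in frame.iterrows()
    ]
    baselines = {}
    if name == "iznik_community":
        baselines = {
            "baseline1": ["Detritus"],
            "baseline2": ["Phytoplankton", "Zooplankton"],
        }
    return CommunityDataset(summaries=summaries, baseline_labels=baselines)


def write_posterior_summary(result, path: str | Path) -> Path:
    """Write a posterior's per-quantity summary table to CSV.

    ``result`` must expose ``named_draws() -> dict[str, 1-D array]`` (all
    posterior objects in this package do) or be such a mapping itself.
    One row per quantity: mean, SD, 2.5/50/97.5 percentiles and the number
    of draws; values round-trip through the file to 6 decimals.
    """
    draws = result.named_draws() if hasattr(result, "named_draws") else dict(result)
    if not draws:
        raise ValueError("posterior has no quantities to summarize")
    rows = []
    for name, vec in draws.items():
        vec = np.asarray(vec, float)
        if vec.size == 0:
            raise ValueError(f"quantity {name!r} has no draws")
        q = np.percentile(vec, [2.5, 50.0, 97.5])
        rows.append(
            {
                "quantity": name,
                "mean": vec.mean(),
                "sd": vec.std(ddof=1) if vec.size > 1 else 0.0,
                "q2.5": q[0],
                "median": q[1],
                "q97.5": q[2],
                "n_draws": vec.size,
            }
        )
    path = Path(path)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format="%.6f")
    return path


def read_posterior_summary(path: str | Path) -> pd.DataFrame:
    """Read back a summary written by :func:`write_posterior_summary`."""
    return pd.read_csv(path)
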