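"""Core containers for δ¹³C/δ¹⁵N community data.

Isotope values are per-mil (‰) deviations from the international standards
(VPDB for carbon, atmospheric N₂ for nitrogen). A *measurement* is one
organism's bivariate isotope point; a *group summary* is the per-taxon
n/mean/SD table form in which community surveys are usually reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STATUSES = ("native", "invasive", "translocated", "hypothetical")

#: soft plausibility bounds for per-mil isotope values in freshwater food webs
D13C_RANGE = (-40.0, 0.0)
D15N_RANGE = (-10.0, 30.0)


class IsotopeRangeWarning(UserWarning):
    """A δ value is finite but outside the usual ecological range."""


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One organism's stable-isotope point with taxon/group metadata."""

    taxon: str
    delta13C: float
    delta15N: float
    group: str = ""
    status: str | None = None
    total_length: float | None = None  # mm
    weight: float | None = None  # g

    def __post_init__(self) -> None:
        for name in ("delta13C", "delta15N"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.status is not None and self.status not in STATUSES:
            raise ValueError(
                f"status must be one of {STATUSES}, got {self.status!r}"
            )
        if not D13C_RANGE[0] <= self.delta13C <= D13C_RANGE[1]:
            warnings.warn(
                f"delta13C={self.delta13C} ‰ outside {D13C_RANGE}",
                IsotopeRangeWarning,
                stacklevel=3,
            )
        if not D15N_RANGE[0] <= self.delta15N <= D15N_RANGE[1]:
            warnings.warn(
                f"delta15N={self.delta15N} ‰ outside {D15N_RANGE}",
                IsotopeRangeWarning,
                stacklevel=3,
            )
        for name in ("total_length", "weight"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 when present, got {v}")


@dataclass(frozen=True)
class GroupSummary:
    """Per-taxon n, means and SDs of both isotopes (one survey-table row).

    ``sd15N``/``sd13C`` may be ``None`` when ``n == 1`` or when the source
    table does not report spread.
    """

    taxon: str
    n: int
    mean15N: float
    mean13C: float
    sd15N: float | None = None
    sd13C: float | None = None
    status: str | None = None
    kind: str | None = None  # fish / amphibian / invertebrate / plankton / ...
    mean_TL: float | None = None  # mm
    mean_W: float | None = None  # g

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for name in ("sd15N", "sd13C"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def is_fish(self) -> bool:
        return self.kind == "fish"


@dataclass
class CommunityDataset:
    """A community: raw measurements and/or group summaries plus baselines.

    ``baseline_labels`` maps a baseline role (``"baseline1"``,
    ``"baseline2"``) to the taxon label(s) filling that role.
    """

    measurements: list[IsotopeMeasurement] = field(default_factory=list)
    summaries: list[GroupSummary] = field(default_factory=list)
    baseline_labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        taxa = [s.taxon for s in self.summaries]
        dupes = {t for t in taxa if taxa.count(t) > 1}
        if dupes:
            raise ValueError(f"duplicate summary taxa: {sorted(dupes)}")

    # -- convenience accessors -------------------------------------------
    def summary(self, taxon: str) -> GroupSummary:
        for s in self.summaries:
            if s.taxon == taxon:
                return s
        raise KeyError(f"no summary for taxon {taxon!r}")

    def measurements_for(self, taxon: str) -> list[IsotopeMeasurement]:
        return [m for m in self.measurements if m.taxon == taxon]

    @property
    def taxa(self) -> list[str]:
        return [s.taxon for s in self.summaries]

    def measurements_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": [m.taxon for m in self.measurements],
                "group": [m.group for m in self.measurements],
                "status": [m.status for m in self.measurements],
                "delta13C": [m.delta13C for m in self.measurements],
                "delta15N": [m.delta15N for m in self.measurements],
            }
        )

    def summaries_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": [s.taxon for s in self.summaries],
                "kind": [s.kind for s in self.summaries],
                "status": [s.status for s in self.summaries],
                "n": [s.n for s in self.summaries],
                "mean15N": [s.mean15N for s in self.summaries],
                "sd15N": [s.sd15N for s in self.summaries],
                "mean13C": [s.mean13C for s in self.summaries],
                "sd13C": [s.sd13C for s in self.summaries],
                "mean_TL": [s.mean_TL for s in self.summaries],
                "mean_W": [s.mean_W for s in self.summaries],
            }
        )


def as_xy(samples: Sequence[IsotopeMeasurement] | np.ndarray | pd.DataFrame) -> np.ndarray:
    """Coerce measurements to an (n, 2) array of (δ¹³C, δ¹⁵N) points."""
    if isinstance(samples, pd.DataFrame):
        return samples[["delta13C", "delta15N"]].to_numpy(float)
    if isinstance(samples, np.ndarray):
        arr = np.asarray(samples, float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("array input must have shape (n, 2)")
        return arr
    return np.array([[m.delta13C, m.delta15N] for m in samples], float)


def summarize_measurements(
    measurements: Iterable[IsotopeMeasurement],
) -> list[GroupSummary]:
    """Per (taxon, group) n, mean and sample (n−1) SD of both isotopes."""
    frame = pd.DataFrame(
        {
            "taxon": [m.taxon for m in measurements],
            "group": [m.group for m in measurements],
            "delta13C": [m.delta13C for m in measurements],
            "delta15N": [m.delta15N for m in measurements],
            "status": [m.status for m in measurements],
        }
    )
    out: list[GroupSummary] = []
    for (taxon, group), sub in frame.groupby(["taxon", "group"], sort=False):
        n = len(sub)
        label = taxon if group == "" else f"{taxon}|{group}"
        out.append(
            GroupSummary(
                taxon=label,
                n=n,
                mean15N=float(sub["delta15N"].mean()),
                mean13C=float(sub["delta13C"].mean()),
                sd15N=float(sub["delta15N"].std(ddof=1)) if n > 1 else None,
                sd13C=float(sub["delta13C"].std(ddof=1)) if n > 1 else None,
                status=sub["status"].iloc[0],
            )
        )
    return out
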