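"""End-to-end forecast of a hypothetical predator introduction.

Donor-population isotope signatures are *superimposed* into the recipient
community biplot — appended on the raw ‰ scales, assuming the introduced
population's niche would settle somewhere within the range spanned by the
donor populations.  The projection then reports:

* predation: Bayesian mixing-model diet posteriors of each donor group
  over the recipient's candidate prey fish;
* competition: two-baseline trophic positions of every fish group and each
  donor, plus ellipse (SEAb) and directional niche overlap between each
  donor and the resident apex predator.

Donor data are usually available only as site means; pseudo-individuals
are generated around each site mean with a configurable assumed SD
(default 1 ‰ per isotope) and a sensitivity scan over that assumption is
included in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CommunityDataset,
    GroupSummary,
    IsotopeMeasurement,
    summarize_measurements,
)
from .ellipse import bayesian_sea
from .mixing import DietPosterior, SourceSet, fit_mixing_model, summarize_diet
from .overlap import bayesian_overlap, directional_overlap
from .synthetic import SyntheticGroupSpec, generate_group
from .trophic import (
    BaselineSpec,
    MCMCConfig,
    TDFSpec,
    TrophicPositionPosterior,
    baseline_from_community,
    fit_two_baseline_tp,
)

STANDARD_ELLIPSE_COVERAGE = 1 - np.exp(-0.5)  # ≈ 0.3935


@dataclass(frozen=True)
class DonorSpec:
    """A donor population: raw measurements, or site means plus an
    assumed per-isotope SD from which pseudo-individuals are generated."""

    label: str
    measurements: tuple[IsotopeMeasurement, ...] = ()
    site_means: tuple[tuple[str, float, float], ...] = ()  # (site, δ¹³C, δ¹⁵N)
    assumed_sd: float = 1.0  # ‰ per isotope, used only with site_means
    n_per_site: int = 10
    #: standardize pseudo-individuals so each site's sample mean/SD equal
    #: the printed mean and the assumed SD exactly
    match_moments: bool = True

    def __post_init__(self) -> None:
        if not self.measurements and not self.site_means:
            raise ValueError("donor needs measurements or site means")
        if self.assumed_sd < 0 or self.n_per_site < 1:
            raise ValueError("invalid donor generation settings")

    def points(self, seed: int = 0) -> list[IsotopeMeasurement]:
        """Donor individuals: raw if given, else deterministic
        pseudo-individuals around each site mean."""
        if self.measurements:
            return list(self.measurements)
        out: list[IsotopeMeasurement] = []
        for site, m13, m15 in self.site_means:
            out.extend(
                replace(m, taxon=self.label, group=site, status="hypothetical")
                for m in generate_group(
                    SyntheticGroupSpec(
                        taxon=f"{self.label}:{site}",
                        n=self.n_per_site,
                        mean13C=m13,
                        mean15N=m15,
                        sd13C=self.assumed_sd,
                        sd15N=self.assumed_sd,
                    ),
                    seed,
                    match_moments=self.match_moments,
                )
            )
        return out


def donors_from_perch_sites(
    perch: CommunityDataset,
    assumed_sd: float = 1.0,
    n_per_site: int = 10,
) -> list[DonorSpec]:
    """Split a perch-site fixture into lake-origin and reservoir-origin
    donor groups (native sites are lakes, translocated sites reservoirs)."""
    def _sites(status: str) -> tuple[tuple[str, float, float], ...]:
        return tuple(
            (s.taxon, s.mean13C, s.mean15N)
            for s in perch.summaries
            if s.status == status
        )

    return [
        DonorSpec(
            label="P. fluviatilis (lakes)",
            site_means=_sites("native"),
            assumed_sd=assumed_sd,
            n_per_site=n_per_site,
        ),
        DonorSpec(
            label="P. fluviatilis (reservoirs)",
            site_means=_sites("translocated"),
            assumed_sd=assumed_sd,
            n_per_site=n_per_site,
        ),
    ]


def superimpose(
    donors: Sequence[DonorSpec],
    recipient: CommunityDataset,
    standardize: bool = False,
    donor_baselines: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> CommunityDataset:
    """Append donor signatures to the recipient community.

    With ``standardize`` off (the default, the "raw superimposition"
    approach) donor points are appended unchanged, flagged
    ``hypothetical``; recipient rows are untouched.  With ``standardize``
    on, each donor's values are shifted by the difference between the
    recipient's and that donor's baseline means (``donor_baselines`` maps
    donor label to its (δ¹³C, δ¹⁵N) baseline mean and is then required).
    """
    if standardize and not donor_baselines:
        raise ValueError("standardize=True requires donor_baselines")
    combined_measurements = list(recipient.measurements)
    combined_summaries = list(recipient.summaries)
    baselines = dict(recipient.baseline_labels)

    if standardize:
        all_roles = [
            t for role in ("baseline1", "baseline2")
            for t in recipient.baseline_labels.get(role, [])
        ]
        rows = [recipient.summary(t) for t in all_roles]
        rec_base = (
            float(np.mean([r.mean13C for r in rows])),
            float(np.mean([r.mean15N for r in rows])),
        )

    for donor in donors:
        pts = donor.points(seed)
        if standardize:
            d13, d15 = donor_baselines[donor.label]
            shift13, shift15 = rec_base[0] - d13, rec_base[1] - d15
            pts = [
                replace(
                    m, delta13C=m.delta13C + shift13, delta15N=m.delta15N + shift15
                )
                for m in pts
            ]
        pts = [
            replace(m, taxon=donor.label, status="hypothetical") for m in pts
        ]
        combined_measurements.extend(pts)
        xy = np.array([[m.delta13C, m.delta15N] for m in pts])
        combined_summaries.append(
            GroupSummary(
                taxon=donor.label,
                kind="fish",
                status="hypothetical",
                n=len(pts),
                mean15N=float(xy[:, 1].mean()),
                mean13C=float(xy[:, 0].mean()),
                sd15N=float(xy[:, 1].std(ddof=1)) if len(pts) > 1 else None,
                sd13C=float(xy[:, 0].std(ddof=1)) if len(pts) > 1 else None,
            )
        )
    return CommunityDataset(
        measurements=combined_measurements,
        summaries=combined_summaries,
        baseline_labels=baselines,
    )


def select_prey(
    community: CommunityDataset,
    apex_label: str,
    extra_exclusions: Sequence[str] = (),
    size_threshold: float | None = None,
    default_sd: float = 0.0,
) -> SourceSet:
    """Candidate prey sources: all resident fish except the apex predator,
    explicit exclusions, and (optionally) taxa whose mean total length
    exceeds ``size_threshold`` mm.  Non-fish groups and hypothetical
    (superimposed) groups are never prey."""
    labels = {s.taxon for s in community.summaries}
    if apex_label not in labels:
        raise ValueError(f"apex taxon {apex_label!r} not in community")
    missing = set(extra_exclusions) - labels
    if missing:
        raise ValueError(f"excluded taxa not in community: {sorted(missing)}")
    prey = [
        s
        for s in community.summaries
        if s.is_fish
        and s.status != "hypothetical"
        and s.taxon != apex_label
        and s.taxon not in set(extra_exclusions)
        and not (
            size_threshold is not None
            and s.mean_TL is not None
            and s.mean_TL > size_threshold
        )
    ]
    if not prey:
        raise ValueError("prey selection produced an empty source set")
    return SourceSet.from_summaries(prey, default_sd=default_sd)


@dataclass(frozen=True)
class ProjectionScenario:
    """Everything needed to run an introduction forecast."""

    recipient: CommunityDataset
    donors: tuple[DonorSpec, ...]
    apex_label: str
    prey_exclusions: tuple[str, ...] = ()
    size_threshold: float | None = None
    lam: float = 2.0
    tdf: TDFSpec = TDFSpec()

    def __post_init__(self) -> None:
        if not self.donors:
            raise ValueError("at least one donor population required")
        labels = {s.taxon for s in self.recipient.summaries}
        if self.apex_label not in labels:
            raise ValueError(f"apex taxon {self.apex_label!r} not in recipient")
        missing = set(self.prey_exclusions) - labels
        if missing:
            raise ValueError(f"excluded taxa not in recipient: {sorted(missing)}")


@dataclass(frozen=True)
class ProjectionConfig:
    """Tunables for :func:`run_projection`."""

    mcmc: MCMCConfig = MCMCConfig()
    per_site_mixing: bool = False
    niche_levels: tuple[float, ...] = (0.95, STANDARD_ELLIPSE_COVERAGE)
    seab_draws: int = 2_000
    overlap_nmc: int = 10_000
    sd_sensitivity: tuple[float, ...] = ()  # e.g. (0.5, 1.0, 2.0)
    group_default_sd: float = 1.0  # ‰ for simulating groups lacking an SD


@dataclass
class ProjectionReport:
    """All projection outputs plus provenance for exact reproduction."""

    tp_by_group: dict[str, TrophicPositionPosterior]
    diet_by_donor: dict[str, DietPosterior]
    diet_by_donor_site: dict[str, DietPosterior]
    overlap_directional: dict[float, pd.DataFrame]
    overlap_seab: dict[str, pd.DataFrame]
    sd_sensitivity: pd.DataFrame
    provenance: dict

    def tp_median_table(self) -> pd.Series:
        return pd.Series(
            {k: v.tp_median for k, v in self.tp_by_group.items()}
        ).sort_values(ascending=False)

    def top_prey(self, donor: str, k: int = 2) -> list[str]:
        return list(summarize_diet(self.diet_by_donor[donor])["source"][:k])

    def write(self, outdir: str | Path) -> Path:
        """Serialize the report (CSVs + provenance JSON) to a directory."""
        from .io import write_posterior_summary

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tp_median_table().rename("tp_median").to_csv(
            outdir / "tp_medians.csv"
        )
        for name, post in self.tp_by_group.items():
            write_posterior_summary(post, outdir / f"tp_{_slug(name)}.csv")
        for name, post in self.diet_by_donor.items():
            summarize_diet(post).to_csv(
                outdir / f"diet_{_slug(name)}.csv", index=False
            )
        for level, mat in self.overlap_directional.items():
            mat.to_csv(outdir / f"overlap_directional_{level:.4f}.csv")
        for pair, frame in self.overlap_seab.items():
            frame.describe().to_csv(outdir / f"overlap_seab_{_slug(pair)}.csv")
        if len(self.sd_sensitivity):
            self.sd_sensitivity.to_csv(
                outdir / "sd_sensitivity.csv", index=False
            )
        (outdir / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str)
        )
        return outdir


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name).strip("_")


def _group_points(
    community: CommunityDataset,
    taxon: str,
    seed: int,
    default_sd: float,
) -> list[IsotopeMeasurement]:
    """Measurements for a group: raw if present, else synthetic
    pseudo-individuals matching the group's summary moments."""
    raw = community.measurements_for(taxon)
    if raw:
        return raw
    s = community.summary(taxon)
    return generate_group(
        SyntheticGroupSpec(
            taxon=taxon,
            n=max(s.n, 2),
            mean13C=s.mean13C,
            mean15N=s.mean15N,
            sd13C=s.sd13C if s.sd13C is not None else default_sd,
            sd15N=s.sd15N if s.sd15N is not None else default_sd,
        ),
        seed,
        match_moments=True,
    )


def run_projection(
    scenario: ProjectionScenario,
    config: ProjectionConfig | None = None,
    seed: int = 0,
) -> ProjectionReport:
    """Run the full forecast: TP for every fish group and donor, diet
    posteriors per donor, and SEAb plus directional overlap between each
    donor and the resident apex predator."""
    config = config or ProjectionConfig()
    rec = scenario.recipient
    combined = superimpose(scenario.donors, rec, seed=seed)
    baseline_spec = baseline_from_community(rec, lam=scenario.lam)

    fish = [s.taxon for s in rec.summaries if s.is_fish]
    donor_labels = [d.label for d in scenario.donors]

    # --- trophic positions ------------------------------------------------
    tp_by_group: dict[str, TrophicPositionPosterior] = {}
    for i, taxon in enumerate(fish + donor_labels):
        pts = _group_points(combined, taxon, seed, config.group_default_sd)
        tp_by_group[taxon] = fit_two_baseline_tp(
            pts,
            baseline_spec,
            tdf=scenario.tdf,
            mcmc=config.mcmc,
            seed=seed + 101 + i,
        )

    # --- diet mixing ------------------------------------------------------
    sources = select_prey(
        rec,
        scenario.apex_label,
        extra_exclusions=scenario.prey_exclusions,
        size_threshold=scenario.size_threshold,
    )
    diet_by_donor: dict[str, DietPosterior] = {}
    diet_by_donor_site: dict[str, DietPosterior] = {}
    for i, donor in enumerate(scenario.donors):
        pts = donor.points(seed)
        diet_by_donor[donor.label] = fit_mixing_model(
            pts, sources, tdf=scenario.tdf, mcmc=config.mcmc, seed=seed + 301 + i
        )
        if config.per_site_mixing and donor.site_means:
            for j, (site, *_rest) in enumerate(donor.site_means):
                site_pts = [m for m in pts if m.group == site]
                diet_by_donor_site[f"{donor.label}:{site}"] = fit_mixing_model(
                    site_pts,
                    sources,
                    tdf=scenario.tdf,
                    mcmc=config.mcmc,
                    seed=seed + 501 + 10 * i + j,
                )

    # --- niche overlap vs the apex predator -------------------------------
    apex_pts = _group_points(combined, scenario.apex_label, seed, config.group_default_sd)
    overlap_groups = {scenario.apex_label: apex_pts}
    for donor in scenario.donors:
        overlap_groups[donor.label] = donor.points(seed)

    overlap_directional: dict[float, pd.DataFrame] = {}
    for level in config.niche_levels:
        labels = list(overlap_groups)
        mat = pd.DataFrame(np.nan, index=labels, columns=labels)
        for i, la in enumerate(labels):
            for j, lb in enumerate(labels):
                if la == lb:
                    continue
                p, _ = directional_overlap(
                    overlap_groups[la],
                    overlap_groups[lb],
                    alpha=level,
                    nmc=config.overlap_nmc,
                    seed=seed + 701 + 100 * i + j,
                )
                mat.loc[la, lb] = p
        overlap_directional[level] = mat

    overlap_seab: dict[str, pd.DataFrame] = {}
    apex_seab = bayesian_sea(apex_pts, ndraws=config.seab_draws, seed=seed + 901)
    for i, donor in enumerate(scenario.donors):
        donor_seab = bayesian_sea(
            overlap_groups[donor.label], ndraws=config.seab_draws, seed=seed + 902 + i
        )
        overlap_seab[f"{donor.label} vs {scenario.apex_label}"] = bayesian_overlap(
            donor_seab, apex_seab, coverage=0.95, seed=seed + 903 + i
        )

    # --- sensitivity of donor TP/diet to the assumed pseudo-individual SD -
    sens_rows = []
    for sd in config.sd_sensitivity:
        for i, donor in enumerate(scenario.donors):
            if not donor.site_means:
                continue
            alt = replace(donor, assumed_sd=sd)
            pts = alt.points(seed)
            tp = fit_two_baseline_tp(
                pts, baseline_spec, tdf=scenario.tdf, mcmc=config.mcmc,
                seed=seed + 1101 + i,
            )
            diet = fit_mixing_model(
                pts, sources, tdf=scenario.tdf, mcmc=config.mcmc,
                seed=seed + 1201 + i,
            )
            top = summarize_diet(diet)["source"].iloc[0]
            sens_rows.append(
                {
                    "donor": donor.label,
                    "assumed_sd": sd,
                    "tp_median": tp.tp_median,
                    "top_prey": top,
                }
            )

    from . import __version__

    provenance = {
        "software": f"isocast {__version__}",
        "seed": seed,
        "apex": scenario.apex_label,
        "donors": donor_labels,
        "donor_assumed_sd": [d.assumed_sd for d in scenario.donors],
        "lambda": scenario.lam,
        "tdf": vars(scenario.tdf) if hasattr(scenario.tdf, "__dict__") else {
            "meanDeltaN": scenario.tdf.meanDeltaN,
            "sdDeltaN": scenario.tdf.sdDeltaN,
            "meanDeltaC": scenario.tdf.meanDeltaC,
            "sdDeltaC": scenario.tdf.sdDeltaC,
        },
        "mcmc": {
            "n_chains": config.mcmc.n_chains,
            "n_iter": config.mcmc.n_iter,
            "n_burn": config.mcmc.n_burn,
        },
        "niche_levels": list(config.niche_levels),
        "prey_sources": list(sources.labels),
    }
    return ProjectionReport(
        tp_by_group=tp_by_group,
        diet_by_donor=diet_by_donor,
        diet_by_donor_site=diet_by_donor_site,
        overlap_directional=overlap_directional,
        overlap_seab=overlap_seab,
        sd_sensitivity=pd.DataFrame(sens_rows),
        provenance=provenance,
    )
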