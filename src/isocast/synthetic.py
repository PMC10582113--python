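"""Synthetic isotope communities, baselines and consumers.

Groups are bivariate-normal clusters in (δ¹³C, δ¹⁵N) space with
configurable means, SDs and correlation, emulating the per-taxon
mean/SD structure of community survey tables.  Consumers are generated
from known diet proportions under the same likelihood the mixing model
fits, so inverse-fit (parameter recovery) tests are exact:

    y_j ~ Normal( Σ_k p_k·μ_kj + Δ_j ,
                  sqrt( Σ_k p_k²·(σ_kj² + τ_j²) + σ_resid,j² ) )

per isotope j, where Δ_j/τ_j are the TDF mean/SD.

Seeding: one integer seed plus the group label defines an independent,
reproducible stream per group, so adding or resizing one group never
perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .datatypes import CommunityDataset, IsotopeMeasurement, summarize_measurements
from .trophic import TDFSpec


def _group_rng(seed: int, label: str) -> np.random.Generator:
    """Named, splittable stream: seed plus a CRC of the group label."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(label.encode()),))
    )


@dataclass(frozen=True)
class SyntheticGroupSpec:
    """Bivariate-normal cluster specification for one taxon."""

    taxon: str
    n: int
    mean13C: float
    mean15N: float
    sd13C: float = 1.0
    sd15N: float = 1.0
    rho: float = 0.0  # isotope correlation; 0 by default (rarely reported)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd13C < 0 or self.sd15N < 0:
            raise ValueError("SDs must be >= 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")

    @property
    def cov(self) -> np.ndarray:
        off = self.rho * self.sd13C * self.sd15N
        return np.array(
            [[self.sd13C**2, off], [off, self.sd15N**2]], float
        )


@dataclass(frozen=True)
class ConsumerGenSpec:
    """Forward-model specification for a consumer with known diet."""

    sources: tuple[SyntheticGroupSpec, ...]
    proportions: tuple[float, ...]
    tdf: TDFSpec = TDFSpec()
    resid_sd13C: float = 0.0
    resid_sd15N: float = 0.0
    n: int = 1
    taxon: str = "consumer"

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, float)
        if len(p) != len(self.sources):
            raise ValueError("one proportion per source required")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be >= 0 and sum to 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def generate_group(
    spec: SyntheticGroupSpec, seed: int, match_moments: bool = False
) -> list[IsotopeMeasurement]:
    """Draw ``spec.n`` bivariate-normal individuals for one taxon.

    With ``match_moments`` the draws are affinely standardized so their
    *sample* mean and covariance equal the spec moments exactly.  Survey
    tables print sample statistics of real data, and a normal likelihood
    depends on the data only through those statistics — so moment-matched
    pseudo-individuals reproduce the published data's sufficient
    statistics rather than a random perturbation of them.  Requires
    n ≥ 3 for the full bivariate standardization; n = 2 standardizes each
    axis separately, n = 1 returns the mean point.
    """
    rng = _group_rng(seed, spec.taxon)
    mean = np.array([spec.mean13C, spec.mean15N])
    if not match_moments:
        pts = rng.multivariate_normal(mean, spec.cov, size=spec.n)
    elif spec.n == 1:
        pts = mean[None, :]
    else:
        z = rng.standard_normal((spec.n, 2))
        z -= z.mean(axis=0)
        if spec.n == 2:
            z /= z.std(axis=0, ddof=1)
        else:
            white = np.linalg.cholesky(np.cov(z, rowvar=False, ddof=1))
            z = z @ np.linalg.inv(white).T
        sd = np.array([spec.sd13C, spec.sd15N])
        scale = np.linalg.cholesky(spec.cov).T if min(sd) > 0 else np.diag(sd)
        pts = mean + (z @ scale if min(sd) > 0 else z * sd)
    return [
        IsotopeMeasurement(taxon=spec.taxon, delta13C=float(c), delta15N=float(n))
        for c, n in pts
    ]


def consumer_moments(spec: ConsumerGenSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean and SD of the consumer distribution, per isotope (C, N)."""
    p = np.asarray(spec.proportions, float)
    mu = np.array(
        [
            p @ [s.mean13C for s in spec.sources] + spec.tdf.meanDeltaC,
            p @ [s.mean15N for s in spec.sources] + spec.tdf.meanDeltaN,
        ]
    )
    var = np.array(
        [
            (p**2) @ [s.sd13C**2 + spec.tdf.sdDeltaC**2 for s in spec.sources]
            + spec.resid_sd13C**2,
            (p**2) @ [s.sd15N**2 + spec.tdf.sdDeltaN**2 for s in spec.sources]
            + spec.resid_sd15N**2,
        ]
    )
    return mu, np.sqrt(var)


def generate_consumer(
    spec: ConsumerGenSpec, seed: int
) -> list[IsotopeMeasurement]:
    """Draw consumers from the mixing-model likelihood at known diet p."""
    mu, sd = consumer_moments(spec)
    rng = _group_rng(seed, spec.taxon)
    pts = mu + sd * rng.standard_normal((spec.n, 2))
    return [
        IsotopeMeasurement(taxon=spec.taxon, delta13C=float(c), delta15N=float(n))
        for c, n in pts
    ]


def generate_community(
    specs: Sequence[SyntheticGroupSpec],
    baseline_roles: Mapping[str, Sequence[str]],
    seed: int,
) -> CommunityDataset:
    """Concatenate generated groups into a dataset with baseline roles."""
    labels = [s.taxon for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon labels in group specs")
    for role in ("baseline1", "baseline2"):
        if role not in baseline_roles:
            raise ValueError(f"baseline role {role!r} not assigned")
        for t in baseline_roles[role]:
            if t not in labels:
                raise ValueError(f"baseline taxon {t!r} has no group spec")
    measurements: list[IsotopeMeasurement] = []
    for spec in specs:
        measurements.extend(generate_group(spec, seed))
    return CommunityDataset(
        measurements=measurements,
        summaries=summarize_measurements(measurements),
        baseline_labels={k: list(v) for k, v in baseline_roles.items()},
    )


def iznik_like_specs(
    dataset: "CommunityDataset",
    default_sd: float = 1.0,
    n_override: int | None = None,
) -> list[SyntheticGroupSpec]:
    """Group specs mirroring a summary table's means/SDs/n (e.g. the
    İznik fixture); groups lacking an SD get ``default_sd``."""
    return [
        SyntheticGroupSpec(
            taxon=s.taxon,
            n=n_override or s.n,
            mean13C=s.mean13C,
            mean15N=s.mean15N,
            sd13C=s.sd13C if s.sd13C is not None else default_sd,
            sd15N=s.sd15N if s.sd15N is not None else default_sd,
        )
        for s in dataset.summaries
    ]
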