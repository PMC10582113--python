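"""Bayesian stable-isotope mixing model for diet-proportion estimation.

A consumer's δ¹³C/δ¹⁵N values are modelled as a proportion-weighted
combination of prey-source signatures shifted by the trophic
discrimination factor (TDF); for consumer point i and isotope j:

    y_ij ~ Normal( Σ_k p_k·μ_kj + Δ_j ,
                   sqrt( Σ_k p_k²·(σ_kj² + τ_j²) + σ_j² ) )

with diet proportions p on the simplex, source moments (μ_kj, σ_kj),
TDF mean/SD (Δ_j, τ_j), and a residual SD σ_j absorbing consumer
overdispersion.  The prior on p is induced by independent standard-normal
latent variables pushed through the softmax (centred log-ratio inverse),
which is symmetric over sources and strictly interior to the simplex.
Sampling is adaptive Metropolis-within-Gibbs on the latent vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._mcmc import adapt_scales, normal_suffstats, split_rhat
from .datatypes import GroupSummary, IsotopeMeasurement, as_xy
from .trophic import MCMCConfig, TDFSpec

SIGMA_FLOOR = 1e-3
SIGMA_PRIOR_SCALE = 2.0  # ‰, half-normal prior on residual SDs


@dataclass(frozen=True)
class SourceSet:
    """Candidate prey sources: per-source isotope means, SDs, sample sizes."""

    labels: tuple[str, ...]
    mean13C: np.ndarray
    mean15N: np.ndarray
    sd13C: np.ndarray
    sd15N: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.labels)
        for name in ("mean13C", "mean15N", "sd13C", "sd15N", "n"):
            arr = np.asarray(getattr(self, name), float)
            object.__setattr__(self, name, arr)
            if arr.shape != (k,):
                raise ValueError(f"{name} must have one entry per source")
        if (self.sd13C < 0).any() or (self.sd15N < 0).any():
            raise ValueError("source SDs must be >= 0")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_summaries(
        cls, summaries: Sequence[GroupSummary], default_sd: float = 0.0
    ) -> "SourceSet":
        """Build a source set from survey-table rows; rows without a
        reported SD get ``default_sd``."""
        return cls(
            labels=tuple(s.taxon for s in summaries),
            mean13C=np.array([s.mean13C for s in summaries]),
            mean15N=np.array([s.mean15N for s in summaries]),
            sd13C=np.array(
                [s.sd13C if s.sd13C is not None else default_sd for s in summaries]
            ),
            sd15N=np.array(
                [s.sd15N if s.sd15N is not None else default_sd for s in summaries]
            ),
            n=np.array([s.n for s in summaries], float),
        )


@dataclass
class DietPosterior:
    """Posterior draws of the diet-proportion simplex over prey sources."""

    p_draws: np.ndarray  # (ndraws, K), rows on the simplex
    sigmaC_draws: np.ndarray
    sigmaN_draws: np.ndarray
    source_labels: tuple[str, ...]
    diagnostics: dict = field(default_factory=dict)

    def named_draws(self) -> dict[str, np.ndarray]:
        out = {
            f"p[{lab}]": self.p_draws[:, k]
            for k, lab in enumerate(self.source_labels)
        }
        out["sigmaC"] = self.sigmaC_draws
        out["sigmaN"] = self.sigmaN_draws
        return out

    @property
    def mean_proportions(self) -> pd.Series:
        return pd.Series(self.p_draws.mean(axis=0), index=self.source_labels)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def fit_mixing_model(
    consumer: Sequence[IsotopeMeasurement] | np.ndarray,
    sources: SourceSet,
    tdf: TDFSpec | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    prior_only: bool = False,
) -> DietPosterior:
    """Fit the mixing model; returns posterior diet proportions.

    With a single source the simplex is zero-dimensional and p = 1 is
    returned exactly.  ``prior_only`` disables the consumer likelihood
    (useful to inspect the induced prior on p).
    """
    tdf = tdf or TDFSpec()
    mcmc = mcmc or MCMCConfig()
    xy = as_xy(consumer)
    if len(xy) < 1:
        raise ValueError("need at least one consumer measurement")
    K = len(sources)
    if K < 1:
        raise ValueError("need at least one source")

    kept_total = mcmc.n_chains * (mcmc.n_iter // mcmc.thin)
    if K == 1:
        return DietPosterior(
            p_draws=np.ones((kept_total, 1)),
            sigmaC_draws=np.full(kept_total, SIGMA_FLOOR),
            sigmaN_draws=np.full(kept_total, SIGMA_FLOOR),
            source_labels=sources.labels,
            diagnostics={"degenerate": "single source; p = 1 exactly"},
        )

    nC, sC, ssC = normal_suffstats(xy[:, 0])
    nN, sN, ssN = normal_suffstats(xy[:, 1])
    muC, muN = sources.mean13C, sources.mean15N
    vC = sources.sd13C**2 + tdf.sdDeltaC**2
    vN = sources.sd15N**2 + tdf.sdDeltaN**2

    rng = np.random.default_rng(seed)
    C = mcmc.n_chains
    ls_lo, ls_hi = np.log(SIGMA_FLOOR), np.log(100.0)

    z = 0.1 * rng.standard_normal((C, K))
    lsc = 0.1 * rng.standard_normal(C)
    lsn = 0.1 * rng.standard_normal(C)

    def logpost(z_, lsc_, lsn_):
        p = _softmax(z_)
        lp = -0.5 * (z_**2).sum(axis=1)  # N(0,1) prior on latents
        sc_, sn_ = np.exp(lsc_), np.exp(lsn_)
        lp += -0.5 * (sc_ / SIGMA_PRIOR_SCALE) ** 2 + lsc_
        lp += -0.5 * (sn_ / SIGMA_PRIOR_SCALE) ** 2 + lsn_
        if prior_only:
            return lp
        mC = p @ muC + tdf.meanDeltaC
        mN = p @ muN + tdf.meanDeltaN
        sdC = np.sqrt((p**2) @ vC + sc_**2)
        sdN = np.sqrt((p**2) @ vN + sn_**2)
        lp += (
            -nC * np.log(sdC)
            - 0.5 * (ssC - 2 * mC * sC + nC * mC**2) / sdC**2
        )
        lp += (
            -nN * np.log(sdN)
            - 0.5 * (ssN - 2 * mN * sN + nN * mN**2) / sdN**2
        )
        return lp

    z_scales = np.full((C, K), 0.5)
    s_scales = {"lsc": np.full(C, 0.3), "lsn": np.full(C, 0.3)}
    total = mcmc.n_burn + mcmc.n_iter
    kept = mcmc.n_iter // mcmc.thin
    p_out = np.empty((C, kept, K))
    sc_out = np.empty((C, kept))
    sn_out = np.empty((C, kept))
    acc_z = 0.0
    keep_idx = 0

    lp = logpost(z, lsc, lsn)
    for it in range(total):
        # coordinate-wise updates on the latent diet vector
        for k in range(K):
            z_p = z.copy()
            z_p[:, k] += z_scales[:, k] * rng.standard_normal(C)
            lp_p = logpost(z_p, lsc, lsn)
            accept = np.log(rng.uniform(size=C)) < lp_p - lp
            z[accept] = z_p[accept]
            lp = np.where(accept, lp_p, lp)
            if it < mcmc.n_burn:
                adapt_scales(z_scales[:, k], accept.astype(float))
            else:
                acc_z += accept.mean() / K
        for name, arr in (("lsc", lsc), ("lsn", lsn)):
            prop = arr + s_scales[name] * rng.standard_normal(C)
            ok = (prop > ls_lo) & (prop < ls_hi)
            if name == "lsc":
                lp_p = np.where(ok, logpost(z, prop, lsn), -np.inf)
            else:
                lp_p = np.where(ok, logpost(z, lsc, prop), -np.inf)
            accept = np.log(rng.uniform(size=C)) < lp_p - lp
            arr[accept] = prop[accept]
            lp = np.where(accept, lp_p, lp)
            if it < mcmc.n_burn:
                adapt_scales(s_scales[name], accept.astype(float))
        if it >= mcmc.n_burn and (it - mcmc.n_burn) % mcmc.thin == 0:
            if keep_idx < kept:
                p_out[:, keep_idx] = _softmax(z)
                sc_out[:, keep_idx] = np.exp(lsc)
                sn_out[:, keep_idx] = np.exp(lsn)
                keep_idx += 1

    rhat_p1 = split_rhat(p_out[:, :, 0])
    diagnostics = {
        "acceptance_z": acc_z / mcmc.n_iter,
        "rhat_p1": rhat_p1,
        "converged": bool(rhat_p1 <= 1.1) if np.isfinite(rhat_p1) else False,
    }
    spreadC = np.ptp(muC) if K > 1 else np.inf
    spreadN = np.ptp(muN) if K > 1 else np.inf
    if spreadC == 0 and spreadN == 0:
        diagnostics["warning"] = (
            "all source means identical; diet proportions are not "
            "identifiable (posterior equals the prior)"
        )
    return DietPosterior(
        p_draws=p_out.reshape(-1, K),
        sigmaC_draws=sc_out.ravel(),
        sigmaN_draws=sn_out.ravel(),
        source_labels=sources.labels,
        diagnostics=diagnostics,
    )


def summarize_diet(
    posterior: DietPosterior, levels: Sequence[float] = (0.5, 0.95)
) -> pd.DataFrame:
    """Per-source posterior summary, sorted by descending posterior mean.

    Columns: mean, median and lower/upper bounds of each requested
    credible level.
    """
    if posterior.p_draws.size == 0:
        raise ValueError("posterior has no draws")
    p = posterior.p_draws
    rows = {
        "source": list(posterior.source_labels),
        "mean": p.mean(axis=0),
        "median": np.median(p, axis=0),
    }
    for level in levels:
        half = 100 * (1 - level) / 2
        lo, hi = np.percentile(p, [half, 100 - half], axis=0)
        rows[f"lo{int(round(level * 100))}"] = lo
        rows[f"hi{int(round(level * 100))}"] = hi
    frame = pd.DataFrame(rows)
    return frame.sort_values("mean", ascending=False).reset_index(drop=True)


def rank_stability(posterior: DietPosterior) -> pd.Series:
    """Posterior probability that each source holds the largest diet
    proportion; probabilities sum to 1."""
    if posterior.p_draws.size == 0:
        raise ValueError("posterior has no draws")
    winners = posterior.p_draws.argmax(axis=1)
    counts = np.bincount(winners, minlength=posterior.p_draws.shape[1])
    return pd.Series(counts / counts.sum(), index=posterior.source_labels)
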