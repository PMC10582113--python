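"""Two-baseline trophic-position model: closed form, TDF simulation, MCMC."""

import numpy as np
import pytest

import isocast as ic
from isocast.datatypes import as_xy


def _baselines(lam=2.0, sd=0.0, n=10):
    sd_ = sd if sd > 0 else None
    return ic.BaselineSpec(
        b1_label="b1",
        b2_label="b2",
        b1_15N=ic.IsotopeMoments(5.0, sd_, n),
        b2_15N=ic.IsotopeMoments(4.0, sd_, n),
        b1_13C=ic.IsotopeMoments(-16.0, sd_, n),
        b2_13C=ic.IsotopeMoments(-24.0, sd_, n),
        lam=lam,
    )


class TestSimulateTDF:
    def test_moments_at_default_spec(self):
        draws = ic.simulate_tdf(ic.TDFSpec(nsim=10_000), seed=1)
        assert abs(draws.deltaN.mean() - 3.4) < 0.03  # 3 SE at nsim=1e4
        assert abs(draws.deltaN.std(ddof=1) - 0.98) < 0.03

    def test_zero_sd_is_constant(self):
        draws = ic.simulate_tdf(ic.TDFSpec(sdDeltaN=0.0, nsim=100), seed=1)
        assert np.all(draws.deltaN == 3.4)

    def test_seed_reproducibility(self):
        a = ic.simulate_tdf(ic.TDFSpec(nsim=50), seed=9)
        b = ic.simulate_tdf(ic.TDFSpec(nsim=50), seed=9)
        np.testing.assert_array_equal(a.deltaN, b.deltaN)


class TestPointEstimate:
    def test_one_step_enrichment_on_baseline1(self):
        b = _baselines()
        tp, alpha = ic.tp_point_estimate(-16.0, 5.0 + 3.4, b, deltaN=3.4)
        assert alpha == 1.0
        assert tp == pytest.approx(3.0)  # lambda + 1

    def test_alpha_clipped_outside_baseline_interval(self):
        b = _baselines()
        _, alpha_lo = ic.tp_point_estimate(-30.0, 9.0, b)
        _, alpha_hi = ic.tp_point_estimate(-10.0, 9.0, b)
        assert alpha_lo == 0.0 and alpha_hi == 1.0

    def test_iznik_apex_closed_form(self, iznik_baselines):
        # hand evaluation: alpha = (-24.65 + 23.135)/(-16.60 + 23.135) < 0
        # → 0; TP = 2 + (12.60 − 4.71)/3.4 = 4.320588…
        tp, alpha = ic.tp_point_estimate(
            -24.65, 12.60, iznik_baselines, deltaN=3.4, lam=2.0
        )
        assert alpha == 0.0
        assert tp == pytest.approx(4.3205882, abs=1e-6)

    def test_nonpositive_deltan_rejected(self):
        with pytest.raises(ValueError):
            ic.tp_point_estimate(-20.0, 9.0, _baselines(), deltaN=0.0)


class TestFitTwoBaselineTP:
    def test_collapses_to_closed_form_as_sds_vanish(self, fast_mcmc):
        b = _baselines(sd=0.0)
        tdf = ic.TDFSpec(3.4, 0.0, 0.0, 0.0)
        tp_true, alpha_true = 3.2, 0.4
        muN = alpha_true * 5.0 + (1 - alpha_true) * 4.0 + 3.4 * (tp_true - 2.0)
        muC = alpha_true * -16.0 + (1 - alpha_true) * -24.0
        consumer = np.tile([muC, muN], (10, 1))
        post = ic.fit_two_baseline_tp(consumer, b, tdf=tdf, mcmc=fast_mcmc, seed=1)
        tp_pt, _ = ic.tp_point_estimate(muC, muN, b, deltaN=3.4)
        assert post.tp_median == pytest.approx(tp_pt, abs=0.01)
        assert post.alpha_median == pytest.approx(alpha_true, abs=0.01)

    def test_monotone_in_consumer_d15n(self, fast_mcmc):
        b = _baselines()
        medians = []
        for d15n in (7.0, 9.0, 11.0):
            consumer = np.column_stack(
                [np.full(8, -20.0), np.full(8, d15n) + [0.1, -0.1] * 4]
            )
            post = ic.fit_two_baseline_tp(consumer, b, mcmc=fast_mcmc, seed=5)
            medians.append(post.tp_median)
        assert medians[0] < medians[1] < medians[2]

    def test_alpha_swap_invariance(self, rng):
        # α and TP autocorrelate strongly (TDF latents); longer chains keep
        # the Monte-Carlo error below the comparison tolerance
        mcmc = ic.MCMCConfig(n_chains=4, n_iter=8000, n_burn=2000)
        b = _baselines(sd=0.3)
        consumer = rng.normal([-20.0, 9.0], 0.4, size=(12, 2))
        post = ic.fit_two_baseline_tp(consumer, b, mcmc=mcmc, seed=3)
        post_sw = ic.fit_two_baseline_tp(consumer, b.swapped(), mcmc=mcmc, seed=4)
        assert post_sw.alpha_median == pytest.approx(1 - post.alpha_median, abs=0.06)
        assert post_sw.tp_median == pytest.approx(post.tp_median, abs=0.15)

    def test_recovers_true_tp_in_interval(self, fast_mcmc):
        b = _baselines(sd=0.3)
        tdf = ic.TDFSpec(3.4, 0.3, 0.39, 0.3)
        tp_true, alpha_true = 3.5, 0.5
        muN = alpha_true * 5.0 + (1 - alpha_true) * 4.0 + 3.4 * (tp_true - 2.0)
        muC = alpha_true * -16.0 + (1 - alpha_true) * -24.0 + 0.39 * (tp_true - 2.0)
        consumer = np.random.default_rng(11).normal([muC, muN], 0.4, size=(25, 2))
        post = ic.fit_two_baseline_tp(consumer, b, tdf=tdf, mcmc=fast_mcmc, seed=2)
        lo, hi = post.tp_interval(0.95)
        assert lo < tp_true < hi
        assert post.tp_median == pytest.approx(tp_true, abs=0.5)

    def test_identical_baseline_carbon_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            ic.BaselineSpec(
                b1_label="a",
                b2_label="b",
                b1_15N=ic.IsotopeMoments(5.0),
                b2_15N=ic.IsotopeMoments(4.0),
                b1_13C=ic.IsotopeMoments(-20.0),
                b2_13C=ic.IsotopeMoments(-20.0),
            )

    def test_single_point_warns(self, fast_mcmc):
        with pytest.warns(UserWarning, match="single consumer"):
            ic.fit_two_baseline_tp(
                np.array([[-20.0, 9.0]]), _baselines(), mcmc=fast_mcmc, seed=1
            )

    def test_draw_invariants(self, fast_mcmc, rng):
        consumer = rng.normal([-20.0, 9.0], 0.5, size=(10, 2))
        post = ic.fit_two_baseline_tp(consumer, _baselines(), mcmc=fast_mcmc, seed=6)
        assert np.all((post.alpha_draws >= 0) & (post.alpha_draws <= 1))
        assert np.all(post.tp_draws >= post.lam)
        assert (
            len(post.tp_draws)
            == len(post.alpha_draws)
            == len(post.sigmaN_draws)
            == len(post.sigmaC_draws)
        )

    def test_reproducible_given_seed(self, fast_mcmc, rng):
        consumer = rng.normal([-20.0, 9.0], 0.5, size=(8, 2))
        a = ic.fit_two_baseline_tp(consumer, _baselines(), mcmc=fast_mcmc, seed=42)
        b = ic.fit_two_baseline_tp(consumer, _baselines(), mcmc=fast_mcmc, seed=42)
        np.testing.assert_array_equal(a.tp_draws, b.tp_draws)
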