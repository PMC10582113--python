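"""Synthetic community and consumer generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import isocast as ic
from isocast.datatypes import as_xy


def _spec(**kw):
    base = dict(taxon="g", n=100, mean13C=-22.0, mean15N=9.0, sd13C=1.0, sd15N=1.0)
    base.update(kw)
    return ic.SyntheticGroupSpec(**base)


class TestGenerateGroup:
    def test_moments_converge(self):
        xy = as_xy(ic.generate_group(_spec(n=5000, mean15N=10.0, sd15N=1.0), seed=1))
        se = 1.0 / np.sqrt(5000)
        assert abs(xy[:, 1].mean() - 10.0) < 3 * se

    def test_zero_sd_collapses_to_mean(self):
        xy = as_xy(ic.generate_group(_spec(n=20, sd13C=0.0, sd15N=0.0), seed=1))
        assert np.all(xy == [-22.0, 9.0])

    def test_seed_determinism(self):
        a = as_xy(ic.generate_group(_spec(), seed=7))
        b = as_xy(ic.generate_group(_spec(), seed=7))
        np.testing.assert_array_equal(a, b)

    def test_streams_independent_of_other_groups(self):
        # same seed, different taxon label → different stream; same label
        # → same draws regardless of what else is generated
        a = as_xy(ic.generate_group(_spec(taxon="a"), seed=3))
        b = as_xy(ic.generate_group(_spec(taxon="b"), seed=3))
        assert not np.array_equal(a, b)
        again = as_xy(ic.generate_group(_spec(taxon="a"), seed=3))
        np.testing.assert_array_equal(a, again)

    def test_match_moments_is_exact(self):
        spec = _spec(n=10, rho=0.3)
        xy = as_xy(ic.generate_group(spec, seed=5, match_moments=True))
        assert xy[:, 0].mean() == pytest.approx(-22.0, abs=1e-9)
        assert xy[:, 1].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        rho = np.corrcoef(xy.T)[0, 1]
        assert rho == pytest.approx(0.3, abs=1e-9)

    @given(rho=st.floats(-0.9, 0.9), sd=st.floats(0.1, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_covariance_construction(self, rho, sd):
        spec = _spec(sd13C=sd, sd15N=2.0, rho=rho)
        cov = spec.cov
        assert cov[0, 1] == pytest.approx(rho * sd * 2.0)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            _spec(n=0)
        with pytest.raises(ValueError):
            _spec(rho=1.5)
        with pytest.raises(ValueError):
            _spec(sd13C=-1.0)


class TestGenerateConsumer:
    def test_degenerate_single_source_hits_mean(self):
        src = _spec(taxon="s", sd13C=0.0, sd15N=0.0)
        spec = ic.ConsumerGenSpec(
            sources=(src,),
            proportions=(1.0,),
            tdf=ic.TDFSpec(0.0, 0.0, 0.0, 0.0),
            n=5,
        )
        xy = as_xy(ic.generate_consumer(spec, seed=1))
        assert np.all(xy == [-22.0, 9.0])

    def test_two_source_symmetry(self):
        s1 = _spec(taxon="a", mean15N=0.0, sd15N=0.5)
        s2 = _spec(taxon="b", mean15N=10.0, sd15N=0.5)
        spec = ic.ConsumerGenSpec(
            sources=(s1, s2),
            proportions=(0.5, 0.5),
            tdf=ic.TDFSpec(0.0, 0.0, 0.0, 0.0),
            n=4000,
        )
        xy = as_xy(ic.generate_consumer(spec, seed=2))
        mu, sd = ic.consumer_moments(spec)
        assert mu[1] == pytest.approx(5.0)
        assert abs(xy[:, 1].mean() - 5.0) < 3 * sd[1] / np.sqrt(4000)

    def test_moments_formula(self):
        s1 = _spec(taxon="a", sd13C=1.0, sd15N=2.0)
        s2 = _spec(taxon="b", sd13C=0.5, sd15N=1.0)
        tdf = ic.TDFSpec(3.4, 0.98, 0.39, 1.3)
        spec = ic.ConsumerGenSpec(
            sources=(s1, s2), proportions=(0.7, 0.3), tdf=tdf,
            resid_sd13C=0.4, resid_sd15N=0.6, n=1,
        )
        mu, sd = ic.consumer_moments(spec)
        assert mu[1] == pytest.approx(0.7 * 9 + 0.3 * 9 + 3.4)
        expected_var = (
            0.49 * (4 + 0.98**2) + 0.09 * (1 + 0.98**2) + 0.36
        )
        assert sd[1] ** 2 == pytest.approx(expected_var)

    def test_simplex_validation(self):
        s = _spec()
        with pytest.raises(ValueError):
            ic.ConsumerGenSpec(sources=(s,), proportions=(0.9,))


class TestGenerateCommunity:
    def _roles(self):
        return {"baseline1": ["det"], "baseline2": ["plank"]}

    def _specs(self):
        return [
            _spec(taxon="det", n=10, mean13C=-16.0, mean15N=5.0),
            _spec(taxon="plank", n=10, mean13C=-24.0, mean15N=4.0),
            _spec(taxon="fish", n=10, mean13C=-21.0, mean15N=9.0),
        ]

    def test_counts(self):
        ds = ic.generate_community(self._specs(), self._roles(), seed=1)
        assert len(ds.measurements) == 30
        assert len(ds.summaries) == 3

    def test_iznik_like_preset(self, iznik):
        specs = ic.iznik_like_specs(iznik)
        assert len(specs) == 19
        ds = ic.generate_community(
            specs,
            {"baseline1": ["Detritus"], "baseline2": ["Phytoplankton", "Zooplankton"]},
            seed=1,
        )
        assert len(ds.summaries) == 19

    def test_duplicate_labels_rejected(self):
        specs = self._specs() + [_spec(taxon="fish")]
        with pytest.raises(ValueError, match="duplicate"):
            ic.generate_community(specs, self._roles(), seed=1)

    def test_missing_baseline_role_rejected(self):
        with pytest.raises(ValueError, match="baseline2"):
            ic.generate_community(self._specs(), {"baseline1": ["det"]}, seed=1)


def test_generator_agrees_with_mixing_likelihood():
    """Average log-density of generated consumers is highest at the true
    diet (the generator and the fitted likelihood share one forward
    model)."""
    s1 = _spec(taxon="a", mean13C=-30.0, mean15N=5.0, sd13C=0.5, sd15N=0.5)
    s2 = _spec(taxon="b", mean13C=-20.0, mean15N=12.0, sd13C=0.5, sd15N=0.5)
    tdf = ic.TDFSpec(3.4, 0.5, 0.39, 0.5)
    true_p = (0.8, 0.2)
    spec = ic.ConsumerGenSpec(
        sources=(s1, s2), proportions=true_p, tdf=tdf,
        resid_sd13C=0.2, resid_sd15N=0.2, n=2000,
    )
    xy = as_xy(ic.generate_consumer(spec, seed=9))

    def avg_loglik(p):
        gen = ic.ConsumerGenSpec(
            sources=(s1, s2), proportions=p, tdf=tdf,
            resid_sd13C=0.2, resid_sd15N=0.2, n=1,
        )
        mu, sd = ic.consumer_moments(gen)
        z = (xy - mu) / sd
        return (-0.5 * z**2 - np.log(sd)).sum(axis=1).mean()

    assert avg_loglik(true_p) > avg_loglik((0.5, 0.5))
    assert avg_loglik(true_p) > avg_loglik((0.95, 0.05))
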