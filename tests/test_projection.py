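"""Superimposition, prey selection, and the end-to-end forecast."""

import numpy as np
import pandas as pd
import pytest

import isocast as ic
from isocast.datatypes import as_xy


@pytest.fixture(scope="module")
def donors(perch):
    return ic.donors_from_perch_sites(perch, assumed_sd=1.0)


@pytest.fixture
def tiny_config():
    return ic.ProjectionConfig(
        mcmc=ic.MCMCConfig(n_chains=2, n_iter=600, n_burn=300),
        seab_draws=100,
        overlap_nmc=400,
        niche_levels=(0.95,),
    )


class TestSuperimpose:
    def test_append_contract(self, iznik, donors):
        combined = ic.superimpose(donors, iznik, seed=1)
        n_donor_pts = sum(d.n_per_site * len(d.site_means) for d in donors)
        assert len(combined.measurements) == n_donor_pts
        assert len(combined.summaries) == len(iznik.summaries) + 2
        # recipient summaries bit-identical
        for s in iznik.summaries:
            assert combined.summary(s.taxon) == s
        assert all(
            m.status == "hypothetical" for m in combined.measurements
        )

    def test_donor_site_means_reproduced(self, iznik, donors, perch):
        combined = ic.superimpose(donors, iznik, seed=1)
        lakes = combined.summary("P. fluviatilis (lakes)")
        site_means = [
            s.mean15N for s in perch.summaries if s.status == "native"
        ]
        assert lakes.mean15N == pytest.approx(np.mean(site_means), abs=1e-9)

    def test_deterministic_given_seed(self, iznik, donors):
        a = ic.superimpose(donors, iznik, seed=5)
        b = ic.superimpose(donors, iznik, seed=5)
        np.testing.assert_array_equal(
            as_xy(a.measurements), as_xy(b.measurements)
        )

    def test_standardize_identical_baselines_is_noop(self, iznik, donors):
        rows = [
            iznik.summary(t)
            for t in ("Detritus", "Phytoplankton", "Zooplankton")
        ]
        base = (
            float(np.mean([r.mean13C for r in rows])),
            float(np.mean([r.mean15N for r in rows])),
        )
        raw = ic.superimpose(donors, iznik, seed=2)
        std = ic.superimpose(
            donors,
            iznik,
            standardize=True,
            donor_baselines={d.label: base for d in donors},
            seed=2,
        )
        np.testing.assert_allclose(
            as_xy(raw.measurements), as_xy(std.measurements), atol=1e-9
        )

    def test_standardize_requires_donor_baselines(self, iznik, donors):
        with pytest.raises(ValueError, match="donor_baselines"):
            ic.superimpose(donors, iznik, standardize=True)


class TestSelectPrey:
    def test_iznik_prey_count_is_11(self, iznik):
        prey = ic.select_prey(iznik, "Silurus glanis")
        assert len(prey) == 11
        assert "Silurus glanis" not in prey.labels

    def test_nonfish_never_prey(self, iznik):
        prey = ic.select_prey(iznik, "Silurus glanis")
        assert set(prey.labels).isdisjoint(
            {"Detritus", "Zooplankton", "Pelophylax ridibundus", "Macrophytes"}
        )

    def test_size_threshold_filters_large_taxa(self, iznik):
        prey = ic.select_prey(iznik, "Silurus glanis", size_threshold=150.0)
        # TL > 150 mm in the fixture: C. tinca (256) and R. frisii (218.4)
        assert len(prey) == 9
        assert {"Capoeta tinca", "Rutilus frisii"}.isdisjoint(prey.labels)

    def test_superimposed_donors_excluded(self, iznik, donors):
        combined = ic.superimpose(donors, iznik, seed=1)
        prey = ic.select_prey(combined, "Silurus glanis")
        assert len(prey) == 11

    def test_missing_apex_rejected(self, iznik):
        with pytest.raises(ValueError, match="apex"):
            ic.select_prey(iznik, "Esox lucius")

    def test_empty_prey_set_rejected(self, iznik):
        fish = [s.taxon for s in iznik.summaries if s.is_fish]
        with pytest.raises(ValueError, match="empty"):
            ic.select_prey(
                iznik, "Silurus glanis",
                extra_exclusions=[t for t in fish if t != "Silurus glanis"],
            )


@pytest.fixture(scope="module")
def report(iznik, donors):
    scenario = ic.ProjectionScenario(
        recipient=iznik, donors=tuple(donors), apex_label="Silurus glanis"
    )
    config = ic.ProjectionConfig(
        mcmc=ic.MCMCConfig(n_chains=2, n_iter=600, n_burn=300),
        seab_draws=100,
        overlap_nmc=400,
        niche_levels=(0.95,),
    )
    return ic.run_projection(scenario, config, seed=7)


class TestRunProjection:
    def test_every_donor_has_diet_and_overlap(self, report, donors):
        for d in donors:
            assert d.label in report.diet_by_donor
            assert any(d.label in k for k in report.overlap_seab)
            mat = report.overlap_directional[0.95]
            assert not np.isnan(mat.loc[d.label, "Silurus glanis"])

    def test_predators_top_the_tp_ladder(self, report, donors):
        tp = report.tp_median_table()
        predators = {d.label for d in donors} | {"Silurus glanis"}
        prey_tp = tp.drop(labels=predators)
        assert tp[list(predators)].min() > prey_tp.max()

    def test_provenance_recorded(self, report):
        prov = report.provenance
        assert prov["seed"] == 7
        assert prov["apex"] == "Silurus glanis"
        assert len(prov["prey_sources"]) == 11

    def test_report_serialization(self, report, tmp_path):
        outdir = report.write(tmp_path / "report")
        assert (outdir / "provenance.json").exists()
        assert (outdir / "tp_medians.csv").exists()
        medians = pd.read_csv(outdir / "tp_medians.csv", index_col=0)
        assert len(medians) == len(report.tp_by_group)

    def test_reproducible_given_seed(self, iznik, donors, tiny_config):
        scenario = ic.ProjectionScenario(
            recipient=iznik, donors=tuple(donors), apex_label="Silurus glanis"
        )
        a = ic.run_projection(scenario, tiny_config, seed=3)
        b = ic.run_projection(scenario, tiny_config, seed=3)
        assert a.tp_median_table().equals(b.tp_median_table())
        for lab in a.diet_by_donor:
            np.testing.assert_array_equal(
                a.diet_by_donor[lab].p_draws, b.diet_by_donor[lab].p_draws
            )

    def test_residents_unaffected_by_donors(self, iznik, donors, tiny_config):
        """Superimposition must not perturb resident inference: fitting a
        resident group before and after adding donors gives identical
        posteriors."""
        baselines = ic.baseline_from_community(iznik)
        combined = ic.superimpose(donors, iznik, seed=1)
        for ds in (iznik, combined):
            assert ds.summary("Vimba vimba") == iznik.summary("Vimba vimba")
        s = iznik.summary("Vimba vimba")
        pts = ic.generate_group(
            ic.SyntheticGroupSpec(
                "Vimba vimba", n=s.n, mean13C=s.mean13C, mean15N=s.mean15N,
                sd13C=s.sd13C, sd15N=s.sd15N,
            ),
            seed=2,
            match_moments=True,
        )
        a = ic.fit_two_baseline_tp(pts, baselines, mcmc=tiny_config.mcmc, seed=4)
        b = ic.fit_two_baseline_tp(
            pts, ic.baseline_from_community(combined), mcmc=tiny_config.mcmc, seed=4
        )
        np.testing.assert_array_equal(a.tp_draws, b.tp_draws)


def test_sd_sensitivity_scan(iznik, donors):
    scenario = ic.ProjectionScenario(
        recipient=iznik, donors=(donors[0],), apex_label="Silurus glanis"
    )
    config = ic.ProjectionConfig(
        mcmc=ic.MCMCConfig(n_chains=2, n_iter=400, n_burn=200),
        seab_draws=50,
        overlap_nmc=300,
        niche_levels=(0.95,),
        sd_sensitivity=(0.5, 2.0),
    )
    report = ic.run_projection(scenario, config, seed=11)
    assert set(report.sd_sensitivity["assumed_sd"]) == {0.5, 2.0}
    assert {"tp_median", "top_prey"} <= set(report.sd_sensitivity.columns)
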