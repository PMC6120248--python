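"""Tests for the synthetic generators: reproducibility, designed signal,
moment calibration and degenerate cases."""
import numpy as np
import pandas as pd
import pytest

from mirmeta import clinical, meta, screen, synthetic
from mirmeta.datatypes import ValidationError


def cohort_spec(**kw):
    base = dict(
        n_features=100,
        n_per_group={"normal": 10, "tumor": 10},
        n_de=10,
        lfc_true=2.0,
        sigma=0.5,
        seed=7,
    )
    base.update(kw)
    return synthetic.CohortSpec(**base)


class TestExpressionCohort:
    def test_seed_reproducibility_bit_identical(self):
        a = synthetic.gen_expression_cohort(cohort_spec())
        b = synthetic.gen_expression_cohort(cohort_spec())
        pd.testing.assert_frame_equal(a.values, b.values)
        c = synthetic.gen_expression_cohort(cohort_spec(seed=8))
        assert not a.values.equals(c.values)

    def test_values_positive_and_shift_recovered(self):
        cohort = synthetic.gen_expression_cohort(cohort_spec(sigma=0.2))
        assert (cohort.values.to_numpy() > 0).all()
        logv = np.log2(cohort.values)
        normal = logv[cohort.samples_in("normal")].mean(axis=1)
        tumor = logv[cohort.samples_in("tumor")].mean(axis=1)
        de = cohort.metadata["de_features"]
        shift = (tumor - normal).loc[de]
        assert shift.mean() == pytest.approx(2.0, abs=0.2)

    def test_null_screen_type_i_error_near_alpha(self):
        # no true shifts: the downstream screen's p < alpha rate should sit
        # near alpha across replicates
        rates = []
        for seed in range(5):
            cohort = synthetic.gen_expression_cohort(
                cohort_spec(n_features=400, n_de=0, lfc_true=0.0, sigma=1.0, seed=seed)
            )
            de = screen.log2fc_screen(cohort, "normal", "tumor")
            rates.append((de["p"] < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_tiny_noise_keeps_group_means_at_truth(self):
        cohort = synthetic.gen_expression_cohort(
            cohort_spec(n_de=0, sigma=0.01, n_per_group={"normal": 30, "tumor": 30})
        )
        logv = np.log2(cohort.values)
        gap = (
            logv[cohort.samples_in("tumor")].mean(axis=1)
            - logv[cohort.samples_in("normal")].mean(axis=1)
        )
        assert np.abs(gap).max() < 0.05

    def test_arm_suffixes_present_and_fraction_respected(self):
        cohort = synthetic.gen_expression_cohort(cohort_spec(arm_fraction=0.5))
        n_arm = sum(f.endswith(("-5p", "-3p")) for f in cohort.values.index)
        assert n_arm == 50

    def test_paired_design_induces_positive_correlation(self):
        spec = cohort_spec(
            paired=True, pair_rho=0.8, sigma=1.0, n_de=0,
            n_per_group={"normal": 50, "tumor": 50}, n_features=200,
        )
        cohort = synthetic.gen_expression_cohort(spec)
        logv = np.log2(cohort.values)
        a = logv[cohort.samples_in("normal")].to_numpy()
        b = logv[cohort.samples_in("tumor")].to_numpy()
        r = np.mean(
            [np.corrcoef(a[i], b[i])[0, 1] for i in range(a.shape[0])]
        )
        assert r > 0.5

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            cohort_spec(sigma=0.0)
        with pytest.raises(ValidationError):
            cohort_spec(n_de=101)
        with pytest.raises(ValidationError):
            cohort_spec(n_per_group={"normal": 0, "tumor": 5})


class TestMetaStudies:
    def test_seed_reproducibility(self):
        spec = synthetic.MetaSimSpec(k_studies=5, smd_true=0.5, tau=0.2, seed=3)
        a = synthetic.gen_meta_studies(spec)
        b = synthetic.gen_meta_studies(spec)
        assert a == b

    def test_single_study_pools_to_itself(self):
        rows = synthetic.gen_meta_studies(
            synthetic.MetaSimSpec(k_studies=1, smd_true=0.5, tau=0.0, seed=2)
        )
        e = meta.smd(rows[0].case, rows[0].control)
        r = meta.pool_fixed([e])
        assert r.pooled == pytest.approx(e.d)

    def test_homogeneous_large_studies_recover_truth(self):
        rows = synthetic.gen_meta_studies(
            synthetic.MetaSimSpec(k_studies=40, smd_true=0.6, tau=0.0,
                                  n_range=(400, 400), seed=4)
        )
        r = meta.pool_fixed(meta.effects_from_rows(rows))
        assert r.pooled == pytest.approx(0.6, abs=3 * r.se)
        assert r.het.I2 < 30

    def test_arm_moments_match_design(self):
        # one huge arm pair: empirical mean/SD should sit at the model values
        rows = synthetic.gen_meta_studies(
            synthetic.MetaSimSpec(k_studies=1, smd_true=0.7, tau=0.0,
                                  n_range=(20000, 20000), seed=9)
        )
        r = rows[0]
        assert r.control.mean == pytest.approx(0.0, abs=0.03)
        assert r.control.sd == pytest.approx(1.0, abs=0.03)
        assert r.case.mean == pytest.approx(0.7, abs=0.03)

    def test_null_ci_coverage_near_nominal(self):
        cover = 0
        reps = 200
        for rep in range(reps):
            rows = synthetic.gen_meta_studies(
                synthetic.MetaSimSpec(k_studies=8, smd_true=0.0, tau=0.0, seed=5000 + rep)
            )
            r = meta.pool_fixed(meta.effects_from_rows(rows))
            cover += r.ci_low <= 0.0 <= r.ci_high
        assert cover / reps == pytest.approx(0.95, abs=0.05)

    def test_bad_n_range_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.MetaSimSpec(k_studies=2, smd_true=0.0, tau=0.1, n_range=(50, 10))


class TestDiagStudies:
    def test_seed_reproducibility(self):
        spec = synthetic.DiagSimSpec(k_studies=6, mu_logit_sens=0.8, mu_logit_spec=1.5, seed=3)
        assert synthetic.gen_diag_studies(spec) == synthetic.gen_diag_studies(spec)

    def test_no_heterogeneity_huge_n_hits_expit_mu(self):
        from scipy.special import expit

        spec = synthetic.DiagSimSpec(
            k_studies=5, mu_logit_sens=0.8, mu_logit_spec=2.2,
            sigma_sens=0.0, sigma_spec=0.0, rho=0.0,
            n_diseased_range=(50000, 50000), n_healthy_range=(50000, 50000), seed=2,
        )
        for s in synthetic.gen_diag_studies(spec):
            assert s.tp / s.n_diseased == pytest.approx(expit(0.8), abs=0.01)
            assert s.tn / s.n_healthy == pytest.approx(expit(2.2), abs=0.01)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.DiagSimSpec(k_studies=3, mu_logit_sens=0, mu_logit_spec=0, rho=1.5)


class TestSurvival:
    def test_null_hazard_gives_uniformish_logrank_p(self):
        ps = []
        for rep in range(60):
            df = synthetic.gen_survival(80, hr_true=1.0, seed=100 + rep)
            try:
                ps.append(clinical.km_logrank(df["time"], df["event"], df["group"]).p)
            except ValidationError:
                continue
        assert np.mean(ps) == pytest.approx(0.5, abs=0.12)
        assert (np.array(ps) < 0.05).mean() < 0.15

    def test_strong_hazard_detected(self):
        df = synthetic.gen_survival(400, hr_true=3.0, seed=11)
        r = clinical.km_logrank(df["time"], df["event"], df["group"])
        assert r.hr > 1.5
        assert r.p < 0.01

    def test_zero_events_surface_downstream_error(self):
        df = synthetic.gen_survival(50, hr_true=1.0, seed=1)
        df["event"] = 0
        with pytest.raises(ValidationError):
            clinical.km_logrank(df["time"], df["event"], df["group"])

    def test_invalid_args_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.gen_survival(1, hr_true=1.0)
        with pytest.raises(ValidationError):
            synthetic.gen_survival(10, hr_true=0.0)


class TestEvidenceNetwork:
    def test_full_membership_passes_any_threshold(self):
        from mirmeta import enrich

        ev, _ = synthetic.gen_evidence_and_network(30, membership_prob=1.0, edge_prob=0.1, seed=1)
        for mv in (1, 6, 12):
            assert len(enrich.vote_count(ev, min_votes=mv)) == 30

    def test_no_edges_no_hubs(self):
        from mirmeta import network

        _, edges = synthetic.gen_evidence_and_network(30, edge_prob=0.0, seed=1)
        net = network.build_network(edges)
        assert network.degree_hubs(net, min_degree=1).empty

    def test_expected_votes_match_moment(self):
        ev, _ = synthetic.gen_evidence_and_network(
            5000, n_sources=12, membership_prob=0.4, edge_prob=0.0, seed=2
        )
        assert ev.sum(axis=1).mean() == pytest.approx(12 * 0.4, abs=0.1)

    def test_probability_validation(self):
        with pytest.raises(ValidationError):
            synthetic.gen_evidence_and_network(10, membership_prob=1.5)
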