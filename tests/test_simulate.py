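"""Simulator: transmission genetics, liability calibration, follow-up, I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinrisk import io as kio
from kinrisk.pgs import compute_scores
from kinrisk.simulate import (
    DEFAULT_ONSET_SCALE,
    DEFAULT_ONSET_SHAPE,
    SimulationConfig,
    calibrate_onset,
    default_config,
    derive_family_history,
    generate_followup,
    mate_and_transmit,
    onset_from_liability,
    simulate_cohort,
    simulate_founders,
    write_cohort,
)

from conftest import panel_from_variants


class TestFounders:
    def test_binomial_moments_at_half(self, rng):
        cfg = default_config(n_families=20_000, n_variants=1, allele_freqs=np.array([0.5]))
        f, _ = simulate_founders(cfg, rng)
        assert f.mean() == pytest.approx(1.0, abs=0.02)
        assert f.var() == pytest.approx(0.5, abs=0.02)

    def test_vanishing_frequency_gives_monomorphic_zero(self, rng):
        cfg = default_config(n_families=1000, n_variants=1, allele_freqs=np.array([1e-9]))
        f, m = simulate_founders(cfg, rng)
        assert (f == 0).all() and (m == 0).all()

    def test_genotype_frequencies_match_binomial_oracle(self, rng):
        # exact binomial probabilities for f=0.3: (0.49, 0.42, 0.09)
        n = 10_000
        cfg = default_config(n_families=n, n_variants=1, allele_freqs=np.array([0.3]))
        f, _ = simulate_founders(cfg, rng)
        probs = {g: stats.binom.pmf(g, 2, 0.3) for g in (0, 1, 2)}
        for g, p in probs.items():
            obs = (f[:, 0] == g).mean()
            assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_empty_panel_is_error(self, rng):
        cfg = default_config()
        cfg.allele_freqs = np.array([])
        with pytest.raises(ValueError, match="non-empty"):
            simulate_founders(cfg, rng)


class TestTransmission:
    def test_homozygote_parents_force_child_dosage(self, rng):
        two = np.full((5, 3), 2)
        zero = np.zeros((5, 3), dtype=int)
        assert (mate_and_transmit(two, two, rng) == 2).all()
        assert (mate_and_transmit(zero, zero, rng) == 0).all()

    def test_het_by_het_matches_punnett_square(self, rng):
        # punnett enumeration oracle: Aa x Aa -> {0: 1/4, 1: 1/2, 2: 1/4}
        n = 10_000
        ones = np.ones((n, 1), dtype=int)
        child = mate_and_transmit(ones, ones, rng)[:, 0]
        for g, p in {0: 0.25, 1: 0.5, 2: 0.25}.items():
            assert abs((child == g).mean() - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_non_integer_dosage_rejected(self, rng):
        with pytest.raises(ValueError, match="integers"):
            mate_and_transmit(np.array([[0.5]]), np.array([[1.0]]), rng)


class TestLiability:
    def test_no_genetics_means_score_independent_of_liability(self):
        cfg = default_config(n_families=10_000, h2=0.0, c2=0.0, pgs_capture=0.5, seed=3)
        co = simulate_cohort(cfg)
        idx = co.truth[co.truth["role"] == "index"]
        r = np.corrcoef(idx["true_pgs"], idx["liability"])[0, 1]
        assert abs(r) < 0.03

    def test_sibling_liability_correlation_tracks_shared_environment(self):
        cfg = default_config(
            n_families=4000, h2=0.0, c2=0.95, pgs_capture=0.5,
            sibling_count_dist={1: 1.0}, seed=4,
        )
        co = simulate_cohort(cfg)
        tr = co.truth
        sib = tr[tr["role"] == "sibling"].set_index("family_id")["liability"]
        idx = tr[tr["role"] == "index"].set_index("family_id")["liability"]
        fam = sib.index.intersection(idx.index)
        r = np.corrcoef(idx.loc[fam], sib.loc[fam])[0, 1]
        assert r == pytest.approx(0.95, abs=0.03)

    def test_pgs_liability_correlation_matches_variance_decomposition(self, big_cohort):
        # corr^2(true_pgs, L) = h2 * pgs_capture = 0.4 * 0.5 = 0.2
        idx = big_cohort.truth[big_cohort.truth["role"] == "index"]
        r2 = np.corrcoef(idx["true_pgs"], idx["liability"])[0, 1] ** 2
        assert r2 == pytest.approx(0.2, abs=0.02)

    def test_liability_variance_is_unit(self, big_cohort):
        assert big_cohort.truth["liability"].var() == pytest.approx(1.0, rel=0.05)

    def test_excessive_variance_fractions_rejected(self):
        with pytest.raises(ValueError, match="h2"):
            default_config(h2=0.7, c2=0.4).validate()

    def test_parent_offspring_regression_recovers_half_h2(self):
        # additive-genetics-only setting: slope = h2/2
        cfg = default_config(n_families=10_000, c2=0.0, seed=9, sibling_count_dist={0: 1.0})
        co = simulate_cohort(cfg)
        tr = co.truth
        father = tr[tr["role"] == "father"].set_index("family_id")["liability"]
        child = tr[tr["role"] == "index"].set_index("family_id")["liability"]
        slope = np.polyfit(father.loc[child.index], child, 1)[0]
        assert slope == pytest.approx(cfg.h2 / 2, abs=0.03)


class TestOnset:
    def test_null_liability_effect_matches_weibull_closed_form(self, rng):
        cfg = default_config(liability_hazard_beta=0.0)
        t = onset_from_liability(np.zeros(5000), cfg, rng)
        cdf = lambda x: 1 - np.exp(-cfg.onset_hazard_scale * x**cfg.onset_hazard_shape)
        assert stats.kstest(t, cdf).pvalue > 0.01

    def test_very_low_liability_never_develops_disease(self, rng):
        cfg = default_config()
        t = onset_from_liability(np.full(100, -40.0), cfg, rng)
        assert (t > 150).all()  # onset far beyond any attainable age

    def test_negative_parameters_rejected(self, rng):
        cfg = default_config()
        cfg.onset_hazard_shape = -1.0
        with pytest.raises(ValueError, match="positive"):
            onset_from_liability(np.zeros(3), cfg, rng)

    def test_default_prevalence_calibration(self, big_cohort):
        # target 8.3% prevalent within 3 Monte Carlo sd at n=10,000
        prev = big_cohort.cohort["t2d_prevalent"].mean()
        assert abs(prev - 0.083) < 3 * np.sqrt(0.083 * 0.917 / 10_000)

    def test_default_incidence_calibration(self, big_cohort):
        inc = big_cohort.cohort["t2d_incident"].mean()
        assert abs(inc - 0.053) < 3 * np.sqrt(0.053 * 0.947 / 10_000)

    def test_calibrate_onset_reproduces_frozen_defaults(self):
        scale, shape = calibrate_onset()
        assert scale == pytest.approx(DEFAULT_ONSET_SCALE, rel=1e-6)
        assert shape == pytest.approx(DEFAULT_ONSET_SHAPE, rel=1e-6)


class TestFollowup:
    def test_no_competing_events_end_at_onset_or_admin(self, rng):
        cfg = default_config(death_hazard=0.0, censor_hazard=0.0)
        age = np.array([50.0, 50.0, 50.0])
        onset = np.array([55.0, 45.0, 300.0])  # incident, prevalent, never
        prev = onset <= age
        fu = generate_followup(age, onset, prev, cfg, rng)
        assert fu.loc[0, "followup_time"] == pytest.approx(5.0)
        assert bool(fu.loc[0, "t2d_incident"])
        assert not fu.loc[1, "t2d_incident"]  # prevalent excluded
        assert fu.loc[2, "followup_time"] == pytest.approx(cfg.followup_years)
        assert not fu["death"].any() and not fu["censored"].any()

    def test_onset_before_death_is_incident_not_death(self):
        cfg = default_config(death_hazard=5.0)  # death almost surely first
        rng_a = np.random.default_rng(0)
        age = np.full(2000, 60.0)
        onset = np.full(2000, 60.5)
        fu = generate_followup(age, onset, onset <= age, cfg, rng_a)
        inc = fu["t2d_incident"]
        assert not (inc & fu["death"]).any()
        assert np.allclose(fu.loc[inc, "followup_time"], 0.5)

    def test_prevalent_and_incident_mutually_exclusive(self, big_cohort):
        c = big_cohort.cohort
        assert not (c["t2d_prevalent"] & c["t2d_incident"]).any()

    def test_negative_duration_rejected(self, rng):
        cfg = default_config()
        cfg.followup_years = -1
        with pytest.raises(ValueError):
            generate_followup(np.array([50.0]), np.array([60.0]), np.array([False]), cfg, rng)


class TestFamilyHistory:
    def test_unaffected_when_onset_beyond_current_age(self, rng):
        fh = derive_family_history(
            ["P1", "P1"], ["father", "mother"],
            onset_ages=[200.0, 150.0], current_ages=[80.0, 80.0],
            recall_unknown_prob=0.0, rng=rng,
        )
        assert not fh["affected"].any()
        assert fh["onset_category"].isna().all()

    def test_onset_at_55_is_early_category(self, rng):
        fh = derive_family_history(
            ["P1"], ["father"], [55.0], [80.0], recall_unknown_prob=0.0, rng=rng
        )
        assert fh.loc[0, "affected"] and fh.loc[0, "onset_category"] == "lt60"

    def test_onset_at_60_is_late_category(self, rng):
        fh = derive_family_history(
            ["P1"], ["father"], [60.0], [80.0], recall_unknown_prob=0.0, rng=rng
        )
        assert fh.loc[0, "onset_category"] == "ge60"

    def test_full_recall_loss_marks_all_unknown(self, rng):
        fh = derive_family_history(
            ["P1"] * 3, ["father", "mother", "sibling"],
            [50.0, 65.0, 40.0], [80.0, 80.0, 60.0],
            recall_unknown_prob=1.0, rng=rng,
        )
        assert (fh["onset_category"] == "unknown").all()


class TestDeterminismAndIO:
    def test_same_seed_gives_bit_identical_tables(self):
        cfg = default_config(n_families=300, n_variants=10)
        a = simulate_cohort(cfg, seed=5)
        b = simulate_cohort(cfg, seed=5)
        pd.testing.assert_frame_equal(a.cohort, b.cohort)
        pd.testing.assert_frame_equal(a.family_history, b.family_history)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)
        c = simulate_cohort(cfg, seed=6)
        assert not a.cohort["age_baseline"].equals(c.cohort["age_baseline"])

    def test_roundtrip_dosages_and_pgs(self, tmp_path):
        co = simulate_cohort(default_config(n_families=80, n_variants=12, seed=2))
        paths = write_cohort(co, tmp_path)
        from kinrisk.pgs import load_dosages, read_scoring_file

        panel = read_scoring_file(paths["scoring_file"])
        dosages, report = load_dosages(paths["vcf"], panel)
        assert report.n_missing == 0
        pd.testing.assert_frame_equal(
            dosages.loc[co.dosages.index].astype(float),
            co.dosages.astype(float),
            check_names=False, check_column_type=False,
        )
        scores = compute_scores(panel, dosages).set_index("person_id")
        truth = co.truth.set_index("person_id").loc[scores.index, "true_pgs"]
        assert np.abs(scores["raw_score"] - truth).max() < 1e-9

    def test_cohort_table_roundtrip(self, tmp_path):
        co = simulate_cohort(default_config(n_families=50, n_variants=5, seed=2))
        paths = write_cohort(co, tmp_path)
        back = kio.read_cohort_table(paths["cohort"])
        assert back["t2d_prevalent"].equals(co.cohort["t2d_prevalent"])
        np.testing.assert_allclose(back["age_baseline"], co.cohort["age_baseline"])

    def test_childless_families_still_have_two_history_rows(self, tmp_path):
        cfg = default_config(n_families=40, n_variants=5, sibling_count_dist={0: 1.0}, seed=8)
        co = simulate_cohort(cfg)
        counts = co.family_history.groupby("person_id").size()
        assert (counts == 2).all()
        paths = write_cohort(co, tmp_path)
        assert len(kio.read_family_history(paths["family_history"])) == 80


class TestScoreCoupling:
    def test_famrs_pgs_spearman_small_and_positive(self, big_cohort):
        """Family score and polygenic score share a weak positive rank
        correlation via transmitted variants (of order r^2 ~ 0.01-0.05)."""
        from kinrisk import famrs
        from kinrisk.discrimination import spearman
        from kinrisk.pgs import compute_scores

        co = big_cohort
        ages = co.cohort.set_index("person_id")["age_baseline"]
        ft = famrs.compute_famrs_table(co.family_history, ages)
        sc = compute_scores(panel_from_variants(co.variants), co.dosages)
        m = ft.merge(sc, on="person_id")
        res = spearman(m["score"], m["raw_score"])
        assert res.spearman_rho > 0
        assert res.p_value < 0.05
        assert 0 < res.rho_squared < 0.1
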