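import numpy as np
import pytest

from kinrisk.simulate import default_config, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def big_cohort():
    """One large default-configuration cohort shared by calibration tests."""
    return simulate_cohort(default_config(n_families=10_000, seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort for model-grid and pipeline-adjacent tests."""
    return simulate_cohort(default_config(n_families=600, n_variants=25, seed=42))


def panel_from_variants(variants):
    from kinrisk.pgs import ScoreVariant

    return [
        ScoreVariant(
            r.variant_id, r.chromosome, r.position,
            r.effect_allele, r.other_allele, r.effect_weight,
        )
        for r in variants.itertuples(index=False)
    ]


@pytest.fixture(scope="session")
def scored_small_cohort(small_cohort):
    """small_cohort plus its FamRS and PGS tables, ready for model fits."""
    from kinrisk import famrs
    from kinrisk.pgs import compute_scores, standardize_and_bin

    co = small_cohort
    ages = co.cohort.set_index("person_id")["age_baseline"]
    famrs_table = famrs.compute_famrs_table(co.family_history, ages)
    scores = standardize_and_bin(compute_scores(panel_from_variants(co.variants), co.dosages))
    return co, famrs_table, scores
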