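"""Liability-threshold simulator for family-structured T2D cohorts.

Each family has two founder parents (Hardy-Weinberg genotypes), one
index participant and a random number of siblings (Mendelian
transmission).  Disease risk acts through a latent standard-normal
liability

    L = z_PGS * sqrt(h2 * pgs_capture) + G_resid + C + E

where z_PGS is the (population-)standardised polygenic score over the
simulated variant panel, G_resid the additive polygenic liability not
captured by the scored variants (transmitted as mid-parent value plus
segregation noise), C a family-shared environment component common to
all members of a family, and E unique noise.  The variance fractions
are h2*pgs_capture, h2*(1-pgs_capture), c2 and 1-h2-c2, so L has unit
variance in expectation.

Age at onset follows a Weibull proportional-hazards model,
h(t) = shape*scale*t^(shape-1) * exp(beta_L*L + beta_BMI*z_BMI + beta_PA*PA),
whose scale and shape defaults are calibrated (``calibrate_onset``) so
that ~8.3% of participants are prevalent cases at baseline and ~5.3% of
the full cohort develops incident disease over ~11 years of follow-up
with death and loss to follow-up competing.  BMI and physical activity
are weakly coupled to the shared environment C, giving adjustment
models genuine confounding to absorb.

Family history interviews are derived from the relatives' *true* onset
ages: a relative is reported affected iff onset has occurred by their
current age, with onset classed as before age 60 / at 60 or later, and
the class replaced by "age unknown" with a configurable recall
probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from . import io as kio

AGE_MIN, AGE_MAX = 35.0, 84.0

# Weibull onset parameters calibrated by calibrate_onset() under the
# remaining defaults to the target prevalence (8.3%) and incidence (5.3%).
DEFAULT_ONSET_SHAPE = 4.196368906936351
DEFAULT_ONSET_SCALE = 1.3063739852635073e-09

_STAGES = (
    "panel",
    "families",
    "founders",
    "transmit",
    "liability",
    "ages",
    "covariates",
    "onset",
    "followup",
    "recall",
)


@dataclass
class SimulationConfig:
    """All knobs of the family cohort generator (see module docstring)."""

    n_families: int = 3000
    sibling_count_dist: dict = field(
        default_factory=lambda: {0: 0.25, 1: 0.40, 2: 0.25, 3: 0.10}
    )
    n_variants: int = 50
    allele_freqs: np.ndarray | None = None
    effect_weights: np.ndarray | None = None
    h2: float = 0.40
    c2: float = 0.10
    pgs_capture: float = 0.50
    age_mean: float = 57.4
    age_sd: float = 12.9
    onset_hazard_scale: float = DEFAULT_ONSET_SCALE
    onset_hazard_shape: float = DEFAULT_ONSET_SHAPE
    liability_hazard_beta: float = 1.5
    bmi_mean: float = 27.7
    bmi_sd: float = 4.5
    bmi_shared_env_coef: float = 3.0
    bmi_hazard_beta: float = 0.25
    pa_prob: float = 0.517
    pa_shared_env_coef: float = -0.5
    pa_hazard_beta: float = -0.2
    followup_years: float = 11.0
    censor_hazard: float = 0.002
    death_hazard: float = 0.009
    parent_age_offset: float = 27.0
    sibling_age_sd: float = 4.0
    recall_unknown_prob: float = 0.2
    pgs_raw_sd: float = 0.123
    target_prevalence: float = 0.083
    target_incidence: float = 0.053
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1 or self.n_variants < 1:
            raise ValueError("need at least one family and one variant")
        if not (0 <= self.h2 < 1 and 0 <= self.c2 < 1 and self.h2 + self.c2 < 1):
            raise ValueError("require 0 <= h2, c2 and h2 + c2 < 1")
        if not (0 < self.pgs_capture <= 1):
            raise ValueError("pgs_capture must be in (0, 1]")
        probs = np.array(list(self.sibling_count_dist.values()), dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("sibling_count_dist must be a probability vector")
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, dtype=float)
            if len(f) != self.n_variants or not ((f > 0) & (f < 1)).all():
                raise ValueError("allele_freqs must be n_variants values in (0,1)")
        if self.onset_hazard_scale <= 0 or self.onset_hazard_shape <= 0:
            raise ValueError("Weibull scale and shape must be positive")
        for hz in (self.censor_hazard, self.death_hazard):
            if hz < 0:
                raise ValueError("hazards must be non-negative")
        if self.followup_years < 0:
            raise ValueError("followup_years must be non-negative")


@dataclass
class Cohort:
    """A simulated cohort: analysis tables plus ground truth for tests."""

    cohort: pd.DataFrame
    family_history: pd.DataFrame
    dosages: pd.DataFrame
    variants: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def default_config(**overrides) -> SimulationConfig:
    return replace(SimulationConfig(), **overrides)


def _stage_rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(s) for name, s in zip(_STAGES, children)}


def simulate_founders(config: SimulationConfig, rng: np.random.Generator):
    """Hardy-Weinberg founder genotypes: dosage ~ Binomial(2, freq) per variant."""
    freqs = config.allele_freqs
    if freqs is None or len(np.atleast_1d(freqs)) == 0:
        raise ValueError("founder draw requires a non-empty allele_freqs panel")
    freqs = np.asarray(freqs, dtype=float)
    shape = (config.n_families, len(freqs))
    father = rng.binomial(2, freqs, size=shape)
    mother = rng.binomial(2, freqs, size=shape)
    return father, mother


def mate_and_transmit(father, mother, rng: np.random.Generator) -> np.ndarray:
    """Mendelian transmission: each parent passes one allele per variant.

    A heterozygote (dosage 1) transmits the alternate allele with
    probability 1/2; homozygotes transmit deterministically, i.e. the
    transmitted allele is Bernoulli(dosage/2).
    """
    father = np.asarray(father)
    mother = np.asarray(mother)
    for d in (father, mother):
        if not np.array_equal(d, np.round(d)) or d.min() < 0 or d.max() > 2:
            raise ValueError("parental dosages must be integers in {0, 1, 2}")
    return rng.binomial(1, father / 2.0) + rng.binomial(1, mother / 2.0)


def assign_liability(
    z_pgs,
    family_c,
    config: SimulationConfig,
    rng: np.random.Generator,
    g_resid=None,
):
    """Compose liabilities L = z_pgs*sqrt(h2*pc) + G_resid + C + E.

    ``g_resid`` may be supplied (e.g. mid-parent + segregation for
    offspring); when None it is drawn N(0, h2*(1-pgs_capture)).  Returns
    (L, g_resid, e_unique).
    """
    if config.h2 + config.c2 >= 1:
        raise ValueError("h2 + c2 must be < 1")
    z_pgs = np.asarray(z_pgs, dtype=float)
    n = z_pgs.shape[0]
    var_g = config.h2 * (1 - config.pgs_capture)
    if g_resid is None:
        g_resid = rng.normal(0.0, math.sqrt(var_g), n) if var_g > 0 else np.zeros(n)
    e = rng.normal(0.0, math.sqrt(1 - config.h2 - config.c2), n)
    lam = math.sqrt(config.h2 * config.pgs_capture)
    return z_pgs * lam + g_resid + np.asarray(family_c) + e, g_resid, e


def onset_from_liability(
    liability,
    config: SimulationConfig,
    rng: np.random.Generator,
    extra_eta=0.0,
) -> np.ndarray:
    """Draw Weibull proportional-hazards onset ages.

    The hazard at age t is shape*scale*t^(shape-1)*exp(beta_L*L + extra),
    so T = (-ln U / (scale*exp(eta)))^(1/shape).  Onset ages are finite
    but can exceed any attainable age; "no onset" is onset beyond the
    lifespan of interest.
    """
    if config.onset_hazard_scale <= 0 or config.onset_hazard_shape <= 0:
        raise ValueError("Weibull scale and shape must be positive")
    liability = np.asarray(liability, dtype=float)
    eta = config.liability_hazard_beta * liability + extra_eta
    u = rng.random(liability.shape)
    with np.errstate(divide="ignore", over="ignore"):
        t = (-np.log(u) / (config.onset_hazard_scale * np.exp(eta))) ** (
            1.0 / config.onset_hazard_shape
        )
    return t


def _exp_times(rate: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, n)


def generate_followup(
    age_baseline,
    onset_age,
    prevalent,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Observe follow-up: min(onset, death, loss, administrative end).

    Incident disease requires onset strictly first among the baseline
    disease-free; prevalent cases never enter the incident risk set.
    Ties (probability zero under continuous hazards) resolve in favour
    of onset, then death, then loss.
    """
    age_baseline = np.asarray(age_baseline, dtype=float)
    onset_age = np.asarray(onset_age, dtype=float)
    prevalent = np.asarray(prevalent, dtype=bool)
    if config.followup_years < 0:
        raise ValueError("followup duration must be non-negative")
    n = len(age_baseline)
    t_onset = np.where(prevalent, np.inf, onset_age - age_baseline)
    if (t_onset[~prevalent] < 0).any():
        raise ValueError("non-prevalent person with onset before baseline")
    t_death = _exp_times(config.death_hazard, n, rng)
    t_cens = _exp_times(config.censor_hazard, n, rng)
    t_admin = config.followup_years
    followup = np.minimum.reduce([t_onset, t_death, t_cens, np.full(n, t_admin)])
    incident = (~prevalent) & (t_onset <= followup)
    death = (~incident) & (t_death <= followup)
    censored = (~incident) & (~death) & (t_cens <= followup) & (t_cens < t_admin)
    return pd.DataFrame(
        {
            "followup_time": followup,
            "t2d_incident": incident,
            "death": death,
            "censored": censored,
        }
    )


def derive_family_history(
    person_ids,
    relations,
    onset_ages,
    current_ages,
    recall_unknown_prob: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Turn relatives' true onsets into interview records.

    A relative is affected iff their onset age does not exceed their
    current age; the onset category (lt60 / ge60) is replaced by
    "unknown" with probability ``recall_unknown_prob``.
    """
    onset_ages = np.asarray(onset_ages, dtype=float)
    current_ages = np.asarray(current_ages, dtype=float)
    affected = onset_ages <= current_ages
    cat = np.where(onset_ages < 60.0, "lt60", "ge60").astype(object)
    forget = rng.random(len(onset_ages)) < recall_unknown_prob
    cat[forget] = "unknown"
    cat[~affected] = None
    return pd.DataFrame(
        {
            "person_id": person_ids,
            "relation": relations,
            "affected": affected,
            "onset_category": cat,
        }
    )


def _draw_ages(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    a = (AGE_MIN - config.age_mean) / config.age_sd
    b = (AGE_MAX - config.age_mean) / config.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )


def _default_panel(config: SimulationConfig, rng: np.random.Generator):
    """Allele frequencies, weights (scaled to the target raw-score sd) and
    variant metadata for the simulated panel."""
    m = config.n_variants
    freqs = (
        np.asarray(config.allele_freqs, dtype=float)
        if config.allele_freqs is not None
        else rng.uniform(0.05, 0.5, m)
    )
    if config.effect_weights is not None:
        weights = np.asarray(config.effect_weights, dtype=float)
        if len(weights) != m:
            raise ValueError("effect_weights length must equal n_variants")
    else:
        weights = rng.normal(0.0, 1.0, m)
        raw_var = float((2 * freqs * (1 - freqs)) @ weights**2)
        weights *= config.pgs_raw_sd / math.sqrt(raw_var)
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    ref_alt = [alleles[j % len(alleles)] for j in range(m)]
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1}" for j in range(m)],
            "chromosome": ["1"] * m,
            "position": [10_000 * (j + 1) for j in range(m)],
            "effect_allele": [a[1] for a in ref_alt],
            "other_allele": [a[0] for a in ref_alt],
            "effect_weight": weights,
            "allele_freq": freqs,
        }
    )
    return freqs, weights, variants


def simulate_cohort(config: SimulationConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a full family cohort under ``config`` (deterministic per seed)."""
    config = config if config is not None else default_config()
    config.validate()
    rngs = _stage_rngs(config.seed if seed is None else seed)
    nf = config.n_families

    freqs, weights, variants = _default_panel(config, rngs["panel"])
    cfg = replace(config, allele_freqs=freqs, effect_weights=weights)

    father_d, mother_d = simulate_founders(cfg, rngs["founders"])
    sib_ks = np.array(list(cfg.sibling_count_dist.keys()))
    sib_ps = np.array(list(cfg.sibling_count_dist.values()), dtype=float)
    sib_counts = rngs["families"].choice(sib_ks, size=nf, p=sib_ps)
    n_children = 1 + sib_counts
    child_fam = np.repeat(np.arange(nf), n_children)
    child_d = mate_and_transmit(father_d[child_fam], mother_d[child_fam], rngs["transmit"])

    # person layout: fathers [0:nf], mothers [nf:2nf], children [2nf:]
    fam_of = np.concatenate([np.arange(nf), np.arange(nf), child_fam])
    dosages = np.vstack([father_d, mother_d, child_d])
    n_people = len(fam_of)
    child0 = 2 * nf + np.concatenate([[0], np.cumsum(n_children)[:-1]])
    is_index = np.zeros(n_people, dtype=bool)
    is_index[child0] = True

    roles = np.array(
        ["father"] * nf + ["mother"] * nf + ["sibling"] * (n_people - 2 * nf),
        dtype=object,
    )
    roles[child0] = "index"
    sib_no = np.zeros(n_people, dtype=int)
    pos_in_fam = np.concatenate([np.arange(k) for k in n_children]) if nf else np.array([])
    roles_children = roles[2 * nf:]
    sib_no[2 * nf:] = np.where(roles_children == "sibling", pos_in_fam, 0)
    person_ids = np.array(
        [
            f"F{fam_of[i]:05d}_{roles[i]}" + (f"{sib_no[i]}" if roles[i] == "sibling" else "")
            for i in range(n_people)
        ],
        dtype=object,
    )

    # liability components
    pgs_mu = float(2 * freqs @ weights)
    pgs_sd = math.sqrt(float((2 * freqs * (1 - freqs)) @ weights**2))
    true_pgs = dosages @ weights
    z_pgs = (true_pgs - pgs_mu) / pgs_sd

    rl = rngs["liability"]
    c_fam = rl.normal(0.0, math.sqrt(cfg.c2), nf) if cfg.c2 > 0 else np.zeros(nf)
    var_g = cfg.h2 * (1 - cfg.pgs_capture)
    g_parents = rl.normal(0.0, math.sqrt(var_g), 2 * nf) if var_g > 0 else np.zeros(2 * nf)
    g_mid = (g_parents[:nf][child_fam] + g_parents[nf:][child_fam]) / 2.0
    g_children = g_mid + (
        rl.normal(0.0, math.sqrt(var_g / 2.0), len(child_fam)) if var_g > 0 else 0.0
    )
    g_resid = np.concatenate([g_parents, g_children])
    liability, _, _ = assign_liability(z_pgs, c_fam[fam_of], cfg, rl, g_resid=g_resid)

    # ages: index from the target age distribution; siblings nearby; parents offset
    ra = rngs["ages"]
    index_age = _draw_ages(cfg, ra, nf)
    ages = np.empty(n_people)
    ages[:nf] = index_age + cfg.parent_age_offset
    ages[nf : 2 * nf] = index_age + cfg.parent_age_offset
    child_ages = index_age[child_fam] + ra.normal(0.0, cfg.sibling_age_sd, len(child_fam))
    child_ages = np.clip(child_ages, 18.0, 100.0)
    child_ages[roles_children == "index"] = index_age
    ages[2 * nf:] = child_ages

    # covariates coupled to the shared environment
    rc = rngs["covariates"]
    c_person = c_fam[fam_of]
    bmi = cfg.bmi_mean + cfg.bmi_shared_env_coef * c_person + rc.normal(0, cfg.bmi_sd, n_people)
    pa = rc.random(n_people) < expit(logit(cfg.pa_prob) + cfg.pa_shared_env_coef * c_person)
    sex = np.where(rc.random(n_people) < 0.512, "F", "M")
    sex[:nf] = "M"
    sex[nf : 2 * nf] = "F"

    extra_eta = cfg.bmi_hazard_beta * (bmi - cfg.bmi_mean) / cfg.bmi_sd + cfg.pa_hazard_beta * pa
    onset = onset_from_liability(liability, cfg, rngs["onset"], extra_eta=extra_eta)
    prevalent = onset <= ages

    # follow-up for index participants only
    idx = np.flatnonzero(is_index)
    fu = generate_followup(
        ages[idx], onset[idx], prevalent[idx], cfg, rngs["followup"]
    )
    assert not (prevalent[idx] & fu["t2d_incident"].to_numpy()).any()

    age_dx = np.where(prevalent[idx], onset[idx], np.nan)
    inc = fu["t2d_incident"].to_numpy()
    age_dx = np.where(inc, ages[idx] + fu["followup_time"].to_numpy(), age_dx)
    cohort_df = pd.DataFrame(
        {
            "person_id": person_ids[idx],
            "family_id": [f"F{f:05d}" for f in fam_of[idx]],
            "sex": sex[idx],
            "age_baseline": ages[idx],
            "bmi": bmi[idx],
            "physical_activity": pa[idx],
            "t2d_prevalent": prevalent[idx],
            "t2d_incident": inc,
            "age_at_diagnosis": age_dx,
            "followup_time": fu["followup_time"].to_numpy(),
            "death": fu["death"].to_numpy(),
            "censored": fu["censored"].to_numpy(),
        }
    )

    # interview: the index person reports parents and siblings
    rel_mask = ~is_index
    rel_index_pid = person_ids[child0][fam_of[rel_mask]]
    rel_roles = np.where(roles[rel_mask] == "sibling", "sibling", roles[rel_mask])
    famhist = derive_family_history(
        rel_index_pid,
        rel_roles,
        onset[rel_mask],
        ages[rel_mask],
        cfg.recall_unknown_prob,
        rngs["recall"],
    )
    famhist = famhist.sort_values(
        ["person_id", "relation"], kind="stable"
    ).reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "person_id": person_ids,
            "family_id": fam_of,
            "role": roles,
            "age": ages,
            "true_pgs": true_pgs,
            "z_pgs": z_pgs,
            "g_resid": g_resid,
            "shared_env": c_person,
            "liability": liability,
            "onset_age": onset,
        }
    )
    dosage_df = pd.DataFrame(
        dosages[idx],
        index=pd.Index(person_ids[idx], name="person_id"),
        columns=variants["variant_id"],
    )
    return Cohort(cohort_df, famhist, dosage_df, variants, truth, cfg)


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write the cohort TSV, family-history TSV, VCF and scoring file."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(cohort.cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    paths = {
        "cohort": out / "cohort.tsv",
        "family_history": out / "family_history.tsv",
        "vcf": out / "genotypes.vcf",
        "scoring_file": out / "score_weights.tsv",
    }
    kio.write_cohort_table(cohort.cohort, paths["cohort"])
    kio.write_family_history(cohort.family_history, paths["family_history"])
    kio.write_vcf(
        cohort.dosages.index.tolist(),
        cohort.variants,
        cohort.dosages.to_numpy(),
        paths["vcf"],
    )
    kio.write_scoring_file(
        cohort.variants, paths["scoring_file"], metadata={"trait": "T2D (simulated)"}
    )
    return {k: str(v) for k, v in paths.items()}


def calibrate_onset(
    config: SimulationConfig | None = None,
    n: int = 200_000,
    seed: int = 20240915,
    shape_bounds: tuple = (1.5, 12.0),
) -> tuple[float, float]:
    """Solve Weibull (scale, shape) for the target prevalence and incidence.

    Nested root-finds on a common-random-number Monte Carlo sample of
    index-person liabilities, ages, covariates and competing death/loss
    times: the inner solve picks the scale (parametrised by the
    characteristic age t0, scale = t0^-shape) hitting
    ``target_prevalence``; the outer solve picks the shape hitting
    ``target_incidence`` (as a fraction of the full cohort).
    Deterministic given ``seed``.
    """
    c = config if config is not None else default_config()
    rng = np.random.default_rng(seed)
    c_shared = rng.normal(0.0, math.sqrt(c.c2), n) if c.c2 > 0 else np.zeros(n)
    rest = rng.normal(0.0, math.sqrt(1 - c.c2), n)
    liab = c_shared + rest
    age = _draw_ages(c, rng, n)
    bmi = c.bmi_mean + c.bmi_shared_env_coef * c_shared + rng.normal(0, c.bmi_sd, n)
    pa = rng.random(n) < expit(logit(c.pa_prob) + c.pa_shared_env_coef * c_shared)
    eta = (
        c.liability_hazard_beta * liab
        + c.bmi_hazard_beta * (bmi - c.bmi_mean) / c.bmi_sd
        + c.pa_hazard_beta * pa
    )
    u = rng.random(n)
    t_end = np.minimum.reduce(
        [
            _exp_times(c.death_hazard, n, rng),
            _exp_times(c.censor_hazard, n, rng),
            np.full(n, c.followup_years),
        ]
    )
    neg_log_u = -np.log(u)
    exp_eta = np.exp(eta)

    def rates(t0: float, shape: float):
        scale = t0 ** (-shape)
        t_onset = (neg_log_u / (scale * exp_eta)) ** (1.0 / shape)
        prev = t_onset <= age
        inc = (~prev) & (t_onset - age <= t_end)
        return prev.mean(), inc.mean()

    def t0_for(shape: float) -> float:
        return optimize.brentq(
            lambda t0: rates(t0, shape)[0] - c.target_prevalence, 40.0, 5000.0, xtol=1e-6
        )

    def inc_gap(shape: float) -> float:
        return rates(t0_for(shape), shape)[1] - c.target_incidence

    lo, hi = shape_bounds
    if inc_gap(lo) * inc_gap(hi) > 0:
        raise ValueError(
            "target incidence unattainable for any shape in "
            f"{shape_bounds} given the other parameters"
        )
    shape = optimize.brentq(inc_gap, lo, hi, xtol=1e-6)
    scale = t0_for(shape) ** (-shape)
    return scale, shape


def simulate_logistic_outcome(
    n: int,
    log_or: float,
    base_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Direct logistic generator with a *known* per-sd score log-odds ratio.

    Used for parameter-recovery studies: z ~ N(0,1) and
    logit P(y=1) = logit(base_rate) + log_or * z, so the fitted logistic
    coefficient targets exactly ``log_or``.
    """
    z = rng.normal(0.0, 1.0, n)
    p = expit(logit(base_rate) + log_or * z)
    return pd.DataFrame({"z": z, "y": rng.random(n) < p})
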