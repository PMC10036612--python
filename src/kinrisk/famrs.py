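"""Weighted family risk score (FamRS) for type 2 diabetes.

The FamRS compares the onset-weighted number of affected first-degree
relatives (parents and siblings) with the number of affected relatives
that would be *expected* given the family size and the participant's age.
Relatives diagnosed before age 60 carry more weight than relatives
diagnosed at 60 or later; relatives whose age at onset is not remembered
fall in between.  The score is the ratio

    FamRS = W_obs / E_exp

where ``W_obs`` sums the onset weights of the affected relatives and
``E_exp`` sums, over *all* reported relatives, the expected affected
weight for the participant's 10-year age band.  A family with no
affected relatives scores exactly 0; the ratio form makes the score
invariant to a joint rescaling of weights and expected risks.

Risk categories: "average" (FamRS <= 0.5), "positive" (0.5 < FamRS <= 1),
"strong positive" (1 < FamRS <= 2) and "very strong positive"
(FamRS > 2).  Because the positive group tends to be small, analyses
usually merge positive and strong positive into a single joined
category (FamRS2), with very strong positive as FamRS3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RELATIONS = ("father", "mother", "sibling")
ONSET_CATEGORIES = ("lt60", "ge60", "unknown")
CATEGORIES = ("average", "positive", "strong_positive", "very_strong_positive")
JOINED = {
    "average": "average",
    "positive": "FamRS2",
    "strong_positive": "FamRS2",
    "very_strong_positive": "FamRS3",
}

#: 10-year participant age bands covered by the expected-risk table.
AGE_BANDS = ((35, 44), (45, 54), (55, 64), (65, 74), (75, 84))

DEFAULT_ONSET_WEIGHTS = {"lt60": 2.0, "ge60": 1.0, "unknown": 1.5}

# Expected affected weight per reported relative, by participant age band.
# Relation-independent by default; every entry is overridable.
_DEFAULT_EXPECTED_BY_BAND = {35: 0.10, 45: 0.15, 55: 0.20, 65: 0.25, 75: 0.30}


def _default_expected_table() -> dict:
    return {
        (band, rel): e
        for band, e in _DEFAULT_EXPECTED_BY_BAND.items()
        for rel in RELATIONS
    }


@dataclass(frozen=True)
class RelativeRecord:
    """One first-degree relative's diabetes report from the family interview.

    ``onset_category`` is required when ``affected`` and must be absent
    otherwise ("lt60" = onset before age 60, "ge60" = at 60 or later,
    "unknown" = affected but age at onset not remembered).
    """

    relation: str
    affected: bool
    onset_category: str | None = None

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.affected:
            if self.onset_category not in ONSET_CATEGORIES:
                raise ValueError(
                    "affected relative requires onset_category in "
                    f"{ONSET_CATEGORIES}, got {self.onset_category!r}"
                )
        elif self.onset_category is not None:
            raise ValueError("onset_category only allowed for affected relatives")


@dataclass
class FamRSConfig:
    """Weights and expected-risk table driving the FamRS.

    ``onset_weight`` maps onset categories to positive weights with
    w(lt60) >= w(unknown) >= w(ge60) > 0.  ``expected_risk_table`` maps
    (age-band lower bound, relation) to the expected affected weight per
    relative, in (0, 1], non-decreasing in the participant's age band.
    """

    onset_weight: dict = field(default_factory=lambda: dict(DEFAULT_ONSET_WEIGHTS))
    expected_risk_table: dict = field(default_factory=_default_expected_table)
    category_cuts: tuple = (0.5, 1.0, 2.0)

    def validate(self) -> None:
        w = self.onset_weight
        if set(w) != set(ONSET_CATEGORIES):
            raise ValueError(f"onset_weight must have keys {ONSET_CATEGORIES}")
        if not (w["lt60"] >= w["unknown"] >= w["ge60"] > 0):
            raise ValueError("need w_lt60 >= w_unknown >= w_ge60 > 0")
        for rel in RELATIONS:
            es = [self.expected_risk_table[(b, rel)] for b, _ in AGE_BANDS]
            if any(not (0 < e <= 1) for e in es):
                raise ValueError("expected risks must lie in (0, 1]")
            if any(b < a for a, b in zip(es, es[1:])):
                raise ValueError("expected risks must be non-decreasing in age band")
        cuts = self.category_cuts
        if not (len(cuts) == 3 and cuts[0] < cuts[1] < cuts[2]):
            raise ValueError("category_cuts must be three strictly increasing values")


@dataclass(frozen=True)
class FamRSResult:
    w_obs: float
    e_exp: float
    score: float
    category: str
    category_joined: str


def age_band(age: float) -> int:
    """Return the lower bound of the 10-year band containing ``age``.

    Bands are decades [35,45), [45,55), ... with 84 included in the last.
    """
    if AGE_BANDS[0][0] <= age <= AGE_BANDS[-1][1]:
        return min(AGE_BANDS[0][0] + 10 * int((age - AGE_BANDS[0][0]) // 10), AGE_BANDS[-1][0])
    raise ValueError(
        f"participant age {age} outside the expected-risk table range "
        f"[{AGE_BANDS[0][0]}, {AGE_BANDS[-1][1]}]"
    )


def categorize_famrs(score: float, cuts: tuple = (0.5, 1.0, 2.0)) -> str:
    """Map a FamRS value to its risk category (intervals right-closed at each cut)."""
    if score < 0:
        raise ValueError("FamRS score cannot be negative")
    if score <= cuts[0]:
        return "average"
    if score <= cuts[1]:
        return "positive"
    if score <= cuts[2]:
        return "strong_positive"
    return "very_strong_positive"


def compute_famrs(
    records: list[RelativeRecord],
    participant_age: float,
    config: FamRSConfig | None = None,
) -> FamRSResult:
    """Compute the FamRS for one participant from their relatives' records.

    Raises if no relatives were reported (the expected sum would be
    undefined) or if the participant's age falls outside the table.
    """
    config = config or FamRSConfig()
    config.validate()
    if not records:
        raise ValueError("FamRS undefined for an empty relative list")
    band = age_band(participant_age)
    w_obs = sum(
        config.onset_weight[r.onset_category] for r in records if r.affected
    )
    e_exp = sum(config.expected_risk_table[(band, r.relation)] for r in records)
    score = w_obs / e_exp
    cat = categorize_famrs(score, config.category_cuts)
    return FamRSResult(w_obs, e_exp, score, cat, JOINED[cat])


def parental_history_flag(records: list[RelativeRecord]) -> bool:
    """True iff any parent is reported affected (simplified yes/no history)."""
    return any(r.affected and r.relation in ("father", "mother") for r in records)


def compute_famrs_table(
    family_history: pd.DataFrame,
    ages: pd.Series,
    config: FamRSConfig | None = None,
) -> pd.DataFrame:
    """Vectorised FamRS for a whole cohort.

    ``family_history`` uses the long TSV dialect (person_id, relation,
    affected, onset_category); ``ages`` maps person_id -> baseline age.
    Returns one row per person with W_obs, E_exp, score, category,
    category_joined and the simplified parental history flag.
    """
    config = config or FamRSConfig()
    config.validate()
    fh = family_history.copy()
    missing = set(fh["person_id"]) - set(ages.index)
    if missing:
        raise ValueError(f"no baseline age for {sorted(missing)[:5]}")
    fh["band"] = ages.reindex(fh["person_id"]).map(age_band).to_numpy()
    aff = fh["affected"].astype(bool)
    fh["w"] = np.where(
        aff, fh["onset_category"].map(config.onset_weight).fillna(0.0), 0.0
    )
    if (aff & fh["onset_category"].isna()).any():
        raise ValueError("affected relative without onset_category")
    fh["e"] = [
        config.expected_risk_table[(b, rel)]
        for b, rel in zip(fh["band"], fh["relation"])
    ]
    fh["parent_aff"] = aff & fh["relation"].isin(["father", "mother"])
    g = fh.groupby("person_id", sort=True)
    out = pd.DataFrame(
        {
            "w_obs": g["w"].sum(),
            "e_exp": g["e"].sum(),
            "parental_history": g["parent_aff"].any(),
        }
    )
    out["score"] = out["w_obs"] / out["e_exp"]
    out["category"] = [
        categorize_famrs(s, config.category_cuts) for s in out["score"]
    ]
    out["category_joined"] = out["category"].map(JOINED)
    return out.reset_index()
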