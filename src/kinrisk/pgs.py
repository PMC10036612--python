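"""Polygenic score engine: score VCF dosages against an effect-weight file.

A polygenic score (PGS) is the per-person sum of genotype dosages times
per-variant effect weights, PGS_i = sum_j d_ij * w_j, where d_ij is the
dosage (expected alternate-allele count, 0..2) oriented to the scoring
file's effect allele.  Scores are then standardised in-sample and cut
into 5% percentile groups and top-q% indicator flags (q in {20,10,5,1}),
with the remainder of the distribution as the implicit reference group.

The scoring-file dialect is the PGS-Catalog-style TSV: '#'-prefixed
metadata lines, then a header with columns rsID, chr_name, chr_position,
effect_allele, other_allele, effect_weight.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "rsID",
    "chr_name",
    "chr_position",
    "effect_allele",
    "other_allele",
    "effect_weight",
)

#: strand-ambiguous (palindromic) allele pairs, excluded from matching by default
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

TOP_QUANTILES = (20, 10, 5, 1)


@dataclass(frozen=True)
class ScoreVariant:
    """One scoring-file row: a variant and its signed effect weight."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    effect_weight: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1 (1-based)")

    @property
    def is_ambiguous(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in AMBIGUOUS_PAIRS


@dataclass
class MatchReport:
    """Per-panel accounting of how variants matched the genotype file."""

    n_panel: int = 0
    n_matched: int = 0
    excluded_ambiguous: list = field(default_factory=list)
    skipped_multiallelic: list = field(default_factory=list)
    unmatched: list = field(default_factory=list)

    @property
    def n_missing(self) -> int:
        return self.n_panel - self.n_matched


def read_scoring_file(path) -> list[ScoreVariant]:
    """Parse a PGS-Catalog-style scoring TSV into ScoreVariants.

    '#'-prefixed lines are metadata and skipped.  Duplicate variant ids,
    missing required columns and non-numeric weights raise ValueError.
    """
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: no scoring rows (comment headers only)")
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: no scoring rows (comment headers only)")
    dupes = df["rsID"][df["rsID"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate variant id(s) {dupes}")
    try:
        weights = df["effect_weight"].astype(float)
        positions = df["chr_position"].astype(int)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric weight or position: {exc}") from exc
    return [
        ScoreVariant(r.rsID, str(r.chr_name), int(p), r.effect_allele, r.other_allele, float(w))
        for r, p, w in zip(df.itertuples(index=False), positions, weights)
    ]


def _dosage_from_record(variant, n_samples: int) -> np.ndarray:
    """ALT-allele dosage per sample: DS field preferred, GT fallback."""
    try:
        ds = variant.format("DS")
    except KeyError:
        ds = None
    if ds is not None:
        return np.asarray(ds, dtype=float).reshape(n_samples)
    # GT fallback: count ALT alleles, missing -> nan
    gts = np.asarray(variant.genotypes, dtype=int)[:, :2]
    d = (gts == 1).sum(axis=1).astype(float)
    d[(gts < 0).any(axis=1)] = np.nan
    return d


def load_dosages(
    vcf_path,
    panel: list[ScoreVariant],
    keep_ambiguous: bool = False,
) -> tuple[pd.DataFrame, MatchReport]:
    """Read a VCF and return effect-allele dosages for every panel variant.

    Matching is exact on chromosome + position + allele pair.  When the
    panel's effect/other alleles are swapped relative to REF/ALT the
    dosage is flipped to 2 - d, so scores are invariant to the VCF's
    allele orientation.  Strand-ambiguous (A/T, C/G) panel variants are
    excluded unless ``keep_ambiguous``; multiallelic records are skipped
    with a warning.  Unmatched panel variants appear as NaN columns.
    """
    from cyvcf2 import VCF

    report = MatchReport(n_panel=len(panel))
    by_pos: dict[tuple, list[ScoreVariant]] = {}
    for v in panel:
        by_pos.setdefault((v.chromosome, v.position), []).append(v)

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    n = len(samples)
    data = {v.variant_id: np.full(n, np.nan) for v in panel}
    matched: set[str] = set()
    for rec in vcf:
        key = (str(rec.CHROM), rec.POS)
        if key not in by_pos:
            continue
        if len(rec.ALT) != 1:
            warnings.warn(f"multiallelic record at {key} skipped")
            report.skipped_multiallelic.append(key)
            continue
        ref, alt = rec.REF, rec.ALT[0]
        for v in by_pos[key]:
            if v.is_ambiguous and not keep_ambiguous:
                continue
            if (v.effect_allele, v.other_allele) == (alt, ref):
                flip = False
            elif (v.effect_allele, v.other_allele) == (ref, alt):
                flip = True
            else:
                continue
            d = _dosage_from_record(rec, n)
            data[v.variant_id] = 2.0 - d if flip else d
            matched.add(v.variant_id)
    vcf.close()
    for v in panel:
        if v.variant_id in matched:
            report.n_matched += 1
        elif v.is_ambiguous and not keep_ambiguous:
            report.excluded_ambiguous.append(v.variant_id)
        else:
            report.unmatched.append(v.variant_id)
    dosages = pd.DataFrame(data, index=pd.Index(samples, name="person_id"))
    return dosages, report


def compute_scores(
    panel: list[ScoreVariant],
    dosages: pd.DataFrame,
    missing_policy: str = "zero",
    allele_freqs: dict | None = None,
) -> pd.DataFrame:
    """Raw PGS per person: sum over matched variants of dosage x weight.

    ``dosages`` is persons x variant_id with NaN for missing variants.
    Missing policy "zero" drops the term, "mean_impute" substitutes the
    Hardy-Weinberg mean dosage 2f (requires ``allele_freqs``), and
    "require_any" errors for persons with no matched variant at all.
    """
    if missing_policy not in ("zero", "mean_impute", "require_any"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    ids = [v.variant_id for v in panel]
    unknown = set(ids) - set(dosages.columns)
    if unknown:
        raise ValueError(f"dosage matrix lacks panel variant(s) {sorted(unknown)[:5]}")
    d = dosages[ids].to_numpy(dtype=float)
    w = np.array([v.effect_weight for v in panel])
    miss = np.isnan(d)
    n_missing = miss.sum(axis=1)
    if missing_policy == "require_any" and (n_missing == len(panel)).any():
        bad = dosages.index[n_missing == len(panel)].tolist()
        raise ValueError(f"no matched variants for person(s) {bad[:5]}")
    filled = d.copy()
    if missing_policy == "mean_impute":
        if allele_freqs is None:
            raise ValueError("mean_impute requires allele_freqs")
        means = np.array([2.0 * allele_freqs[v.variant_id] for v in panel])
        filled[miss] = np.broadcast_to(means, d.shape)[miss]
    else:
        filled[miss] = 0.0
    return pd.DataFrame(
        {
            "person_id": dosages.index,
            "raw_score": filled @ w,
            "n_matched": len(panel) - n_missing,
            "n_missing": n_missing,
        }
    ).reset_index(drop=True)


def standardize_and_bin(scores: pd.DataFrame, score_col: str = "raw_score") -> pd.DataFrame:
    """Add z-scores, 5% percentile groups and top-q% flags in-sample.

    z uses the in-sample mean and sd (n-1 denominator).  Percentile
    group b (1..20) holds rank fractions in ((b-1)/20, b/20]; the top-q%
    flag marks ranks strictly above the empirical (100-q)th percentile.
    Ties are broken by stable input order, so results are deterministic.
    """
    out = scores.copy()
    x = out[score_col].to_numpy(dtype=float)
    n = len(x)
    if n < 20:
        raise ValueError(f"need >= 20 individuals for 5% bins, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero score variance; cannot standardise")
    out["z_score"] = (x - x.mean()) / sd
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    frac = ranks / n
    out["percentile_group"] = np.ceil(frac * 20).astype(int)
    for q in TOP_QUANTILES:
        out[f"top{q}"] = frac > 1 - q / 100
    return out


def score_vcf(
    vcf_path,
    scoring_path,
    missing_policy: str = "zero",
    keep_ambiguous: bool = False,
) -> tuple[pd.DataFrame, MatchReport]:
    """End-to-end: scoring file + VCF -> standardised, binned PGS table."""
    panel = read_scoring_file(scoring_path)
    dosages, report = load_dosages(vcf_path, panel, keep_ambiguous=keep_ambiguous)
    scores = compute_scores(panel, dosages, missing_policy=missing_policy)
    return standardize_and_bin(scores), report
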