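"""File dialects shared across the pipeline.

Plain-text formats only: tab-separated cohort / family-history / score
tables, VCF v4.2 with a DS (dosage) FORMAT field, and the
PGS-Catalog-style scoring TSV.  Booleans are stored as 0/1; missing
ages as empty fields.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COHORT_COLUMNS = [
    "person_id",
    "sex",
    "age_baseline",
    "bmi",
    "physical_activity",
    "t2d_prevalent",
    "t2d_incident",
    "age_at_diagnosis",
    "followup_time",
    "death",
    "censored",
]
_COHORT_BOOL = ["physical_activity", "t2d_prevalent", "t2d_incident", "death", "censored"]

FAMHIST_COLUMNS = ["person_id", "relation", "affected", "onset_category"]


def write_cohort_table(df: pd.DataFrame, path) -> None:
    out = df[COHORT_COLUMNS].copy()
    for c in _COHORT_BOOL:
        out[c] = out[c].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"person_id": str, "sex": str})
    for c in _COHORT_BOOL:
        df[c] = df[c].astype(bool)
    return df


def write_family_history(df: pd.DataFrame, path) -> None:
    out = df[FAMHIST_COLUMNS].copy()
    out["affected"] = out["affected"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_family_history(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"person_id": str, "onset_category": str})
    df["affected"] = df["affected"].astype(bool)
    df["onset_category"] = df["onset_category"].where(df["onset_category"].notna(), None)
    return df


def write_scoring_file(variants: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a PGS-Catalog-style scoring TSV ('#' metadata, then header).

    ``variants`` needs columns variant_id, chromosome, position,
    effect_allele, other_allele, effect_weight.
    """
    with open(path, "w") as fh:
        fh.write("### kinrisk scoring file\n")
        for k, v in (metadata or {}).items():
            fh.write(f"#{k}={v}\n")
        fh.write("rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n")
        for r in variants.itertuples(index=False):
            fh.write(
                f"{r.variant_id}\t{r.chromosome}\t{r.position}\t"
                f"{r.effect_allele}\t{r.other_allele}\t{r.effect_weight!r}\n"
            )


def write_vcf(
    sample_ids,
    variants: pd.DataFrame,
    dosages: np.ndarray,
    path,
    with_gt: bool = False,
) -> None:
    """Write a minimal VCF v4.2 with per-sample DS dosages (GT optional).

    ``dosages`` is samples x variants, aligned with ``sample_ids`` and the
    rows of ``variants`` (columns variant_id, chromosome, position,
    effect_allele (ALT), other_allele (REF)).
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.shape != (len(sample_ids), len(variants)):
        raise ValueError("dosage matrix shape does not match samples x variants")
    fmt = "GT:DS" if with_gt else "DS"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        if with_gt:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(variants["chromosome"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in sample_ids)
            + "\n"
        )
        for j, r in enumerate(variants.itertuples(index=False)):
            cells = []
            for d in dosages[:, j]:
                ds = f"{d:.6g}"
                if with_gt:
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(round(d)), "./.")
                    cells.append(f"{gt}:{ds}")
                else:
                    cells.append(ds)
            fh.write(
                f"{r.chromosome}\t{r.position}\t{r.variant_id}\t"
                f"{r.other_allele}\t{r.effect_allele}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )
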