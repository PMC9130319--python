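"""File I/O: weight tables, genotypes (VCF / PLINK-RAW), phenotypes, exposure
distributions.

Formats are the field's plain-text interchange conventions:

* weight table — TSV with header ``rsid chrom pos effect_allele other_allele
  weight eaf locus source_n source_p``;
* genotypes — either a VCF (unphased GT, dosage = count of the ALT allele)
  or a PLINK ``--recode A``-style TSV whose score columns are named
  ``rsID_countedallele`` with values 0/1/2/NA;
* phenotypes — CSV, one row per participant, with smoking status,
  pack-years, covariates, follow-up time and the 0/1 event indicator;
* exposure distributions — TSV with ``level proportion source`` rows.

Round trips are bit-exact for integers and strings and stable to 1e-12 for
floats (written with 17 significant digits).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .paf import ExposureDistribution
from .prs import GenotypeMatrix, ValidationError, VariantWeight

def FLOAT_FMT(value) -> str:  # shortest exact round-trip representation
    return repr(float(value))

WEIGHT_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "weight", "eaf", "locus", "source_n", "source_p",
]

PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_weight_table(panel: Sequence[VariantWeight], path: str | Path) -> None:
    rows = [dataclasses.asdict(v) for v in panel]
    df = pd.DataFrame(rows)[WEIGHT_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_weight_table(path: str | Path) -> list[VariantWeight]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "locus": str})
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: weight table lacks columns {missing}")
    panel = []
    for i, row in df.iterrows():
        try:
            panel.append(
                VariantWeight(
                    rsid=str(row["rsid"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    effect_allele=str(row["effect_allele"]),
                    other_allele=str(row["other_allele"]),
                    weight=float(row["weight"]),
                    eaf=float(row["eaf"]),
                    locus="" if pd.isna(row["locus"]) else str(row["locus"]),
                    source_n=int(row["source_n"]),
                    source_p=float(row["source_p"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {i + 2}: {exc}") from exc
    return panel


# ---------------------------------------------------------------------------
# genotypes

def write_vcf(gm: GenotypeMatrix, path: str | Path, panel: Sequence[VariantWeight]) -> None:
    """Minimal VCF 4.2 with unphased GT; ALT is the counted (effect) allele."""
    pos_of = {v.rsid: v for v in panel}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, rsid in enumerate(gm.rsids):
            v = pos_of[rsid]
            col = gm.dosages[:, j]
            gts = [
                "./." if np.isnan(g) else gt_codes[int(round(g))] for g in col
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{rsid}\t{v.other_allele}\t{v.effect_allele}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read unphased GT dosages; the counted allele is ALT, other is REF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rsids, counted, other, rows = [], [], [], []
    for var in vcf:
        rsids.append(var.ID or f"{var.CHROM}:{var.POS}")
        counted.append(var.ALT[0])
        other.append(var.REF)
        gts = np.asarray([g[:2] for g in var.genotypes])  # (n, 2) allele codes
        dose = np.where((gts < 0).any(axis=1), np.nan, (gts > 0).sum(axis=1)).astype(float)
        rows.append(dose)
    vcf.close()
    dosages = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, rsids, dosages, counted, other)


def write_plink_raw(gm: GenotypeMatrix, path: str | Path) -> None:
    """PLINK --recode A dialect: meta columns then rsID_countedallele 0/1/2."""
    if gm.counted_alleles is None:
        raise ValidationError("PLINK-RAW export needs counted alleles")
    df = pd.DataFrame(
        {
            "FID": gm.sample_ids,
            "IID": gm.sample_ids,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": -9,
        }
    )
    for j, rsid in enumerate(gm.rsids):
        col = gm.dosages[:, j]
        df[f"{rsid}_{gm.counted_alleles[j]}"] = [
            "NA" if np.isnan(g) else int(round(g)) for g in col
        ]
    df.to_csv(path, sep=" ", index=False)


def read_plink_raw(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    missing = [c for c in PLINK_META if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: PLINK-RAW header lacks {missing}")
    score_cols = [c for c in df.columns if c not in PLINK_META]
    rsids, counted = [], []
    for c in score_cols:
        if "_" not in c:
            raise ValidationError(f"{path}: column {c!r} is not rsID_allele formatted")
        rsid, allele = c.rsplit("_", 1)
        rsids.append(rsid)
        counted.append(allele)
    dosages = df[score_cols].to_numpy(dtype=float)
    return GenotypeMatrix(
        [str(s) for s in df["IID"]], rsids, dosages, counted, None
    )


# ---------------------------------------------------------------------------
# phenotypes and scores

REQUIRED_PHENOTYPE_COLUMNS = [
    "sample_id", "smoking_status", "pack_years", "follow_up_years", "event",
]


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: phenotype file lacks columns {missing}")
    bad_time = df.index[df["follow_up_years"] <= 0]
    if len(bad_time):
        raise ValidationError(
            f"{path}: non-positive follow-up time at data row(s) {list(bad_time[:5] + 2)}"
        )
    bad_event = df.index[~df["event"].isin([0, 1])]
    if len(bad_event):
        raise ValidationError(
            f"{path}: event indicator outside 0/1 at data row(s) {list(bad_event[:5] + 2)}"
        )
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample IDs")
    return df


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    out = scores.reset_index(names="sample_id")
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("sample_id")


# ---------------------------------------------------------------------------
# exposure distributions

def write_exposure_distributions(
    dists: Sequence[ExposureDistribution], path: str | Path
) -> None:
    rows = [
        {"level": lv, "proportion": p, "source": d.source, "reference": d.reference}
        for d in dists
        for lv, p in zip(d.levels, d.proportions)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_exposure_distributions(path: str | Path) -> dict[str, ExposureDistribution]:
    df = pd.read_csv(path, sep="\t")
    for col in ("level", "proportion", "source", "reference"):
        if col not in df.columns:
            raise ValidationError(f"{path}: exposure table lacks column {col!r}")
    out = {}
    for src, sub in df.groupby("source", sort=True):
        ref = sub["reference"].iloc[0]
        out[str(src)] = ExposureDistribution(
            tuple(sub["level"].astype(str)),
            tuple(sub["proportion"].astype(float)),
            str(ref),
            str(src),
        )
    return out
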