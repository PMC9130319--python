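"""Polygenic risk score construction and categorisation.

A polygenic risk score (PRS) aggregates many common variants of individually
small effect into a single additive predictor: for participant *i*,

    S_i = sum_j w_j * g_ij

where ``g_ij`` in ``[0, 2]`` is the dosage of the effect allele at variant *j*
and ``w_j`` the per-allele log-scale effect size taken from an external
development GWAS.  Scores are z-standardised over the analysis cohort and cut
into quintiles; the lowest quintile is the *low* genetic-risk category,
quintiles 2-4 *intermediate*, and the top quintile *high*.

This module covers panel selection (one independent variant per locus by
development-cohort sample size and p-value), harmonisation of genotype files
to the panel's effect alleles (strand flips, allele swaps, palindromic-SNP
exclusion, mean imputation of missing dosages), scoring, standardisation and
categorisation, plus the smoking-exposure categorisation used alongside the
genetic categories.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_BASES = frozenset(_COMPLEMENT)

GENETIC_RISK_LEVELS = ("low", "intermediate", "high")
SMOKING_STATUS_LEVELS = ("never", "former", "current")
PACKYEAR_LEVELS = ("no", "light", "intermediate", "heavy")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclasses.dataclass(frozen=True)
class VariantWeight:
    """One scored variant: alleles, per-allele effect size and frequency.

    ``weight`` is the per-allele effect size on the log scale (log odds ratio
    or log hazard ratio from the development GWAS, dimensionless); ``eaf`` is
    the effect-allele frequency in the source population, strictly inside
    (0, 1).  ``locus`` groups variants in linkage disequilibrium so panel
    selection can keep exactly one per locus; ``source_n``/``source_p`` are
    the development-cohort sample size and association p-value used by the
    selection rule.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    weight: float
    eaf: float
    locus: str = ""
    source_n: int = 0
    source_p: float = 1.0
    available: bool = True

    def __post_init__(self) -> None:
        for name in ("effect_allele", "other_allele"):
            a = getattr(self, name)
            if a not in _BASES:
                raise ValidationError(
                    f"{self.rsid}: {name} {a!r} is not a single base A/C/G/T"
                )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if not (0.0 < self.eaf < 1.0):
            raise ValidationError(
                f"{self.rsid}: effect-allele frequency {self.eaf} outside (0, 1)"
            )
        if not math.isfinite(self.weight):
            raise ValidationError(f"{self.rsid}: weight is not finite")
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: position must be 1-based positive")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous A/T and C/G variants."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def effective_locus(self) -> str:
        return self.locus if self.locus else self.rsid


@dataclasses.dataclass
class GenotypeMatrix:
    """Additive effect-allele dosages, samples x variants.

    ``dosages`` is float with NaN marking missing calls; non-missing entries
    lie in [0, 2].  ``counted_alleles``/``other_alleles`` record, per variant,
    which allele the dosage counts (needed for harmonisation from files).
    """

    sample_ids: list[str]
    rsids: list[str]
    dosages: np.ndarray
    counted_alleles: list[str] | None = None
    other_alleles: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.rsids):
            raise ValidationError(
                f"dosage matrix {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.rsids)} variants"
            )
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError("dosages must lie in [0, 2] or be missing (NaN)")
        for name in ("counted_alleles", "other_alleles"):
            alleles = getattr(self, name)
            if alleles is not None and len(alleles) != m:
                raise ValidationError(f"{name} length does not match variant count")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_rate(self) -> np.ndarray:
        """Per-variant fraction of missing dosages."""
        return np.isnan(self.dosages).mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.rsids)


def _chrom_key(chrom: str):
    m = re.fullmatch(r"(?:chr)?(\d+)", str(chrom))
    return (0, int(m.group(1)), "") if m else (1, 0, str(chrom))


def select_variants(catalog: Sequence[VariantWeight]) -> list[VariantWeight]:
    """Apply the panel-selection rule to a variant catalog.

    Keeps common (MAF > 0.01), available variants and, within each locus /
    LD group, exactly one variant: the one with the largest development-cohort
    sample size, ties broken by smallest p-value, then lexicographic rsID.
    Returns the panel sorted by (chromosome, position).
    """
    rsids = [v.rsid for v in catalog]
    if len(set(rsids)) != len(rsids):
        dupes = sorted({r for r in rsids if rsids.count(r) > 1})
        raise ValidationError(f"duplicate rsIDs in catalog: {', '.join(dupes)}")
    eligible = [v for v in catalog if v.available and v.maf > 0.01]
    by_locus: dict[str, list[VariantWeight]] = {}
    for v in eligible:
        by_locus.setdefault(v.effective_locus, []).append(v)
    kept = [
        min(group, key=lambda v: (-v.source_n, v.source_p, v.rsid))
        for group in by_locus.values()
    ]
    return sorted(kept, key=lambda v: (_chrom_key(v.chrom), v.pos))


def harmonize_genotypes(
    genotypes: GenotypeMatrix,
    panel: Sequence[VariantWeight],
    *,
    keep_palindromic: bool = False,
    impute_missing: bool = True,
) -> tuple[GenotypeMatrix, list[VariantWeight]]:
    """Align a genotype matrix to a panel's effect alleles.

    Output columns follow panel order and count the panel's effect allele:
    if the file counted the other allele (directly or on the opposite
    strand), the dosage is flipped to ``2 - g``.  Strand-ambiguous
    palindromic variants (A/T, C/G) are excluded by default.  Missing
    dosages are imputed as ``2 * eaf`` (the Hardy-Weinberg mean) unless
    ``impute_missing`` is False.  Panel variants absent from the file, and
    variants whose alleles cannot be reconciled, are dropped with a warning.

    Returns the harmonised matrix together with the matching panel subset
    (same variant order), ready for :func:`compute_prs`.
    """
    col_of = {r: j for j, r in enumerate(genotypes.rsids)}
    if not any(v.rsid in col_of for v in panel):
        raise ValidationError("no rsID overlap between genotypes and panel")
    counted = genotypes.counted_alleles
    other = genotypes.other_alleles

    cols: list[np.ndarray] = []
    kept_panel: list[VariantWeight] = []
    for v in panel:
        if v.rsid not in col_of:
            log.warning("panel variant %s absent from genotype file; dropped", v.rsid)
            continue
        if v.is_palindromic and not keep_palindromic:
            log.warning(
                "palindromic variant %s (%s/%s) excluded from scoring",
                v.rsid, v.effect_allele, v.other_allele,
            )
            continue
        j = col_of[v.rsid]
        g = genotypes.dosages[:, j].astype(float).copy()
        if counted is not None:
            ca = counted[j]
            oa = other[j] if other is not None else None
            flip = _orientation(v, ca, oa)
            if flip is None:
                log.warning(
                    "variant %s: file alleles (%s/%s) incompatible with panel "
                    "(%s/%s) even after strand complement; dropped",
                    v.rsid, ca, oa, v.effect_allele, v.other_allele,
                )
                continue
            if flip:
                g = 2.0 - g
        if impute_missing:
            g = np.where(np.isnan(g), 2.0 * v.eaf, g)
        cols.append(g)
        kept_panel.append(v)

    dosages = (
        np.column_stack(cols) if cols else np.empty((genotypes.n_samples, 0))
    )
    out = GenotypeMatrix(
        sample_ids=list(genotypes.sample_ids),
        rsids=[v.rsid for v in kept_panel],
        dosages=dosages,
        counted_alleles=[v.effect_allele for v in kept_panel],
        other_alleles=[v.other_allele for v in kept_panel],
    )
    return out, kept_panel


def _orientation(v: VariantWeight, counted: str, other: str | None) -> bool | None:
    """Return True if the file dosage must be flipped, False if not, None if
    the allele pair cannot be reconciled with the panel variant."""
    ea, oa = v.effect_allele, v.other_allele
    if counted == ea and other in (oa, None):
        return False
    if counted == oa and other in (ea, None):
        return True
    cc = _COMPLEMENT.get(counted)
    co = _COMPLEMENT.get(other) if other is not None else None
    if cc == ea and co in (oa, None):
        return False
    if cc == oa and co in (ea, None):
        return True
    return None


def compute_prs(genotypes: GenotypeMatrix, panel: Sequence[VariantWeight]) -> pd.Series:
    """Raw additive scores ``S_i = sum_j w_j g_ij``.

    Columns must already be aligned to the panel (same rsIDs, same order);
    use :func:`harmonize_genotypes` first for file input.  Dosages left
    missing (NaN) after harmonisation contribute nothing to the sum.
    """
    panel_rsids = [v.rsid for v in panel]
    if list(genotypes.rsids) != panel_rsids:
        raise ValidationError(
            "genotype columns are not aligned to the panel; "
            "run harmonize_genotypes first"
        )
    w = np.array([v.weight for v in panel], dtype=float)
    contrib = genotypes.dosages * w
    raw = np.nansum(contrib, axis=1) if contrib.size else np.zeros(genotypes.n_samples)
    return pd.Series(raw, index=genotypes.sample_ids, name="prs_raw")


def standardize_prs(raw: pd.Series | np.ndarray) -> pd.Series:
    """Z-standardise raw scores over the cohort (sample SD, n-1 denominator)."""
    s = pd.Series(np.asarray(raw, dtype=float)) if not isinstance(raw, pd.Series) else raw
    if len(s) < 2:
        raise ValidationError("need at least 2 scores to standardise")
    sd = s.std(ddof=1)
    if sd == 0 or not math.isfinite(sd):
        raise ValidationError("scores have zero variance; z-standardisation undefined")
    z = (s - s.mean()) / sd
    return z.rename("prs_z")


def categorize_prs(z: pd.Series) -> pd.DataFrame:
    """Assign empirical quintiles and low/intermediate/high categories.

    Quintile boundaries sit at the 20th/40th/60th/80th empirical
    percentiles; ties are broken by rank order (stable sort on value then
    position) so group sizes never differ from n/5 by more than one.
    """
    n = len(z)
    if n < 5:
        raise ValidationError("need at least 5 participants for quintiles")
    order = np.lexsort((np.arange(n), np.asarray(z, dtype=float)))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    quintile = (rank * 5) // n + 1
    category = np.where(quintile == 1, "low", np.where(quintile == 5, "high", "intermediate"))
    return pd.DataFrame(
        {"quintile": quintile, "genetic_risk": pd.Categorical(category, categories=GENETIC_RISK_LEVELS)},
        index=z.index,
    )


def score_cohort(genotypes: GenotypeMatrix, panel: Sequence[VariantWeight]) -> pd.DataFrame:
    """Convenience composition: raw score, z-score, quintile and category."""
    raw = compute_prs(genotypes, panel)
    z = standardize_prs(raw)
    cats = categorize_prs(z)
    out = pd.DataFrame({"prs_raw": raw, "prs_z": z})
    return out.join(cats)


def categorize_smoking(
    status: pd.Series | Sequence[str], pack_years: pd.Series | Sequence[float]
) -> pd.DataFrame:
    """Smoking-status and pack-year categories plus the mismatch flag.

    Pack-year bins: no (0), light (0.1-19.9), intermediate (20-39.9) and
    heavy (>= 40); edges at 20 and 40 are left-closed, matching the bin
    labels.  The mismatch flag marks participants reported as never-smokers
    but carrying positive pack-years (excludable in sensitivity analyses).
    """
    status = pd.Series(status).astype(str)
    py = pd.Series(np.asarray(pack_years, dtype=float), index=status.index)
    bad_status = sorted(set(status) - set(SMOKING_STATUS_LEVELS))
    if bad_status:
        raise ValidationError(f"unknown smoking status values: {bad_status}")
    if (py < 0).any():
        rows = list(py.index[py < 0])[:5]
        raise ValidationError(f"negative pack-years at rows {rows}")
    cat = np.full(len(py), "no", dtype=object)
    cat[py > 0] = "light"
    cat[py >= 20] = "intermediate"
    cat[py >= 40] = "heavy"
    return pd.DataFrame(
        {
            "smoking_status": pd.Categorical(status, categories=SMOKING_STATUS_LEVELS),
            "packyear_category": pd.Categorical(cat, categories=PACKYEAR_LEVELS),
            "smoking_mismatch": (status.values == "never") & (py.values > 0),
        },
        index=py.index,
    )


def default_panel(n_variants: int = 33) -> list[VariantWeight]:
    """A synthetic 33-variant panel for simulation and examples.

    This is an *emulation* of a published lung-cancer susceptibility panel
    (33 independent common SNPs spanning loci such as 5p15/TERT, 15q25/CHRNA3-5
    and 6p21), not the published table itself: rsIDs, positions, per-allele
    log odds ratios (centred near 0.1, a few protective) and effect-allele
    frequencies are generated from a fixed internal seed.  Effect sizes and
    frequencies are in the range GWAS report for common cancer variants, so
    the resulting score distribution is realistic; the weights carry no
    biological meaning.
    """
    rng = np.random.default_rng(20220222)
    chroms = [str(c) for c in (1, 3, 5, 6, 8, 9, 10, 12, 13, 15, 15, 20, 22)]
    panel: list[VariantWeight] = []
    pos_base = rng.integers(1_000_000, 90_000_000, size=n_variants)
    for j in range(n_variants):
        eaf = float(np.clip(rng.beta(2.0, 2.0), 0.05, 0.95))
        weight = float(rng.normal(0.10, 0.07))
        ea, oa = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        # avoid palindromic pairs in the default panel so every variant scores
        if _COMPLEMENT[ea] == oa:
            oa = {"A": "C", "T": "G", "C": "A", "G": "T"}[ea]
        panel.append(
            VariantWeight(
                rsid=f"rs{1_000_000 + int(rng.integers(0, 8_999_999))}",
                chrom=chroms[j % len(chroms)],
                pos=int(pos_base[j]),
                effect_allele=str(ea),
                other_allele=str(oa),
                weight=weight,
                eaf=eaf,
                locus=f"locus_{j:02d}",
                source_n=int(rng.integers(20_000, 120_000)),
                source_p=float(10.0 ** rng.uniform(-30, -8)),
            )
        )
    return sorted(panel, key=lambda v: (_chrom_key(v.chrom), v.pos))
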