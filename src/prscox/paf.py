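"""Population-attributable fractions and generalized impact fractions.

Two classical estimators are provided, clearly labelled because they answer
the "what if nobody smoked" question from different inputs:

* Miettinen's case-load form, which combines the exposure distribution
  *among cases* with (possibly covariate-adjusted) hazard ratios:

      PAF = sum_k p_ck (HR_k - 1) / HR_k

* Levin's prevalence form, which combines the *population* exposure
  distribution with the hazard ratios — and therefore also supports
  external standardisation to survey prevalences:

      PAF = (sum_k p_k HR_k - 1) / (sum_k p_k HR_k)

The generalized impact fraction replaces "everyone at reference" with an
arbitrary counterfactual distribution p*_k:

      GIF = (sum p_k HR_k - sum p*_k HR_k) / (sum p_k HR_k)

and reduces exactly to the Levin PAF when p* puts all mass on the reference.
Confidence intervals come from a parametric bootstrap that jointly resamples
log hazard ratios (multivariate normal at the Cox fit's estimate and
covariance) and exposure proportions (Dirichlet at the observed counts).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .prs import ValidationError
from .survival import CoxFit

__all__ = [
    "ExposureDistribution",
    "PAFResult",
    "paf_case_load",
    "paf_prevalence",
    "generalized_impact_fraction",
    "paf_confidence_interval",
    "stratified_paf",
]


@dataclasses.dataclass(frozen=True)
class ExposureDistribution:
    """Ordered exposure levels with proportions and a designated reference.

    ``source`` tags where the proportions come from: ``"cohort"`` (the
    analysis population), ``"cases"`` (events only; required by the
    case-load estimator) or ``"external:<name>"`` (survey standardisation).
    """

    levels: tuple[str, ...]
    proportions: tuple[float, ...]
    reference: str
    source: str = "cohort"

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if len(self.levels) != len(p):
            raise ValidationError("levels and proportions differ in length")
        if len(set(self.levels)) != len(self.levels):
            raise ValidationError("duplicate exposure levels")
        if p.min() < 0 or p.max() > 1 or abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError("proportions must lie in [0, 1] and sum to 1")
        if self.reference not in self.levels:
            raise ValidationError(f"reference level {self.reference!r} not among levels")

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, float], reference: str, source: str = "cohort"
    ) -> "ExposureDistribution":
        levels = tuple(counts)
        total = float(sum(counts.values()))
        if total <= 0:
            raise ValidationError("counts must sum to a positive total")
        return cls(levels, tuple(c / total for c in counts.values()), reference, source)

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(self.levels), name="proportion")


@dataclasses.dataclass
class PAFResult:
    """Point estimate with (optional) bootstrap percentile interval."""

    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    method: str = "prevalence"
    counterfactual: str = "all at reference"
    n_boot: int = 0
    seed: int | None = None
    flagged: str | None = None


def _check_hrs(dist: ExposureDistribution, hrs: Mapping[str, float]) -> np.ndarray:
    out = np.empty(len(dist.levels))
    for i, lv in enumerate(dist.levels):
        if lv == dist.reference:
            hr = hrs.get(lv, 1.0)
            if abs(hr - 1.0) > 1e-12:
                raise ValidationError("reference level must have HR 1")
            out[i] = 1.0
        else:
            if lv not in hrs:
                raise ValidationError(f"missing hazard ratio for level {lv!r}")
            hr = float(hrs[lv])
            if hr <= 0:
                raise ValidationError(f"hazard ratio for {lv!r} must be positive")
            out[i] = hr
    return out


def paf_case_load(case_dist: ExposureDistribution, hrs: Mapping[str, float]) -> float:
    """Miettinen case-load PAF: sum_k p_ck (HR_k - 1)/HR_k.

    ``case_dist`` must carry the exposure distribution among *cases*; the
    hazard ratios may be covariate-adjusted, which is the main reason to
    prefer this form for cohort-internal estimates.
    """
    if case_dist.source != "cases":
        raise ValidationError("case-load PAF needs the exposure distribution among cases")
    hr = _check_hrs(case_dist, hrs)
    p = np.asarray(case_dist.proportions)
    return float(np.sum(p * (hr - 1.0) / hr))


def paf_prevalence(prev: ExposureDistribution, hrs: Mapping[str, float]) -> float:
    """Levin (multi-category) PAF: (sum p_k HR_k - 1) / (sum p_k HR_k)."""
    if prev.source == "cases":
        raise ValidationError("prevalence PAF needs a cohort or external distribution")
    hr = _check_hrs(prev, hrs)
    p = np.asarray(prev.proportions)
    s = float(np.sum(p * hr))
    return (s - 1.0) / s


def generalized_impact_fraction(
    prev: ExposureDistribution,
    counterfactual: ExposureDistribution,
    hrs: Mapping[str, float],
) -> float:
    """GIF = (sum p HR - sum p* HR) / (sum p HR) for a counterfactual shift."""
    if tuple(prev.levels) != tuple(counterfactual.levels):
        raise ValidationError("factual and counterfactual distributions must share levels")
    hr = _check_hrs(prev, hrs)
    p = np.asarray(prev.proportions)
    pstar = np.asarray(counterfactual.proportions)
    s = float(np.sum(p * hr))
    return (s - float(np.sum(pstar * hr))) / s


def paf_confidence_interval(
    method: str,
    dist_counts: Mapping[str, float],
    reference: str,
    fit: CoxFit,
    hr_columns: Mapping[str, str],
    counterfactual: ExposureDistribution | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    resample_proportions: bool = True,
) -> PAFResult:
    """Parametric-bootstrap percentile interval for a PAF or GIF.

    Each replicate draws a log-HR vector from N(beta-hat, cov) and exposure
    proportions from Dirichlet(observed counts), then recomputes the chosen
    estimator (``"case_load"``, ``"prevalence"`` or ``"impact_fraction"``).
    ``hr_columns`` maps each non-reference exposure level to the fit's
    coefficient name.  Deterministic given the seed.
    """
    if n_boot < 200:
        raise ValidationError("n_boot must be >= 200")
    if method not in ("case_load", "prevalence", "impact_fraction"):
        raise ValidationError(f"unknown PAF method {method!r}")
    if method == "impact_fraction" and counterfactual is None:
        raise ValidationError("impact_fraction needs a counterfactual distribution")
    source = "cases" if method == "case_load" else "cohort"
    dist = ExposureDistribution.from_counts(dist_counts, reference, source)
    levels = list(dist.levels)
    nonref = [lv for lv in levels if lv != reference]
    for lv in nonref:
        if lv not in hr_columns:
            raise ValidationError(f"no coefficient mapped for level {lv!r}")
    cols = [hr_columns[lv] for lv in nonref]
    beta = fit.beta[cols].to_numpy()
    cov = fit.covariance.loc[cols, cols].to_numpy()
    try:
        np.linalg.cholesky(cov + 1e-15 * np.eye(len(cols)))
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular coefficient covariance: {exc}") from exc

    def estimator(d: ExposureDistribution, hrs: Mapping[str, float]) -> float:
        if method == "case_load":
            return paf_case_load(d, hrs)
        if method == "prevalence":
            return paf_prevalence(d, hrs)
        return generalized_impact_fraction(d, counterfactual, hrs)

    point = estimator(dist, {lv: float(np.exp(b)) for lv, b in zip(nonref, beta)})

    rng = np.random.default_rng(seed)
    counts = np.asarray([dist_counts[lv] for lv in levels], dtype=float)
    degenerate_cov = not np.any(cov)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        lb = beta if degenerate_cov else rng.multivariate_normal(beta, cov)
        if resample_proportions and not np.any(counts <= 0):
            props = rng.dirichlet(counts)
        else:
            props = counts / counts.sum()
        d_b = ExposureDistribution(tuple(levels), tuple(props), reference, source)
        boots[b] = estimator(d_b, {lv: float(np.exp(x)) for lv, x in zip(nonref, lb)})
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return PAFResult(
        estimate=point,
        ci_low=float(lo),
        ci_high=float(hi),
        method=method,
        counterfactual=(
            counterfactual and f"shift to {dict(zip(counterfactual.levels, counterfactual.proportions))}"
        ) or "all at reference",
        n_boot=n_boot,
        seed=seed,
    )


def stratified_paf(
    data: pd.DataFrame,
    strata_col: str,
    exposure_col: str,
    reference: str,
    fit_fn,
    hr_columns: Mapping[str, str],
    method: str = "case_load",
    event_col: str = "event",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, PAFResult]:
    """Per-stratum PAF with stratum-specific hazard ratios and distributions.

    ``fit_fn(stratum_data) -> CoxFit`` supplies the stratum-specific model.
    Strata with an empty exposure-by-event cell are flagged in the result
    rather than silently dropped.
    """
    out: dict[str, PAFResult] = {}
    levels = [str(v) for v in pd.unique(data[exposure_col].astype(str))]
    for s, sub in data.groupby(strata_col, observed=True, sort=True):
        cases = sub[sub[event_col] == 1]
        empty = [
            lv
            for lv in levels
            if (cases[exposure_col].astype(str) == lv).sum() == 0
        ]
        if empty:
            out[str(s)] = PAFResult(
                estimate=float("nan"),
                method=method,
                flagged=f"no events at exposure level(s) {empty}",
            )
            continue
        fit = fit_fn(sub)
        if not fit.converged:
            out[str(s)] = PAFResult(
                estimate=float("nan"),
                method=method,
                flagged=f"stratum fit did not converge: {fit.warnings}",
            )
            continue
        src = cases if method == "case_load" else sub
        counts = src[exposure_col].astype(str).value_counts().to_dict()
        counts = {lv: counts.get(lv, 0) for lv in levels}
        out[str(s)] = paf_confidence_interval(
            method, counts, reference, fit, hr_columns, n_boot=n_boot, seed=seed
        )
    return out
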