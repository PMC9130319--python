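"""Cox proportional-hazards models and survival utilities.

The centrepiece is a Newton-Raphson maximiser of the Cox partial likelihood
with Efron (default) or Breslow handling of tied event times.  For an event
time t with tied event set D (|D| = d), risk set R, and risk scores
r_i = exp(x_i' beta), the Efron contribution to the log partial likelihood is

    sum_{i in D} x_i' beta - sum_{l=0}^{d-1} log( S0(R) - (l/d) S0(D) )

with S0 the sum of risk scores (Breslow sets l/d to 0).  The gradient and
observed information follow by differentiation; the covariance of beta-hat is
the inverse observed information at the maximum.

Also here: hazard ratios with Wald intervals, the ordinal trend test, the
likelihood-ratio gene-environment interaction test, a Grambsch-Therneau
scaled-Schoenfeld-residual test of proportional hazards, restricted cubic
spline bases, Kaplan-Meier cumulative incidence, ROC AUC, incidence rates per
1000 person-years, and the Schoenfeld approximation to post-hoc power.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .prs import ValidationError

__all__ = [
    "CategoricalTerm",
    "ContinuousTerm",
    "ModelSpec",
    "CoxFit",
    "GroupSummary",
    "fit_cox",
    "hazard_ratios",
    "trend_test",
    "interaction_test",
    "score_test",
    "schoenfeld_ph_test",
    "rcs_basis",
    "cumulative_incidence",
    "roc_auc",
    "concordance",
    "incidence_rate",
    "posthoc_power",
    "group_summaries",
]


# ---------------------------------------------------------------------------
# model specification and design-matrix construction

@dataclasses.dataclass(frozen=True)
class CategoricalTerm:
    """Categorical exposure entering as dummies against a named reference."""

    column: str
    reference: str
    levels: tuple[str, ...] | None = None  # non-reference order; inferred if None


@dataclasses.dataclass(frozen=True)
class ContinuousTerm:
    column: str


Term = CategoricalTerm | ContinuousTerm


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Outcome columns, exposure terms, adjustment covariates, tie method."""

    time_col: str
    event_col: str
    exposures: tuple[Term, ...] = ()
    adjustment: tuple[str, ...] = ()
    ties: str = "efron"
    strata: str | None = None

    def __post_init__(self) -> None:
        if self.ties not in ("efron", "breslow"):
            raise ValidationError(f"ties method must be efron or breslow, got {self.ties!r}")
        names = [t.column for t in self.exposures] + list(self.adjustment)
        if len(names) != len(set(names)):
            raise ValidationError("duplicate terms in model specification")


def _term_columns(data: pd.DataFrame, term: Term) -> pd.DataFrame:
    if isinstance(term, ContinuousTerm):
        return data[[term.column]].astype(float)
    values = data[term.column].astype(str)
    if term.levels is not None:
        levels = list(term.levels)
    else:
        present = values.unique().tolist()
        levels = [lv for lv in sorted(present) if lv != term.reference]
        # keep categorical ordering when the source column carries one
        if isinstance(data[term.column].dtype, pd.CategoricalDtype):
            order = [str(c) for c in data[term.column].cat.categories]
            levels = [lv for lv in order if lv != term.reference and lv in present]
    unknown = set(values.unique()) - set(levels) - {term.reference}
    if unknown:
        raise ValidationError(
            f"{term.column}: levels {sorted(unknown)} neither reference nor listed"
        )
    out = pd.DataFrame(index=data.index)
    for lv in levels:
        out[f"{term.column}[{lv}]"] = (values == lv).astype(float)
    return out


def build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix (reference levels dropped) in spec order."""
    blocks = [_term_columns(data, t) for t in spec.exposures]
    if spec.adjustment:
        blocks.append(data[list(spec.adjustment)].astype(float))
    if not blocks:
        raise ValidationError("model has no terms")
    X = pd.concat(blocks, axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValidationError(f"missing values in design columns {bad}")
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    centered = arr - arr.mean(axis=0)
    scale = centered.std(axis=0)
    zero = scale == 0
    if zero.any():
        raise ValidationError(f"constant (aliased) column: {X.columns[zero][0]}")
    _, R = np.linalg.qr(centered / scale, mode="reduced")
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps * 100
    if (diag < tol).any():
        j = int(np.argmin(diag))
        raise ValidationError(f"collinear design; aliased column near {X.columns[j]}")


# ---------------------------------------------------------------------------
# partial likelihood machinery

def _partial_likelihood_parts(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and observed information.

    Walks unique times in decreasing order, accumulating risk-set sums
    S0 = sum r, S1 = sum r x, S2 = sum r x x' incrementally; each tied event
    group then contributes via the Efron (or Breslow) correction.
    """
    n, p = X.shape
    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    with np.errstate(over="raise"):
        try:
            eta = Xs @ beta
            r = np.exp(eta)
        except FloatingPointError:
            return -np.inf, np.zeros(p), np.eye(p)
    rX = r[:, None] * Xs

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))

    # unique event times, processed in decreasing order so the risk set only
    # ever grows; subjects (events and censored alike) are folded in as one
    # vectorized chunk per event time
    event_times = np.unique(ts[es == 1])[::-1]
    # prefix end in the descending sort for each event time: #{t_j >= t}
    prefix_ends = np.searchsorted(-ts, -event_times, side="right")
    prev_end = 0
    for t, end in zip(event_times, prefix_ends):
        a, b = prev_end, end
        prev_end = end
        S0 += r[a:b].sum()
        S1 += rX[a:b].sum(axis=0)
        S2 += Xs[a:b].T @ rX[a:b]
        # tied event set at this time
        blk = np.arange(np.searchsorted(-ts, -t, side="left"), end)
        idx = blk[es[blk] == 1]
        d = idx.size
        rD = r[idx].sum()
        sD = rX[idx].sum(axis=0)
        S2D = Xs[idx].T @ rX[idx]
        if ties == "efron" and d > 1:
            c = np.arange(d) / d
        else:
            c = np.zeros(d)
        denom = S0 - c * rD  # (d,)
        if np.any(denom <= 0):
            return -np.inf, np.zeros(p), np.eye(p)
        Z = (S1[None, :] - c[:, None] * sD) / denom[:, None]  # (d, p)
        ll += eta[idx].sum() - np.log(denom).sum()
        grad += Xs[idx].sum(axis=0) - Z.sum(axis=0)
        inv = 1.0 / denom
        info += S2 * inv.sum() - S2D * (c * inv).sum() - Z.T @ Z
    return ll, grad, info


def _stratified_parts(X, time, event, strata, beta, ties):
    if strata is None:
        return _partial_likelihood_parts(X, time, event, beta, ties)
    ll, grad, info = 0.0, np.zeros(X.shape[1]), np.zeros((X.shape[1],) * 2)
    for s in np.unique(strata):
        m = strata == s
        l, g, i = _partial_likelihood_parts(X[m], time[m], event[m], beta, ties)
        ll += l
        grad += g
        info += i
    return ll, grad, info


@dataclasses.dataclass
class CoxFit:
    """A converged (or diagnosed) Cox partial-likelihood fit."""

    beta: pd.Series
    covariance: pd.DataFrame
    loglik: float
    loglik_null: float
    n_obs: int
    n_events: int
    iterations: int
    converged: bool
    ties: str
    warnings: list[str] = dataclasses.field(default_factory=list)
    spec: ModelSpec | None = None

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)), index=self.beta.index, name="se")

    def linear_predictor(self, data: pd.DataFrame) -> pd.Series:
        X = build_design(data, self.spec)
        return pd.Series(X.to_numpy() @ self.beta.to_numpy(), index=data.index, name="lp")


def fit_cox(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    max_iter: int = 50,
    tol_loglik: float = 1e-9,
    tol_grad: float = 1e-6,
) -> CoxFit:
    """Maximise the Efron/Breslow partial likelihood by Newton-Raphson.

    Convergence when the relative log-likelihood change drops below 1e-9 or
    the gradient max-norm below 1e-6 (at most 50 iterations); step-halving
    guards each Newton step.  The covariance is the inverse observed
    information at the optimum.  Non-convergence and apparently monotone
    likelihoods (divergent coefficients, as under complete separation) are
    flagged in ``warnings``, never silent.
    """
    time = data[spec.time_col].to_numpy(dtype=float)
    event = data[spec.event_col].to_numpy()
    if not np.isin(event, (0, 1)).all():
        raise ValidationError("event indicator must be 0/1")
    event = event.astype(int)
    if event.sum() < 1:
        raise ValidationError("no events in the data")
    Xdf = build_design(data, spec)
    _check_full_rank(Xdf)
    X = Xdf.to_numpy(dtype=float)
    strata = data[spec.strata].to_numpy() if spec.strata else None
    p = X.shape[1]

    beta = np.zeros(p)
    ll, grad, info = _stratified_parts(X, time, event, strata, beta, spec.ties)
    loglik_null = ll
    warnings: list[str] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(f"singular information matrix: {exc}") from exc
        new_beta = beta + step
        new_ll, new_grad, new_info = _stratified_parts(X, time, event, strata, new_beta, spec.ties)
        halvings = 0
        while new_ll < ll and halvings < 25:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _stratified_parts(
                X, time, event, strata, new_beta, spec.ties
            )
            halvings += 1
        rel_change = abs(new_ll - ll) / max(abs(ll), 1.0)
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if rel_change < tol_loglik or np.max(np.abs(grad)) < tol_grad:
            converged = True
            break
    if not converged:
        warnings.append("did not converge within iteration limit")
    if np.max(np.abs(beta)) > 15:
        warnings.append("divergent coefficient; possible monotone likelihood / separation")
        converged = False
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        warnings.append("singular information at optimum")
    cov = (cov + cov.T) / 2.0
    return CoxFit(
        beta=pd.Series(beta, index=Xdf.columns, name="beta"),
        covariance=pd.DataFrame(cov, index=Xdf.columns, columns=Xdf.columns),
        loglik=float(ll),
        loglik_null=float(loglik_null),
        n_obs=len(data),
        n_events=int(event.sum()),
        iterations=it,
        converged=converged,
        ties=spec.ties,
        warnings=warnings,
        spec=spec,
    )


def hazard_ratios(fit: CoxFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-term HR = exp(beta) with Wald confidence limits and p-values."""
    if not fit.converged:
        raise ValidationError(f"fit did not converge: {fit.warnings}")
    z = stats.norm.ppf(1 - alpha / 2)
    se = fit.se
    beta = fit.beta
    wald = beta / se
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - z * se),
            "ci_high": np.exp(beta + z * se),
            "p": 2 * stats.norm.sf(np.abs(wald)),
        }
    )


def score_test(data: pd.DataFrame, spec: ModelSpec) -> tuple[float, float]:
    """Score (Rao) test of beta = 0: chi-square statistic and p-value.

    On two-group data without tied event times this statistic is exactly the
    log-rank chi-square.
    """
    time = data[spec.time_col].to_numpy(dtype=float)
    event = data[spec.event_col].to_numpy().astype(int)
    Xdf = build_design(data, spec)
    strata = data[spec.strata].to_numpy() if spec.strata else None
    _, grad, info = _stratified_parts(
        Xdf.to_numpy(float), time, event, strata, np.zeros(Xdf.shape[1]), spec.ties
    )
    chi2 = float(grad @ np.linalg.solve(info, grad))
    return chi2, float(stats.chi2.sf(chi2, Xdf.shape[1]))


def trend_test(data: pd.DataFrame, spec: ModelSpec, exposure: str) -> float:
    """P for trend: refit with the ordered category scored 0, 1, 2, ...

    The named exposure must be a categorical term with at least three
    levels (reference first); its Wald p-value from the refit is returned.
    """
    term = next(
        (t for t in spec.exposures if isinstance(t, CategoricalTerm) and t.column == exposure),
        None,
    )
    if term is None:
        raise ValidationError(f"{exposure} is not a categorical exposure of this model")
    cols = _term_columns(data, term)
    levels = [term.reference] + [c[len(exposure) + 1 : -1] for c in cols.columns]
    if len(levels) < 3:
        raise ValidationError("trend test needs >= 3 ordered levels")
    codes = pd.Series(data[exposure].astype(str)).map({lv: i for i, lv in enumerate(levels)})
    work = data.copy()
    ord_col = f"{exposure}__ordinal"
    work[ord_col] = codes.astype(float)
    new_exposures = tuple(
        t for t in spec.exposures if t.column != exposure
    ) + (ContinuousTerm(ord_col),)
    refit = fit_cox(work, dataclasses.replace(spec, exposures=new_exposures))
    return float(hazard_ratios(refit).loc[ord_col, "p"])


def interaction_test(
    data: pd.DataFrame, spec: ModelSpec, term_a: str, term_b: str
) -> tuple[float, CoxFit, CoxFit]:
    """Likelihood-ratio test for term_a x term_b product terms.

    Fits the specified model with and without all pairwise products of the
    design columns of the two named terms; the LRT statistic is referred to
    a chi-square with one degree of freedom per product column.  Returns
    (p, fit_with_interaction, fit_without).
    """
    terms = {t.column: t for t in spec.exposures}
    for name in (term_a, term_b):
        if name not in terms:
            raise ValidationError(f"term {name!r} not present in the model specification")
    cols_a = _term_columns(data, terms[term_a])
    cols_b = _term_columns(data, terms[term_b])
    work = data.copy()
    prod_terms: list[Term] = []
    for ca, cb in itertools.product(cols_a.columns, cols_b.columns):
        name = f"{ca}*{cb}"
        work[name] = cols_a[ca] * cols_b[cb]
        prod_terms.append(ContinuousTerm(name))
    fit0 = fit_cox(work, spec)
    fit1 = fit_cox(work, dataclasses.replace(spec, exposures=spec.exposures + tuple(prod_terms)))
    lrt = 2.0 * (fit1.loglik - fit0.loglik)
    if lrt < -1e-6:
        raise ValidationError(
            f"nested likelihoods decreased ({lrt:.3g}); numerical failure in interaction test"
        )
    df = len(prod_terms)
    p = float(stats.chi2.sf(max(lrt, 0.0), df))
    return p, fit1, fit0


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic

def schoenfeld_ph_test(
    fit: CoxFit, data: pd.DataFrame, transform: str = "km"
) -> pd.DataFrame:
    """Grambsch-Therneau test of proportional hazards per term and globally.

    Scaled Schoenfeld residuals at each event time are regressed on a time
    transform g(t) (default: one minus the Kaplan-Meier survival estimate);
    the score test of zero slope uses the average risk-set covariance
    I(beta-hat)/d.  Returns a table with per-term rows plus a GLOBAL row,
    each carrying the chi-square, df and p-value.
    """
    if not fit.converged:
        raise ValidationError("proportional-hazards test requires a converged fit")
    spec = fit.spec
    time = data[spec.time_col].to_numpy(dtype=float)
    event = data[spec.event_col].to_numpy().astype(int)
    if event.sum() < 2:
        raise ValidationError("need at least 2 events")
    Xdf = build_design(data, spec)
    X = Xdf.to_numpy(float)
    beta = fit.beta.to_numpy()
    p = X.shape[1]

    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    r = np.exp(Xs @ beta)
    rX = r[:, None] * Xs

    S0, S1 = 0.0, np.zeros(p)
    info = np.zeros((p, p))
    resid_rows: list[np.ndarray] = []
    resid_times: list[float] = []
    S2 = np.zeros((p, p))
    event_times = np.unique(ts[es == 1])[::-1]
    prefix_ends = np.searchsorted(-ts, -event_times, side="right")
    prev_end = 0
    for t, end in zip(event_times, prefix_ends):
        a, b = prev_end, end
        prev_end = end
        S0 += r[a:b].sum()
        S1 += rX[a:b].sum(axis=0)
        S2 += Xs[a:b].T @ rX[a:b]
        blk = np.arange(np.searchsorted(-ts, -t, side="left"), end)
        ev_idx = blk[es[blk] == 1]
        xbar = S1 / S0
        V = S2 / S0 - np.outer(xbar, xbar)
        for i in ev_idx:
            resid_rows.append(Xs[i] - xbar)
            resid_times.append(ts[i])
            info += V

    resid = np.asarray(resid_rows)  # (d, p), Schoenfeld residuals
    times = np.asarray(resid_times)
    d = resid.shape[0]
    if np.unique(times).size < 2:
        raise ValidationError("all events share one time; PH test undefined")

    if transform == "km":
        km = _km_survival(time, event)
        g = 1.0 - np.interp(times, km[0], km[1])
    elif transform == "rank":
        g = stats.rankdata(times)
    elif transform == "identity":
        g = times.copy()
    else:
        raise ValidationError(f"unknown time transform {transform!r}")
    g = g - g.mean()
    gg = float(g @ g)

    vbar = info / d  # average risk-set covariance
    u = resid.T @ g  # (p,)
    vbar_inv = np.linalg.inv(vbar)
    rows = []
    for j, name in enumerate(Xdf.columns):
        chi = u[j] ** 2 / (gg * vbar[j, j])
        rows.append((name, chi, 1, stats.chi2.sf(chi, 1)))
    chi_global = float(u @ vbar_inv @ u) / gg
    rows.append(("GLOBAL", chi_global, p, stats.chi2.sf(chi_global, p)))
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"]).set_index("term")


def schoenfeld_residuals(fit: CoxFit, data: pd.DataFrame) -> pd.DataFrame:
    """Unscaled Schoenfeld residuals (one row per event, ordered by time)."""
    spec = fit.spec
    time = data[spec.time_col].to_numpy(dtype=float)
    event = data[spec.event_col].to_numpy().astype(int)
    Xdf = build_design(data, spec)
    X = Xdf.to_numpy(float)
    beta = fit.beta.to_numpy()
    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    r = np.exp(Xs @ beta)
    rX = r[:, None] * Xs
    S0, S1 = 0.0, np.zeros(X.shape[1])
    rows, times = [], []
    event_times = np.unique(ts[es == 1])[::-1]
    prefix_ends = np.searchsorted(-ts, -event_times, side="right")
    prev_end = 0
    for t, end in zip(event_times, prefix_ends):
        S0 += r[prev_end:end].sum()
        S1 += rX[prev_end:end].sum(axis=0)
        blk = np.arange(np.searchsorted(-ts, -t, side="left"), end)
        prev_end = end
        for i in blk[es[blk] == 1]:
            rows.append(Xs[i] - S1 / S0)
            times.append(ts[i])
    out = pd.DataFrame(rows, columns=Xdf.columns)
    out.insert(0, "time", times)
    return out.sort_values("time", kind="stable").reset_index(drop=True)


def _km_survival(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier survival over the pooled sample (times, S(t))."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq, first = np.unique(t, return_index=True)
    n = len(t)
    at_risk = n - first
    d = np.add.reduceat(e, first)
    surv = np.cumprod(1.0 - d / at_risk)
    return uniq, surv


# ---------------------------------------------------------------------------
# splines, curves, discrimination, rates, power

_RCS_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def rcs_basis(
    x: np.ndarray | pd.Series, n_knots: int = 4, knots: Sequence[float] | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Restricted cubic spline basis (linear tails, Harrell knot quantiles).

    Returns ``n_knots - 1`` columns — the linear term plus the truncated-cubic
    combinations, normalised by the squared knot span — and the knot
    locations.  The basis is exactly linear beyond the boundary knots.
    """
    arr = np.asarray(x, dtype=float)
    if knots is None:
        if n_knots not in _RCS_QUANTILES:
            raise ValidationError("n_knots must be 3, 4 or 5")
        knots = np.quantile(arr, _RCS_QUANTILES[n_knots])
    knots = np.asarray(sorted(knots), dtype=float)
    k = len(knots)
    if np.unique(knots).size != k:
        raise ValidationError("knots must be distinct; too few distinct x values")
    if np.unique(arr).size < k:
        raise ValidationError("need at least as many distinct values as knots")
    span2 = (knots[-1] - knots[0]) ** 2

    def cube(u: np.ndarray) -> np.ndarray:
        return np.clip(u, 0.0, None) ** 3

    cols = {"rcs1": arr}
    tk, tk1 = knots[-1], knots[-2]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            cube(arr - tj)
            - cube(arr - tk1) * (tk - tj) / (tk - tk1)
            + cube(arr - tk) * (tk1 - tj) / (tk - tk1)
        ) / span2
        cols[f"rcs{j + 2}"] = term
    index = x.index if isinstance(x, pd.Series) else None
    return pd.DataFrame(cols, index=index), knots


def cumulative_incidence(
    data: pd.DataFrame,
    group_col: str,
    time_col: str = "follow_up_years",
    event_col: str = "event",
) -> pd.DataFrame:
    """Per-group Kaplan-Meier cumulative risk, 1 - S(t), as a long table.

    Columns: group, time, cum_risk.  Each curve starts at (0, 0) and is a
    non-decreasing step function bounded by 1.
    """
    from lifelines import KaplanMeierFitter

    frames = []
    for g, sub in data.groupby(group_col, observed=True, sort=True):
        if len(sub) == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(sub[time_col], sub[event_col])
        sf = km.survival_function_
        frames.append(
            pd.DataFrame(
                {
                    "group": str(g),
                    "time": sf.index.to_numpy(dtype=float),
                    "cum_risk": 1.0 - sf.iloc[:, 0].to_numpy(dtype=float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def roc_auc(event_labels: np.ndarray, risk_scores: np.ndarray) -> float:
    """ROC area via the Mann-Whitney U statistic (ties counted one half)."""
    y = np.asarray(event_labels).astype(int)
    s = np.asarray(risk_scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("ROC AUC needs both classes present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def concordance(time, event, risk_scores) -> float:
    """Harrell's C for censored data (labelled alternative to the binary AUC)."""
    from lifelines.utils import concordance_index

    return float(concordance_index(time, -np.asarray(risk_scores, float), event))


def incidence_rate(events: int, person_years: float) -> float:
    """Events per 1000 person-years (unrounded; round only for display)."""
    if person_years <= 0:
        raise ValidationError("person-years must be positive")
    if events < 0:
        raise ValidationError("event count must be nonnegative")
    return events / person_years * 1000.0


def posthoc_power(
    n_events: int, exposed_fraction: float, hr: float, alpha: float = 0.05
) -> float:
    """Schoenfeld approximation to two-group log-rank power.

    power = Phi( |log hr| * sqrt(d p (1-p)) - z_{1-alpha/2} ) with d events
    and exposed fraction p.
    """
    if hr <= 0:
        raise ValidationError("hazard ratio must be positive")
    if not (0 < exposed_fraction < 1):
        raise ValidationError("exposed fraction must be in (0, 1)")
    if n_events < 1:
        raise ValidationError("need at least one event")
    z = stats.norm.ppf(1 - alpha / 2)
    return float(
        stats.norm.cdf(
            abs(np.log(hr)) * np.sqrt(n_events * exposed_fraction * (1 - exposed_fraction)) - z
        )
    )


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Counts, person-years and incidence rate for one exposure group."""

    group: str
    n: int
    events: int
    person_years: float

    @property
    def ir_per_1000(self) -> float:
        return incidence_rate(self.events, self.person_years)


def group_summaries(
    data: pd.DataFrame,
    group_col: str,
    time_col: str = "follow_up_years",
    event_col: str = "event",
) -> list[GroupSummary]:
    """Per-group n, events, person-years and incidence rate."""
    out = []
    for g, sub in data.groupby(group_col, observed=True, sort=True):
        out.append(
            GroupSummary(
                group=str(g),
                n=len(sub),
                events=int(sub[event_col].sum()),
                person_years=float(sub[time_col].sum()),
            )
        )
    return out
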