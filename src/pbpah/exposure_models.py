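"""Exposure model fitting: screening, LASSO selection, OLS and mixed models.

The modelling recipe applied at every aggregation level:

1. screen candidate covariates by Pearson correlation with the
   sqrt-transformed outcome (drop |r| < 0.10; note pairs with r >= 0.8);
2. run the LASSO regularization path over the standardized survivors and,
   for each active set along the path, refit unpenalized OLS; keep the
   active set with minimum AIC (or maximum R-squared);
3. report the OLS refit with standard errors, p-values, sequential
   partial R-squared in path entry order, and variance inflation factors;
4. for repeated person-day data, additionally fit a linear mixed model
   with a subject random intercept and an independent random slope.

Unpenalized refits are reported because shrunken LASSO coefficients carry
no standard errors or p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import lars_path
from statsmodels.regression.mixed_linear_model import MixedLMParams

__all__ = [
    "CandidateScreen",
    "ModelFit",
    "MixedFit",
    "screen_candidates",
    "lasso_select",
    "fit_linear",
    "fit_mixed",
    "run_model_suite",
]


@dataclass
class CandidateScreen:
    correlations: dict  # name -> Pearson r with the outcome
    retained: list  # |r| >= threshold, in input order
    dropped: list
    high_correlation_pairs: list  # (name_a, name_b, r) with |r| >= 0.8, each pair once
    threshold: float = 0.10


def screen_candidates(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    threshold: float = 0.10,
    high_r: float = 0.8,
) -> CandidateScreen:
    """Correlation screen of candidate covariates against the outcome.

    Zero-variance candidates are excluded with a warning (r undefined).
    """
    y = table[outcome].to_numpy(dtype=float)
    corr: dict[str, float] = {}
    usable = []
    for name in candidates:
        x = table[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"candidate {name!r} has zero variance; excluded from screen")
            continue
        corr[name] = float(np.corrcoef(x, y)[0, 1])
        usable.append(name)
    retained = [n for n in usable if abs(corr[n]) >= threshold]
    dropped = [n for n in usable if abs(corr[n]) < threshold]
    pairs = []
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            r = float(np.corrcoef(table[a], table[b])[0, 1])
            if abs(r) >= high_r:
                pairs.append((a, b, r))
    return CandidateScreen(corr, retained, dropped, pairs, threshold)


def _dedupe_columns(table: pd.DataFrame, candidates: list[str]) -> list[str]:
    """Drop exactly duplicated candidate columns, keeping the first (with warning)."""
    kept: list[str] = []
    for name in candidates:
        if any(table[name].equals(table[k]) for k in kept):
            warnings.warn(f"candidate {name!r} duplicates an earlier column; keeping first")
            continue
        kept.append(name)
    return kept


def lasso_select(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    criterion: str = "aic",
) -> list[str]:
    """Active set optimizing the criterion along the LASSO path, in entry order.

    The path is computed by least-angle regression on internally
    standardized candidates; each distinct active set is refit by
    unpenalized OLS and scored. ``criterion`` is "aic" (minimize) or
    "r2" (maximize; with a monotone path this favours the largest set).
    """
    if criterion not in ("aic", "r2"):
        raise ValueError(f"unknown criterion {criterion!r}")
    candidates = _dedupe_columns(table, candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates for path selection")
    n = len(table)
    if n <= len(candidates) + 1:
        raise ValueError(f"saturated design: n={n} with {len(candidates)} candidates")
    X = table[candidates].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    y = table[outcome].to_numpy(dtype=float)

    _, _, coefs = lars_path(X, y - y.mean(), method="lasso")
    active_sets: list[tuple[str, ...]] = [()]
    entry_order: list[str] = []
    for step in range(coefs.shape[1]):
        active = [candidates[j] for j in range(len(candidates)) if coefs[j, step] != 0]
        for name in active:
            if name not in entry_order:
                entry_order.append(name)
        ordered = tuple(n_ for n_ in entry_order if n_ in active)
        if ordered not in active_sets:
            active_sets.append(ordered)

    def score(terms: tuple[str, ...]) -> float:
        exog = sm.add_constant(table[list(terms)]) if terms else np.ones((n, 1))
        res = sm.OLS(y, exog).fit()
        return res.aic if criterion == "aic" else -res.rsquared

    best = min(active_sets, key=score)
    return list(best)


@dataclass
class ModelFit:
    """An OLS exposure model: per-term inference plus variance accounting."""

    terms: list  # (name, beta, se, p, partial_r2, vif)
    intercept: tuple  # (beta, se, p)
    r2: float
    adj_r2: float
    n: int
    selection_path: list = field(default_factory=list)
    criterion_trace: list = field(default_factory=list)

    def coef(self, name: str) -> float:
        for t in self.terms:
            if t[0] == name:
                return t[1]
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [("Intercept", *self.intercept, np.nan, np.nan)] + [tuple(t) for t in self.terms]
        return pd.DataFrame(
            rows, columns=["term", "beta", "se", "p_value", "partial_r2", "vif"]
        )


def _vif(table: pd.DataFrame, terms: list[str]) -> dict[str, float]:
    if len(terms) == 1:
        return {terms[0]: 1.0}
    out = {}
    for name in terms:
        others = [t for t in terms if t != name]
        res = sm.OLS(table[name], sm.add_constant(table[others])).fit()
        out[name] = 1.0 / max(1.0 - res.rsquared, 1e-12)
    return out


def fit_linear(
    table: pd.DataFrame,
    outcome: str,
    terms: list[str],
    partial_mode: str = "sequential",
) -> ModelFit:
    """OLS with intercept; SEs, p-values, partial R², VIF.

    ``partial_mode``: "sequential" (Type-I R² increments in the given term
    order, summing exactly to R²) or "last" (squared semipartial of each
    term entered last). Rank-deficient designs raise, naming the terms.
    """
    if table[[outcome] + terms].isna().any().any():
        raise ValueError("missing values in outcome or terms")
    n = len(table)
    if n <= len(terms) + 1:
        raise ValueError(f"n={n} too small for {len(terms)} terms")
    exog = sm.add_constant(table[terms].astype(float))
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError(f"rank-deficient design among terms {terms}")
    res = sm.OLS(table[outcome].astype(float), exog).fit()

    def r2_of(subset: list[str]) -> float:
        ex = sm.add_constant(table[subset].astype(float)) if subset else np.ones((n, 1))
        return sm.OLS(table[outcome].astype(float), ex).fit().rsquared

    partial = {}
    if partial_mode == "sequential":
        prev = 0.0
        for i, name in enumerate(terms):
            cur = r2_of(terms[: i + 1])
            partial[name] = cur - prev
            prev = cur
    elif partial_mode == "last":
        full = res.rsquared
        for name in terms:
            partial[name] = full - r2_of([t for t in terms if t != name])
    else:
        raise ValueError(f"unknown partial_mode {partial_mode!r}")

    vif = _vif(table, terms)
    rows = [
        (name, res.params[name], res.bse[name], res.pvalues[name], partial[name], vif[name])
        for name in terms
    ]
    return ModelFit(
        terms=rows,
        intercept=(res.params["const"], res.bse["const"], res.pvalues["const"]),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n=n,
        selection_path=list(terms),
    )


@dataclass
class MixedFit:
    """REML mixed model: fixed-effect table plus variance components."""

    terms: list  # (name, beta, se, p)
    intercept: tuple  # (beta, se, p)
    var_intercept: float
    var_slope: float | None
    var_residual: float
    slope_term: str | None
    n: int
    n_groups: int
    converged: bool
    warnings: list = field(default_factory=list)

    def coef(self, name: str) -> float:
        for t in self.terms:
            if t[0] == name:
                return t[1]
        raise KeyError(name)


def fit_mixed(
    table: pd.DataFrame,
    outcome: str,
    terms: list[str],
    group: str = "subject_id",
    random_slope_term: str | None = "pct_invehicle",
) -> MixedFit:
    """Linear mixed model with subject random intercept and random slope.

    Fit by REML; the random intercept and the random slope (on
    ``random_slope_term``, which must be one of ``terms``) are modelled as
    independent (diagonal covariance). When the slope variance is
    inestimable (e.g. single observation per group) the model falls back
    to intercept-only with a recorded warning; non-convergence is flagged,
    never silently replaced.
    """
    y = table[outcome].astype(float)
    exog = sm.add_constant(table[terms].astype(float))
    groups = table[group]
    notes: list[str] = []

    counts = groups.value_counts()
    slope_ok = random_slope_term is not None and (counts >= 2).sum() >= 2
    if random_slope_term is not None and not slope_ok:
        notes.append("random slope inestimable (<2 groups with >=2 obs); intercept-only")

    def _fit(with_slope: bool):
        if with_slope:
            exog_re = sm.add_constant(table[[random_slope_term]].astype(float))
            model = sm.MixedLM(y, exog, groups=groups, exog_re=exog_re)
            free = MixedLMParams.from_components(
                fe_params=np.ones(exog.shape[1]), cov_re=np.eye(2)
            )
        else:
            model = sm.MixedLM(y, exog, groups=groups)
            free = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return model.fit(reml=True, free=free, method="lbfgs", maxiter=200)
            except np.linalg.LinAlgError:
                # the score involves inverting the profiled information
                # matrix, which is singular when a variance component
                # collapses to zero; retry derivative-free
                return model.fit(reml=True, free=free, method="powell", maxiter=500)

    use_slope = slope_ok
    res = _fit(use_slope)
    if use_slope and (not np.all(np.isfinite(res.bse_fe)) or res.cov_re.iloc[1, 1] < 1e-10):
        if res.cov_re.iloc[1, 1] < 1e-10:
            notes.append("singular random-slope variance; refit intercept-only")
            use_slope = False
            res = _fit(False)

    converged = bool(getattr(res, "converged", True))
    rows = [(t, res.fe_params[t], res.bse_fe[t], res.pvalues[t]) for t in terms]
    return MixedFit(
        terms=rows,
        intercept=(res.fe_params["const"], res.bse_fe["const"], res.pvalues["const"]),
        var_intercept=float(res.cov_re.iloc[0, 0]),
        var_slope=float(res.cov_re.iloc[1, 1]) if use_slope else None,
        var_residual=float(res.scale),
        slope_term=random_slope_term if use_slope else None,
        n=len(table),
        n_groups=int(groups.nunique()),
        converged=converged,
        warnings=notes,
    )


def run_model_suite(
    person_day: pd.DataFrame,
    subject: pd.DataFrame,
    subject_activity: pd.DataFrame,
    candidates_daily: list[str],
    candidates_subject: list[str],
    candidates_activity: list[str],
    criterion: str = "aic",
    random_slope_term: str = "pct_invehicle",
    max_subject_terms: int = 3,
) -> dict:
    """Screen, select and fit the exposure model at all three levels.

    The subject-level model is reduced to ``max_subject_terms`` by
    dropping the least-significant selected term (small-sample
    parsimony). Returns a report dict of CandidateScreen / ModelFit /
    MixedFit objects per level.
    """
    report: dict = {}

    def level(name, table, cands):
        screen = screen_candidates(table, "sqrt_pah", cands)
        selected = (
            lasso_select(table, "sqrt_pah", screen.retained, criterion)
            if len(screen.retained) >= 2
            else list(screen.retained)
        )
        fit = fit_linear(table, "sqrt_pah", selected) if selected else None
        report[name] = {"screen": screen, "selected": selected, "ols": fit}
        return selected

    daily_terms = level("daily", person_day, candidates_daily)
    if daily_terms:
        slope = random_slope_term if random_slope_term in daily_terms else daily_terms[0]
        report["daily"]["mixed"] = fit_mixed(
            person_day, "sqrt_pah", daily_terms, random_slope_term=slope
        )

    subj_terms = level("subject", subject, candidates_subject)
    if len(subj_terms) > max_subject_terms:
        fit = report["subject"]["ols"]
        worst = max(fit.terms, key=lambda t: t[3])[0]  # largest p-value
        reduced = [t for t in subj_terms if t != worst]
        report["subject"]["reduced_terms"] = reduced
        report["subject"]["ols_reduced"] = fit_linear(subject, "sqrt_pah", reduced)

    level("activity", subject_activity, candidates_activity)
    return report
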