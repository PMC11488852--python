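"""Degree-day accounting and courtship-assay statistics.

Covers the behavioral side of the study design: accumulated degree days
(a physiological-age scale), Z-tests of mating proportions, logistic
models for competitive courtship outcomes, Cox proportional-hazards
regression for right-censored copulation latencies (Efron or Breslow tie
handling — latencies observed on a 10-minute grid are heavily tied), and
nested-model chi-square comparisons.

Batch and strain enter the logistic and Cox fits as fixed-effect dummies
(a deliberate approximation of the random-effect formulation), so results
are comparable, not identical, to mixed-model fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "accumulated_degree_days",
    "proportion_ztest",
    "fit_competitive_model",
    "fit_cox_latency",
    "compare_nested_models",
    "CoxFit",
    "GlmFit",
]


def accumulated_degree_days(t_dev: float, t_threshold: float, days: float) -> float:
    """Accumulated degree days: ``(T_D - T_t) * d``.

    ``t_threshold`` is the threshold developmental temperature (12.4 deg C
    for house fly); a negative result means development below threshold
    and is flagged with a warning.
    """
    add = (t_dev - t_threshold) * days
    if add < 0:
        warnings.warn("negative degree days: development below threshold temperature",
                      stacklevel=2)
    return add


def proportion_ztest(
    x1: int, n1: int, x2: int, n2: int, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Pooled-variance Z-test comparing two proportions.

    No continuity correction.  ``alternative='one_sided'`` tests
    ``p1 > p2``.  Returns ``(z, p)``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    z = 0.0 if se == 0 else (p1 - p2) / se
    if alternative == "two_sided":
        p = 2 * stats.norm.sf(abs(z))
    elif alternative == "one_sided":
        p = stats.norm.sf(z)
    else:
        raise ValueError("alternative must be 'two_sided' or 'one_sided'")
    return float(z), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# design-matrix helpers shared by the logistic and Cox fits


def _term_columns(data: pd.DataFrame, term: str) -> pd.DataFrame:
    """Dummy-code one model term; ``a:b`` builds interaction columns."""
    if ":" in term:
        left, right = term.split(":", 1)
        lcols = _term_columns(data, left)
        rcols = _term_columns(data, right)
        out = {}
        for ln, lv in lcols.items():
            for rn, rv in rcols.items():
                out[f"{ln}:{rn}"] = lv * rv
        return pd.DataFrame(out, index=data.index)
    col = data[term]
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(col.astype(str), prefix=term, drop_first=True)
        return dummies.astype(float)
    return pd.DataFrame({term: col.astype(float)})


def _build_design(
    data: pd.DataFrame, terms: list[str], intercept: bool = True
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    parts, mapping = [], {}
    for term in terms:
        cols = _term_columns(data, term)
        mapping[term] = list(cols.columns)
        parts.append(cols)
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=data.index)
    if intercept:
        X.insert(0, "Intercept", 1.0)
    return X, mapping


@dataclass
class GlmFit:
    """A fitted logistic model plus type-II likelihood-ratio tests."""

    params: pd.Series
    loglik: float
    terms: list[str] = field(default_factory=list)
    anova: pd.DataFrame | None = None
    separated: bool = False

    @property
    def n_params(self) -> int:
        return len(self.params)


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.Series, float, bool]:
    model = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial())
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = model.fit(maxiter=200)
        params = np.asarray(res.params)
        llf = float(res.llf)
        if np.max(np.abs(params)) > 15:
            separated = True
    except Exception:
        separated = True
        res = model.fit_regularized(alpha=1e-3, L1_wt=0.0)
        params = np.asarray(res.params)
        mu = 1 / (1 + np.exp(-(X.to_numpy() @ params)))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    if separated:
        warnings.warn("possible complete separation; penalized/capped fit flagged",
                      stacklevel=3)
    return pd.Series(params, index=X.columns), llf, separated


def fit_competitive_model(
    trials: pd.DataFrame, formula_variant: str = "genotype_contest"
) -> GlmFit:
    """Logistic regression for competitive courtship outcomes.

    ``genotype_contest`` models whether the blue male won on the blue
    male's genotype, the shared developmental temperature, their
    interaction and batch (``W ~ G_B + T + G_B x T + b``); required
    columns are ``blue_wins`` (or ``winner`` + ``blue_genotype``),
    ``blue_genotype``, ``temperature``, ``batch``.  ``temperature_contest``
    swaps the roles (``W ~ G + T_B + G x T_B + b``) with columns
    ``blue_wins``, ``genotype``, ``blue_temperature``, ``batch``.

    Batch enters as fixed-effect dummies; with a single batch the term is
    dropped with a warning.  Type-II likelihood-ratio chi-square tests are
    reported per fixed effect.
    """
    trials = trials.copy()
    if "blue_wins" not in trials.columns:
        trials["blue_wins"] = (trials["winner"] == trials["blue_genotype"]).astype(float)
    if formula_variant == "genotype_contest":
        fixed = ["blue_genotype", "temperature", "blue_genotype:temperature"]
    elif formula_variant == "temperature_contest":
        fixed = ["genotype", "blue_temperature", "genotype:blue_temperature"]
    else:
        raise ValueError("formula_variant must be 'genotype_contest' or 'temperature_contest'")
    y = trials["blue_wins"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome labels must be present")
    terms = list(fixed)
    if trials["batch"].nunique() >= 2:
        terms.append("batch")
    else:
        warnings.warn("single batch: batch term dropped", stacklevel=2)

    # categorical temperature, per the assay design (two rearing regimes)
    for c in ("temperature", "blue_temperature"):
        if c in trials.columns:
            trials[c] = trials[c].astype(str)

    X, _ = _build_design(trials, terms)
    params, llf, separated = _fit_logit(y, X)

    rows = []
    for term in fixed:
        # type II: main effects tested without interactions containing them
        keep_full = [t for t in terms if t == term or ":" not in t or ":" in term]
        if ":" not in term:
            keep_full = [t for t in terms if ":" not in t or term not in t.split(":")]
            if term not in keep_full:
                keep_full.append(term)
        keep_red = [t for t in keep_full if t != term]
        Xf, _ = _build_design(trials, [t for t in terms if t in keep_full])
        Xr, _ = _build_design(trials, [t for t in terms if t in keep_red])
        _, llf_f, _ = _fit_logit(y, Xf)
        _, llf_r, _ = _fit_logit(y, Xr)
        chi2 = max(2.0 * (llf_f - llf_r), 0.0)
        df = Xf.shape[1] - Xr.shape[1]
        rows.append({"term": term, "chi2": chi2, "df": df,
                     "p": float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan})
    anova = pd.DataFrame(rows).set_index("term")
    if separated:
        anova[["chi2", "p"]] = np.nan
    return GlmFit(params=params, loglik=llf, terms=terms, anova=anova, separated=separated)


# ---------------------------------------------------------------------------
# Cox proportional hazards with Efron/Breslow ties


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``summary`` holds, per coefficient: ``coef``, ``se``, ``hr`` (the
    hazard ratio ``exp(coef)``) and its Wald 95% CI.  ``anova`` holds
    per-term analysis-of-deviance chi-square tests.
    """

    summary: pd.DataFrame
    loglik: float
    terms: list[str] = field(default_factory=list)
    anova: pd.DataFrame | None = None
    ties: str = "efron"
    n_iter: int = 0

    @property
    def params(self) -> pd.Series:
        return self.summary["coef"]

    @property
    def n_params(self) -> int:
        return len(self.summary)


def _cox_loglik_grad_hess(beta, X, order_times, order_events, ties):
    """Partial log-likelihood, gradient and Hessian (negative curvature).

    Rows of ``X`` must be sorted by ascending time; ``order_events`` is the
    event indicator in the same order.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # stabilize exponentials; constant shift cancels
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)
    # suffix (risk-set) sums: risk set at time t = all with time >= t
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and order_times[j] == order_times[i]:
            j += 1
        tied = [k for k in range(i, j) if order_events[k]]
        d = len(tied)
        if d:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            xs = X[tied]
            ll += eta[tied].sum()
            if ties == "breslow" or d == 1:
                for _ in range(d):
                    ll -= np.log(s0)
                    grad_term = s1 / s0
                    grad -= grad_term
                    hess -= s2 / s0 - np.outer(grad_term, grad_term)
                grad += xs.sum(axis=0)
            elif ties == "efron":
                d0 = w[tied].sum()
                d1 = wx[tied].sum(axis=0)
                d2 = wxx[tied].sum(axis=0)
                for l in range(d):
                    f = l / d
                    a0 = s0 - f * d0
                    a1 = s1 - f * d1
                    a2 = s2 - f * d2
                    ll -= np.log(a0)
                    grad_term = a1 / a0
                    grad -= grad_term
                    hess -= a2 / a0 - np.outer(grad_term, grad_term)
                grad += xs.sum(axis=0)
            else:
                raise ValueError("ties must be 'efron' or 'breslow'")
        i = j
    return ll, grad, hess


def _cox_newton(X, times, events, ties, max_iter=100, tol=1e-9):
    order = np.argsort(times, kind="stable")
    Xs = X[order]
    ts = times[order]
    es = events[order]
    beta = np.zeros(X.shape[1])
    ll, grad, hess = _cox_loglik_grad_hess(beta, Xs, ts, es, ties)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step-halving to guarantee ascent
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, hess_new = _cox_loglik_grad_hess(cand, Xs, ts, es, ties)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.linalg.norm(grad) < tol or np.max(np.abs(step)) < 1e-10:
            return beta, ll, hess, it
    raise RuntimeError(
        f"Cox Newton failed to converge in {max_iter} iterations "
        f"(gradient norm {np.linalg.norm(grad):.3g})"
    )


def fit_cox_latency(
    records: pd.DataFrame,
    covariates: list[str] = ("genotype",),
    ties: str = "efron",
    duration_col: str = "latency_min",
    censored_col: str = "censored",
) -> CoxFit:
    """Cox proportional-hazards regression for copulation latency.

    Unmated individuals are right-censored at the observation bound.
    Categorical covariates are dummy-coded (first level as reference;
    batch/strain enter the same way, as fixed effects); ``a:b`` terms give
    interactions.  Newton optimization of the partial likelihood with
    Efron (default, appropriate for the tied 10-minute grid) or Breslow
    tie handling; Wald 95% CIs on hazard ratios; per-term analysis-of-
    deviance chi-square via likelihood-ratio drops (type II).
    """
    covariates = list(covariates)
    events = (~records[censored_col].astype(bool)).to_numpy()
    if events.sum() == 0:
        raise ValueError("no uncensored events")
    times = records[duration_col].to_numpy(dtype=float)
    X, mapping = _build_design(records, covariates, intercept=False)
    beta, ll, hess, n_iter = _cox_newton(X.to_numpy(dtype=float), times, events, ties)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "hr_ci_low": np.exp(beta - z * se),
            "hr_ci_high": np.exp(beta + z * se),
        },
        index=X.columns,
    )

    rows = []
    for term in covariates:
        keep_full = [t for t in covariates if ":" not in t or term == t or ":" in term]
        if ":" not in term:
            keep_full = [t for t in covariates if ":" not in t or term not in t.split(":")]
            if term not in keep_full:
                keep_full.append(term)
        keep_red = [t for t in keep_full if t != term]
        Xf, _ = _build_design(records, [t for t in covariates if t in keep_full], intercept=False)
        Xr, _ = _build_design(records, [t for t in covariates if t in keep_red], intercept=False)
        _, llf, _, _ = _cox_newton(Xf.to_numpy(dtype=float), times, events, ties)
        if Xr.shape[1]:
            _, llr, _, _ = _cox_newton(Xr.to_numpy(dtype=float), times, events, ties)
        else:
            llr = _cox_loglik_grad_hess(
                np.zeros(0), np.empty((len(times), 0)),
                np.sort(times), events[np.argsort(times, kind="stable")], ties,
            )[0]
        chi2 = max(2.0 * (llf - llr), 0.0)
        df = Xf.shape[1] - Xr.shape[1]
        rows.append({"term": term, "chi2": chi2, "df": df,
                     "p": float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan})
    anova = pd.DataFrame(rows).set_index("term")
    return CoxFit(summary=summary, loglik=ll, terms=covariates, anova=anova,
                  ties=ties, n_iter=n_iter)


def compare_nested_models(full, reduced) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square between two nested fitted models.

    ``chi2 = 2 (loglik_full - loglik_reduced)``, ``df`` the parameter
    difference; both objects must expose ``loglik`` (or ``llf``) and
    ``n_params`` (or ``params``).  Models whose term sets are exposed are
    checked for genuine nesting.
    """
    def _ll(m):
        return float(getattr(m, "loglik", getattr(m, "llf", None)))

    def _k(m):
        k = getattr(m, "n_params", None)
        return int(k if k is not None else len(m.params))

    tf, tr = getattr(full, "terms", None), getattr(reduced, "terms", None)
    if tf is not None and tr is not None and not set(tr).issubset(set(tf)):
        raise ValueError("models are not nested (reduced terms not a subset)")
    df = _k(full) - _k(reduced)
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    chi2 = 2.0 * (_ll(full) - _ll(reduced))
    if chi2 < -1e-6:
        raise ValueError("full model fits worse than reduced: models not nested?")
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p
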