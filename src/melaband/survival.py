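"""Cox proportional-hazards evaluation of the prognostic factor set.

The Cox model is fitted by Newton–Raphson on the Breslow partial
likelihood (analytic gradient and Hessian; Efron's tie correction is
available behind a flag). Reported per covariate: the coefficient, its
standard error from the inverse observed information, the hazard ratio
``exp(beta)`` with a 95% Wald CI, and a two-sided Wald p-value.

Discrimination is summarized by Harrell's concordance index — the
fraction of comparable patient pairs (the earlier time is an observed
event) ranked correctly by the risk score, ties in score counting 1/2 —
with a percentile bootstrap CI over patient resamples. Optimism is
assessed by leave-one-out cross-validation: each patient's linear
predictor comes from a model fitted without them, and the C-index is
computed on the pooled out-of-fold predictors (its CI bootstrapped over
the pooled triples).

No multiple-testing correction is applied across the univariable
screen; per-model complete-case n values are reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_Z975 = float(stats.norm.ppf(0.975))


class ValidationError(ValueError):
    pass


class UndefinedConcordanceError(ValueError):
    """No comparable pairs: concordance is undefined."""


@dataclass
class CoxResult:
    """A fitted Cox model with inference and concordance summaries."""

    model_id: str
    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    log_partial_likelihood: float
    n: int
    n_events: int
    ties_method: str
    converged: bool
    n_iter: int
    diagnostics: str = ""
    c_index: float | None = None
    c_index_ci: tuple[float, float] | None = None
    loocv_c_index: float | None = None
    loocv_c_index_ci: tuple[float, float] | None = None
    extras: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.coef,
                "se": self.se,
                "HR": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p,
            }
        )


def _prepare(X, time, event):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(time).size == X.shape[1]:
        X = X.T
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=bool).ravel()
    if not (X.shape[0] == time.size == event.size):
        raise ValidationError("X, time and event lengths differ")
    return X, time, event


def breslow_partial_loglik(beta, X, time, event):
    """Breslow log partial likelihood (tied event times share a risk set)."""
    X, time, event = _prepare(X, time, event)
    beta = np.asarray(beta, dtype=float).ravel()
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # descending: risk set = prefix
    eta_s, t_s, e_s = eta[order], time[order], event[order]
    log_cum = np.logaddexp.accumulate(eta_s)
    # risk set for an event at t includes every subject with time >= t,
    # so ties must all point at the last (largest-index) tied position
    _, inverse = np.unique(-t_s, return_inverse=True)
    last_idx = np.zeros(inverse.max() + 1, dtype=int)
    np.maximum.at(last_idx, inverse, np.arange(t_s.size))
    log_denom = log_cum[last_idx[inverse]]
    return float(np.sum((eta_s - log_denom)[e_s]))


def _breslow_derivatives(beta, X, time, event):
    """Log-likelihood, score and observed information (Breslow ties)."""
    n, p = X.shape
    eta = X @ beta
    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    w = np.exp(eta[order] - eta.max())  # stabilized
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * Xs, axis=0)
    s2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    _, inverse = np.unique(-ts, return_inverse=True)
    last_idx = np.zeros(inverse.max() + 1, dtype=int)
    np.maximum.at(last_idx, inverse, np.arange(n))
    at = last_idx[inverse]
    ev = np.flatnonzero(es)
    s0e = s0[at[ev]]
    s1e = s1[at[ev]]
    s2e = s2[at[ev]]
    xbar = s1e / s0e[:, None]
    loglik = float(np.sum(np.log(w[ev]) - np.log(s0e)))
    score = (Xs[ev] - xbar).sum(axis=0)
    info = (s2e / s0e[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", xbar, xbar)
    return loglik, score, info


def cox_fit(
    X,
    time,
    event,
    covariates: list[str] | None = None,
    ties: str = "breslow",
    max_iter: int = 100,
    score_tol: float = 1e-8,
    step_tol: float = 1e-10,
    model_id: str = "cox",
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Breslow tie handling by default (Efron via lifelines behind the
    ``ties="efron"`` flag). Convergence when the max absolute score drops
    below ``score_tol`` or the Newton step below ``step_tol``. A monotone
    (perfectly separating) likelihood is flagged as non-convergence with
    a diagnostic rather than raised.
    """
    X, time, event = _prepare(X, time, event)
    n, p = X.shape
    if covariates is None:
        covariates = [f"x{j}" for j in range(p)]
    if event.sum() < 2:
        raise ValidationError("need at least 2 events")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [covariates[j] for j in np.flatnonzero(sds == 0)]
        raise ValidationError(f"constant covariate(s): {bad}")

    if ties == "efron":
        return _cox_fit_efron(X, time, event, covariates, model_id)
    if ties != "breslow":
        raise ValueError(f"unknown ties method {ties!r}")

    # fit on centered, unit-sd covariates for conditioning; the partial
    # likelihood is location-invariant and scaling is undone afterwards
    center = X.mean(axis=0)
    Xs_ = (X - center) / sds
    beta = np.zeros(p)
    converged = False
    diagnostics = ""
    loglik = -np.inf
    it = 0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for it in range(1, max_iter + 1):
            loglik, score, info = _breslow_derivatives(beta, Xs_, time, event)
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                diagnostics = "singular information matrix"
                break
            # step-halving to keep the likelihood non-decreasing
            for _ in range(30):
                new_ll, *_ = _breslow_derivatives(beta + step, Xs_, time, event)
                if np.isfinite(new_ll) and new_ll >= loglik - 1e-12:
                    break
                step = step / 2.0
            beta = beta + step
            if np.max(np.abs(score)) < score_tol or np.max(np.abs(step)) < step_tol:
                converged = True
                break
        loglik, score, info = _breslow_derivatives(beta, Xs_, time, event)
    if np.max(np.abs(beta)) > 10:  # |log-hazard| > 10 per covariate sd
        converged = False
        diagnostics = diagnostics or "monotone likelihood (perfect separation?)"
        logger.warning("cox_fit %s: %s", model_id, diagnostics)

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    beta = beta / sds  # back to the original covariate scale
    se = se / sds
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # CI may overflow for unconverged fits
        return CoxResult(
        model_id=model_id,
        covariates=list(covariates),
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_lower=np.exp(beta - _Z975 * se),
        ci_upper=np.exp(beta + _Z975 * se),
        p=pvals,
        log_partial_likelihood=loglik,
        n=n,
        n_events=int(event.sum()),
        ties_method=ties,
        converged=converged,
        n_iter=it,
        diagnostics=diagnostics,
    )


def _cox_fit_efron(X, time, event, covariates, model_id) -> CoxResult:
    from lifelines import CoxPHFitter

    df = pd.DataFrame(X, columns=covariates)
    df["_time"] = time
    df["_event"] = event.astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    beta = cph.params_.to_numpy()
    se = cph.standard_errors_.to_numpy()
    return CoxResult(
        model_id=model_id,
        covariates=list(covariates),
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_lower=np.exp(beta - _Z975 * se),
        ci_upper=np.exp(beta + _Z975 * se),
        p=cph.summary["p"].to_numpy(),
        log_partial_likelihood=float(cph.log_likelihood_),
        n=X.shape[0],
        n_events=int(event.sum()),
        ties_method="efron",
        converged=True,
        n_iter=-1,
    )


def harrell_c(risk_scores, time, event) -> float:
    """Harrell's concordance index of a risk score.

    A pair is comparable when the strictly earlier time carries an
    event; it is concordant when that patient has the higher risk score,
    and score ties count 1/2.
    """
    s = np.asarray(risk_scores, dtype=float).ravel()
    t = np.asarray(time, dtype=float).ravel()
    e = np.asarray(event, dtype=bool).ravel()
    if not (s.size == t.size == e.size):
        raise ValidationError("risk_scores, time and event lengths differ")
    # comparable[i, j]: t_i < t_j and subject i had an event
    earlier = t[:, None] < t[None, :]
    comparable = earlier & e[:, None]
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise UndefinedConcordanceError("no comparable pairs")
    higher = s[:, None] > s[None, :]
    tied = s[:, None] == s[None, :]
    concordant = float((comparable & higher).sum())
    half = float((comparable & tied).sum())
    return (concordant + 0.5 * half) / n_comp


def bootstrap_c_ci(
    X,
    time,
    event,
    B: int = 1000,
    seed: int | None = None,
    ties: str = "breslow",
) -> tuple[float, tuple[float, float]]:
    """Apparent Harrell's C with a percentile bootstrap CI.

    Patients are resampled with replacement; the model is refitted and
    its C recomputed on each replicate; the CI is the 2.5/97.5
    percentile of the replicate distribution. Replicates with < 2 events
    or a degenerate design are skipped (warned above 10%).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    X, time, event = _prepare(X, time, event)
    n = X.shape[0]
    fit = cox_fit(X, time, event, ties=ties)
    c_hat = harrell_c(X @ fit.coef, time, event)
    rng = np.random.default_rng(seed)
    cs = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            bfit = cox_fit(X[idx], time[idx], event[idx], ties=ties)
            cs.append(harrell_c(X[idx] @ bfit.coef, time[idx], event[idx]))
        except (ValidationError, UndefinedConcordanceError):
            skipped += 1
    if skipped > 0.1 * B:
        warnings.warn(f"{skipped}/{B} bootstrap replicates skipped", stacklevel=2)
    lo, hi = np.percentile(cs, [2.5, 97.5])
    return c_hat, (float(lo), float(hi))


def loocv_c(
    X,
    time,
    event,
    B: int = 1000,
    seed: int | None = None,
    ties: str = "breslow",
) -> tuple[float, tuple[float, float]]:
    """Leave-one-out cross-validated concordance.

    Each patient's linear predictor comes from a model fitted on the
    other n-1; Harrell's C is computed on the pooled out-of-fold
    predictors and its CI bootstrapped over the pooled
    (predictor, time, event) triples.
    """
    X, time, event = _prepare(X, time, event)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("LOOCV needs n >= 3")
    lp = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            fit = cox_fit(X[mask], time[mask], event[mask], ties=ties)
            lp[i] = X[i] @ fit.coef
        except ValidationError as exc:
            logger.warning("LOOCV fold %d skipped: %s", i, exc)
        mask[i] = True
    keep = ~np.isnan(lp)
    c_hat = harrell_c(lp[keep], time[keep], event[keep])
    rng = np.random.default_rng(seed)
    kept = np.flatnonzero(keep)
    cs = []
    for _ in range(B):
        idx = rng.choice(kept, kept.size, replace=True)
        try:
            cs.append(harrell_c(lp[idx], time[idx], event[idx]))
        except UndefinedConcordanceError:
            continue
    lo, hi = np.percentile(cs, [2.5, 97.5])
    return c_hat, (float(lo), float(hi))


def univariate_screen(
    features: pd.DataFrame,
    time_col: str = "time_months",
    event_col: str = "event",
    factors: list[str] | None = None,
    B: int = 1000,
    seed: int | None = None,
    ties: str = "breslow",
) -> pd.DataFrame:
    """One single-covariate Cox model per factor (complete-case each).

    Returns a table with HR, 95% CI bounds, p, and the factor's Harrell
    C with its bootstrap CI. Factors missing for more than half the
    patients are excluded with a warning.
    """
    if factors is None:
        from melaband.features import FACTOR_COLUMNS

        factors = [c for c in FACTOR_COLUMNS if c in features.columns]
    rng = np.random.default_rng(seed)
    rows = []
    for factor in factors:
        if factor not in features.columns:
            logger.warning("factor %r absent from the feature table", factor)
            continue
        sub = features[[factor, time_col, event_col]].dropna()
        if len(sub) < 0.5 * len(features):
            warnings.warn(
                f"factor {factor!r} missing for more than half the patients; excluded",
                stacklevel=2,
            )
            continue
        x = sub[[factor]].to_numpy()
        t = sub[time_col].to_numpy()
        e = sub[event_col].to_numpy(dtype=bool)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            fit = cox_fit(x, t, e, covariates=[factor], ties=ties, model_id=factor)
            c, (clo, chi) = bootstrap_c_ci(x, t, e, B=B, seed=sub_seed, ties=ties)
        except (ValidationError, UndefinedConcordanceError) as exc:
            logger.warning("factor %r skipped: %s", factor, exc)
            continue
        rows.append(
            {
                "factor": factor,
                "n": len(sub),
                "n_events": int(e.sum()),
                "HR": fit.hr[0],
                "ci_lower": fit.ci_lower[0],
                "ci_upper": fit.ci_upper[0],
                "p": fit.p[0],
                "c_index": c,
                "c_ci_lower": clo,
                "c_ci_upper": chi,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


#: multivariable models: traditional base plus one nuclei-size factor each
MULTIVARIABLE_SIZE_FACTORS = (
    "invasive_mean_nuclei_size",
    "invasive_mean_tumor_nuclei_size",
    "invasive_mean_coloc_nuclei_size",
)
BASE_FACTORS = ("mitosis", "thickness_mm")


def multivariable_models(
    features: pd.DataFrame,
    time_col: str = "time_months",
    event_col: str = "event",
    size_factors=MULTIVARIABLE_SIZE_FACTORS,
    base_factors=BASE_FACTORS,
    B: int = 1000,
    seed: int | None = None,
    ties: str = "breslow",
    collinearity_r: float = 0.999,
) -> list[CoxResult]:
    """The base model (mitosis + thickness) and one model per invasive
    nuclei-size factor added to it, each with apparent and LOOCV C."""
    rng = np.random.default_rng(seed)
    specs = [("base", list(base_factors))] + [
        (f, list(base_factors) + [f]) for f in size_factors if f in features.columns
    ]
    results = []
    for model_id, covs in specs:
        sub = features[covs + [time_col, event_col]].dropna()
        x = sub[covs].to_numpy()
        corr = np.corrcoef(x, rowvar=False)
        offdiag = np.abs(corr[~np.eye(len(covs), dtype=bool)])
        if offdiag.size and offdiag.max() > collinearity_r:
            raise ValidationError(
                f"model {model_id!r}: near-perfect collinearity among covariates"
            )
        t = sub[time_col].to_numpy()
        e = sub[event_col].to_numpy(dtype=bool)
        fit = cox_fit(x, t, e, covariates=covs, ties=ties, model_id=model_id)
        s1, s2 = (int(rng.integers(0, 2**31 - 1)) for _ in range(2))
        fit.c_index, fit.c_index_ci = bootstrap_c_ci(x, t, e, B=B, seed=s1, ties=ties)
        fit.loocv_c_index, fit.loocv_c_index_ci = loocv_c(
            x, t, e, B=B, seed=s2, ties=ties
        )
        results.append(fit)
    return results


def multivariable_table(results: list[CoxResult]) -> pd.DataFrame:
    """Flatten multivariable fits into a per-covariate report table."""
    rows = []
    for res in results:
        for j, cov in enumerate(res.covariates):
            rows.append(
                {
                    "model": res.model_id,
                    "covariate": cov,
                    "HR": res.hr[j],
                    "ci_lower": res.ci_lower[j],
                    "ci_upper": res.ci_upper[j],
                    "p": res.p[j],
                    "c_index": res.c_index,
                    "c_ci_lower": res.c_index_ci[0] if res.c_index_ci else np.nan,
                    "c_ci_upper": res.c_index_ci[1] if res.c_index_ci else np.nan,
                    "loocv_c_index": res.loocv_c_index,
                    "loocv_c_ci_lower": (
                        res.loocv_c_index_ci[0] if res.loocv_c_index_ci else np.nan
                    ),
                    "loocv_c_ci_upper": (
                        res.loocv_c_index_ci[1] if res.loocv_c_index_ci else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def summarize_cohort(clinical: pd.DataFrame) -> dict:
    """Cohort characteristics: n, median/range age, sex split, and per
    endpoint the event count, percentage and median follow-up.

    Percentages are rounded to one decimal.
    """
    if len(clinical) == 0:
        raise ValidationError("empty clinical table")
    n = len(clinical)
    out: dict = {
        "n": n,
        "median_age": float(clinical["age"].median()),
        "age_range": (float(clinical["age"].min()), float(clinical["age"].max())),
    }
    if "sex" in clinical.columns:
        counts = clinical["sex"].value_counts()
        out["sex"] = {
            str(k): {"count": int(v), "percent": round(100.0 * v / n, 1)}
            for k, v in counts.items()
        }
    endpoints = (
        clinical["endpoint"].unique().tolist() if "endpoint" in clinical.columns else ["all"]
    )
    out["endpoints"] = {}
    for ep in endpoints:
        sub = clinical if ep == "all" else clinical[clinical["endpoint"] == ep]
        n_ep = len(sub)
        n_event = int(sub["event"].sum())
        out["endpoints"][str(ep)] = {
            "n": n_ep,
            "events": n_event,
            "event_percent": round(100.0 * n_event / n_ep, 1),
            "censored": n_ep - n_event,
            "censored_percent": round(100.0 * (n_ep - n_event) / n_ep, 1),
            "median_time_months": float(sub["time_months"].median()),
        }
    return out
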