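"""Feature ranking, survival analysis and incremental-value ROC comparison.

Cox models and Kaplan-Meier estimates are delegated to ``lifelines``; the
maximally selected cutpoint search and the logistic-importance ranking are
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as _stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score


@dataclass
class SurvivalRecord:
    """Censored OS/PFS times with clinical covariates for one patient."""

    os_days: float
    os_event: bool
    pfs_days: float
    pfs_event: bool
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.os_days <= 0 or self.pfs_days <= 0:
            raise ValueError("survival times must be positive")
        self.os_event = bool(self.os_event)
        self.pfs_event = bool(self.pfs_event)


@dataclass(frozen=True)
class RankedFeature:
    name: str
    importance: float  # in [0, 100]
    selected: bool  # importance > 50


@dataclass
class CoxModelResult:
    """Per-term hazard ratios with Wald CIs/p-values and the model LL."""

    summary: pd.DataFrame  # index: term; columns: hr, ci_lower, ci_upper, p
    log_likelihood: float

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def p(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])


@dataclass(frozen=True)
class Cutpoint:
    cutoff: float
    statistic: float  # standardized log-rank |z| at the chosen split
    groups: np.ndarray  # 1 where value > cutoff, else 0


@dataclass
class AucComparison:
    auc_baseline: float
    ci_baseline: tuple[float, float]
    auc_augmented: float
    ci_augmented: tuple[float, float]
    delta: float
    p_value: float
    n_boot: int


def _standardize(X: pd.DataFrame) -> np.ndarray:
    Z = np.asarray(X, dtype=float)
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (Z - mu) / sd


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """|z| statistics from an L2-penalized logistic fit (separation fallback).

    Newton iterations on the penalized log-likelihood; standard errors from
    the inverse penalized Hessian.  The intercept is unpenalized.
    """
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = np.diag([0.0] + [alpha] * p)
    for _ in range(100):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = Xd.T @ (y - mu) - pen @ beta
        H = (Xd.T * W) @ Xd + pen
        step = np.linalg.solve(H, grad)
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    return np.abs(beta[1:] / se[1:])


def rank_features(
    features: pd.DataFrame, labels: Sequence
) -> list[RankedFeature]:
    """Rank centroid features by logistic-regression importance.

    The cluster label is regressed on the standardized features; the
    importance of each feature is the absolute Wald z statistic of its
    coefficient, min-max scaled to [0, 100].  Features scoring above 50 are
    flagged as selected.  Perfect separation triggers a penalized refit with
    a warning.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 clusters, got {len(uniq)}")
    y = (labels == uniq[1]).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("one cluster is empty")
    Z = _standardize(features)
    names = list(features.columns)

    import statsmodels.api as sm

    zstats = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, sm.add_constant(Z)).fit(disp=0, maxiter=200)
            if fit.mle_retvals.get("converged", False) and np.all(
                np.isfinite(fit.bse)
            ):
                zv = np.abs(fit.tvalues[1:])
                if np.all(np.isfinite(zv)):
                    zstats = zv
        except Exception:
            zstats = None
    if zstats is None:
        warnings.warn(
            "logistic fit did not converge (possible separation); "
            "using L2-penalized refit for importance",
            stacklevel=2,
        )
        zstats = _ridge_logit(Z, y)

    zstats = np.asarray(zstats, dtype=float)
    zmin, zmax = zstats.min(), zstats.max()
    if zmax > zmin:
        scores = (zstats - zmin) / (zmax - zmin) * 100.0
    else:
        scores = np.full_like(zstats, 100.0)
    return [
        RankedFeature(name=n, importance=float(s), selected=bool(s > 50))
        for n, s in zip(names, scores)
    ]


def two_sample_logrank(
    times: np.ndarray, events: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-sample log-rank: returns (chi-square statistic, standardized z).

    z = sum(O1 - E1) / sqrt(sum V) over distinct event times, with the
    hypergeometric variance; handles tied event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group).astype(bool)
    event_times = np.unique(times[events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        dying = events & (times == t)
        d = dying.sum()
        d1 = (dying & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 0.0
    z = o_minus_e / np.sqrt(var)
    return float(z * z), float(z)


def optimal_cutpoint(
    values: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
    min_prop: float = 0.1,
) -> Cutpoint:
    """Maximally selected log-rank cutpoint.

    Scans midpoints between consecutive distinct values, keeping splits that
    leave at least ``min_prop`` of the sample on each side, and returns the
    cutoff maximizing the absolute standardized log-rank statistic.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = len(values)
    if len(np.unique(values)) < 2:
        raise ValueError("need at least two distinct values to dichotomize")
    if not events.any():
        raise ValueError("no events: cutpoint search undefined")
    uniq = np.unique(values)
    candidates = 0.5 * (uniq[:-1] + uniq[1:])
    min_count = int(np.ceil(min_prop * n))
    best: tuple[float, float] | None = None
    for c in candidates:
        high = values > c
        if high.sum() < min_count or (~high).sum() < min_count:
            continue
        _, z = two_sample_logrank(times, events, high)
        if best is None or abs(z) > best[1] + 1e-12:
            best = (float(c), abs(z))
    if best is None:
        raise ValueError(
            f"no admissible split leaves >= {min_count} patients on each side"
        )
    cutoff, stat = best
    return Cutpoint(cutoff=cutoff, statistic=stat, groups=(values > cutoff).astype(int))


def log_rank_test(
    groups: Sequence, times: Sequence[float], events: Sequence[bool]
) -> tuple[float, float]:
    """Standard two-sided log-rank test; returns (statistic, p).

    p comes from a chi-square with (number of groups - 1) df.
    """
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank requires at least two groups")
    if not events.any():
        raise ValueError("log-rank requires at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def kaplan_meier(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence | None = None,
) -> dict:
    """Product-limit survival curves (and median) per group.

    Returns ``{group: {"timeline": array, "survival": array, "median": float}}``;
    with ``groups=None`` a single entry keyed ``"all"``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
        keys = {0: "all"}
    else:
        groups = np.asarray(groups)
        keys = {g: g for g in np.unique(groups)}
    out = {}
    for g, key in keys.items():
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        out[key] = {
            "timeline": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
            "median": float(kmf.median_survival_time_),
        }
    return out


def cox_ph_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariate_cols: Sequence[str] | None = None,
    ties: str = "efron",
) -> CoxModelResult:
    """Cox proportional-hazards fit (Efron ties by default).

    ``covariate_cols`` restricts the model terms; non-convergence is raised,
    never silenced.  Warns when there are fewer events than terms.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    if covariate_cols is not None:
        df = df[list(covariate_cols) + [duration_col, event_col]]
    terms = [c for c in df.columns if c not in (duration_col, event_col)]
    n_events = int(df[event_col].sum())
    if n_events < len(terms):
        warnings.warn(
            f"only {n_events} events for {len(terms)} model terms", stacklevel=2
        )
    # zero-variance terms cancel in the partial likelihood: HR 1, p 1
    constant = [t for t in terms if df[t].nunique() <= 1]
    varying = [t for t in terms if t not in constant]
    if constant:
        warnings.warn(f"constant covariates reported as null: {constant}", stacklevel=2)
    if varying and ties == "efron":
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df[varying + [duration_col, event_col]],
                duration_col=duration_col,
                event_col=event_col,
            )
        s = cph.summary
        summary = pd.DataFrame(
            {
                "hr": s["exp(coef)"],
                "ci_lower": s["exp(coef) lower 95%"],
                "ci_upper": s["exp(coef) upper 95%"],
                "p": s["p"],
            }
        )
        ll = float(cph.log_likelihood_)
    elif varying:  # breslow via statsmodels (lifelines implements Efron only)
        from statsmodels.duration.hazard_regression import PHReg

        model = PHReg(
            df[duration_col].to_numpy(float),
            df[varying].to_numpy(float),
            status=df[event_col].to_numpy(int),
            ties="breslow",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit()
        z = _stats.norm.ppf(0.975)
        summary = pd.DataFrame(
            {
                "hr": np.exp(fit.params),
                "ci_lower": np.exp(fit.params - z * fit.bse),
                "ci_upper": np.exp(fit.params + z * fit.bse),
                "p": fit.pvalues,
            },
            index=varying,
        )
        ll = float(model.loglike(fit.params))
    else:
        summary = pd.DataFrame(columns=["hr", "ci_lower", "ci_upper", "p"])
        ll = float("nan")
    for t in constant:
        summary.loc[t] = {"hr": 1.0, "ci_lower": 0.0, "ci_upper": np.inf, "p": 1.0}
    summary = summary.loc[terms]
    return CoxModelResult(summary=summary, log_likelihood=ll)


def twelve_month_outcome(
    times: Sequence[float], events: Sequence[bool], horizon: float = 365.0
) -> tuple[np.ndarray, int]:
    """Binary status at ``horizon`` days: 1 = event before horizon.

    Patients censored before the horizon without an event carry no 12-month
    status and are returned as NaN; their count is the second element.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out = np.where(events & (times <= horizon), 1.0, 0.0)
    undetermined = (~events) & (times < horizon)
    out[undetermined] = np.nan
    return out, int(undetermined.sum())


def _fit_auc(X: np.ndarray, y: np.ndarray) -> float:
    clf = LogisticRegression(C=1e4, max_iter=2000)
    clf.fit(X, y)
    return float(roc_auc_score(y, clf.decision_function(X)))


def incremental_auc(
    baseline: pd.DataFrame,
    features: pd.DataFrame,
    outcome: Sequence,
    n_boot: int = 2000,
    seed: int = 0,
    method: str = "bootstrap",
) -> AucComparison:
    """Compare in-sample AUCs of a baseline model vs baseline + features.

    Both models are logistic regressions; CIs come from a seeded paired
    bootstrap (refit on each resample).  The primary comparison p-value is a
    two-sided paired-bootstrap test of the AUC difference; ``method="anova"``
    reproduces a legacy one-way ANOVA on the bootstrap AUC samples.
    """
    if method not in ("bootstrap", "anova"):
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(outcome, dtype=float)
    keep = np.isfinite(y)
    y = y[keep].astype(int)
    Xb = _standardize(np.asarray(baseline, dtype=float)[keep])
    Xf = _standardize(np.asarray(features, dtype=float)[keep])
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    Xa = np.column_stack([Xb, Xf])
    auc_b = _fit_auc(Xb, y)
    auc_a = _fit_auc(Xa, y)

    rng = np.random.default_rng(seed)
    n = len(y)
    boots_b = np.empty(n_boot)
    boots_a = np.empty(n_boot)
    done = 0
    while done < n_boot:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue  # resample lost a class; redraw
        boots_b[done] = _fit_auc(Xb[idx], yb)
        boots_a[done] = _fit_auc(Xa[idx], yb)
        done += 1
    ci_b = tuple(np.percentile(boots_b, [2.5, 97.5]))
    ci_a = tuple(np.percentile(boots_a, [2.5, 97.5]))
    diff = boots_a - boots_b
    if method == "anova":
        p = float(_stats.f_oneway(boots_a, boots_b).pvalue)
    else:
        p_lo = float(np.mean(diff <= 0))
        p_hi = float(np.mean(diff >= 0))
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    return AucComparison(
        auc_baseline=auc_b,
        ci_baseline=(float(ci_b[0]), float(ci_b[1])),
        auc_augmented=auc_a,
        ci_augmented=(float(ci_a[0]), float(ci_a[1])),
        delta=auc_a - auc_b,
        p_value=p,
        n_boot=n_boot,
    )
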