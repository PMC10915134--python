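"""Survival analysis: median splits, Kaplan-Meier/log-rank, Cox models,
Harrell's concordance, repeated cross-validated model comparison and the
ISS / R-ISS / R2-ISS staging systems.

Cox models with Efron tie handling are fitted through lifelines; a compact
in-house Newton maximiser of the partial likelihood provides the Breslow
tie option (and doubles as an independently checkable route).  The
concordance index counts risk ties as 1/2 over usable pairs (the smaller
time of the pair is an event).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .io import ClinicalTable
from .stats import GroupComparisonResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Grouping and nonparametric survival
# ---------------------------------------------------------------------------


def median_split(scores: pd.Series) -> pd.Series:
    """Label samples 'high' (score > median) or 'low' (score <= median).

    Values equal to the median deterministically go to 'low'.  An
    all-identical score vector has no split and is an error.
    """
    s = pd.Series(scores, dtype=float)
    if s.size < 2:
        raise ValueError("median split needs >= 2 samples")
    if s.nunique() == 1:
        raise ValueError("all scores identical; median split is degenerate")
    med = float(np.median(s.to_numpy()))
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")


@dataclass(frozen=True)
class KMLogrankResult:
    curves: dict  # group -> survival-function DataFrame (index time, column S)
    chi_square: float
    p_value: float
    df: int
    group_sizes: dict


def km_logrank(times, events, group_labels) -> KMLogrankResult:
    """Kaplan-Meier curves per group and the log-rank test across groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(group_labels)
    if times.size != events.size or times.size != groups.size:
        raise ValueError("times, events and groups must have equal length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if events.sum() == 0:
        raise ValueError("no events observed; log-rank undefined")
    curves = {}
    sizes = {}
    for g in labels:
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        km = KaplanMeierFitter()
        km.fit(times[mask], events[mask], label=str(g))
        curves[g] = km.survival_function_
        sizes[g] = int(mask.sum())
    res = multivariate_logrank_test(times, groups, events)
    return KMLogrankResult(
        curves=curves,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        df=len(labels) - 1,
        group_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    """Per-covariate estimates from a Cox proportional-hazards fit."""

    summary: pd.DataFrame  # index covariate; coef, hr, ci_low, ci_high, se, p
    log_likelihood: float
    converged: bool
    ties: str

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def coef(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "coef"])


def _cox_loglik_breslow(beta, times, events, X):
    """Breslow partial log-likelihood, gradient and Hessian."""
    eta = X @ beta
    order = np.argsort(-times, kind="stable")  # descending time
    Xo, eo, to = X[order], events[order], times[order]
    w = np.exp(eta[order])
    ll, grad = 0.0, np.zeros(X.shape[1])
    hess = np.zeros((X.shape[1], X.shape[1]))
    s0 = 0.0
    s1 = np.zeros(X.shape[1])
    s2 = np.zeros((X.shape[1], X.shape[1]))
    i = 0
    n = len(to)
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        for k in range(i, j):  # everyone at this time enters the risk set
            s0 += w[k]
            s1 += w[k] * Xo[k]
            s2 += w[k] * np.outer(Xo[k], Xo[k])
        for k in range(i, j):
            if eo[k]:
                ll += (Xo[k] @ beta) - math.log(s0)
                grad += Xo[k] - s1 / s0
                hess -= s2 / s0 - np.outer(s1, s1) / s0**2
        i = j
    return ll, grad, hess


def _cox_newton(times, events, X, max_iter=100, tol=1e-9):
    beta = np.zeros(X.shape[1])
    ll_prev = -np.inf
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik_breslow(beta, times, events, X)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, ll, hess, False
        beta_new = beta - step
        # step-halving for stability
        for _ in range(30):
            ll_new = _cox_loglik_breslow(beta_new, times, events, X)[0]
            if ll_new >= ll - 1e-12:
                break
            beta_new = (beta + beta_new) / 2.0
        beta = beta_new
        if np.abs(grad).max() < tol or abs(ll - ll_prev) < tol:
            ll, grad, hess = _cox_loglik_breslow(beta, times, events, X)
            diverged = np.abs(beta).max() > 10
            return beta, ll, hess, not diverged
        ll_prev = ll
    ll, grad, hess = _cox_loglik_breslow(beta, times, events, X)
    return beta, ll, hess, np.abs(beta).max() <= 10


def cox_fit(times, events, covariates: pd.DataFrame, ties: str = "efron") -> CoxResult:
    """Fit a Cox proportional-hazards model.

    ``ties='efron'`` (default) uses lifelines' Newton fit; ``'breslow'``
    uses the in-house partial-likelihood maximiser.  Monotone likelihood
    (complete separation) is reported as a non-converged result with
    signed-infinite coefficients rather than an exception.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = pd.DataFrame(covariates).astype(float)
    if events.sum() == 0:
        raise ValueError("Cox model needs >= 1 event")
    const = X.nunique() <= 1
    if const.any():
        raise ValueError(f"constant covariates: {list(X.columns[const])}")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")

    if ties == "efron":
        df = X.copy()
        df["_time"] = times
        df["_event"] = events
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(
                    df,
                    duration_col="_time",
                    event_col="_event",
                    fit_options={"precision": 1e-9},
                )
        except ConvergenceError:
            return _separation_result(times, events, X, ties)
        s = cph.summary
        if not np.isfinite(s["coef"].to_numpy()).all() or np.abs(
            s["coef"].to_numpy()
        ).max() > 10:
            return _separation_result(times, events, X, ties)
        summary = pd.DataFrame(
            {
                "coef": s["coef"],
                "hr": s["exp(coef)"],
                "se": s["se(coef)"],
                "ci_low": s["exp(coef) lower 95%"],
                "ci_high": s["exp(coef) upper 95%"],
                "p": s["p"],
            }
        )
        summary.index = list(X.columns)
        return CoxResult(
            summary=summary,
            log_likelihood=float(cph.log_likelihood_),
            converged=True,
            ties="efron",
        )

    beta, ll, hess, converged = _cox_newton(times, events, X.to_numpy())
    if not converged:
        return _separation_result(times, events, X, ties)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    zcrit = sps.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "ci_low": np.exp(beta - zcrit * se),
            "ci_high": np.exp(beta + zcrit * se),
            "p": 2.0 * sps.norm.sf(np.abs(beta) / se),
        },
        index=list(X.columns),
    )
    return CoxResult(summary=summary, log_likelihood=float(ll), converged=True, ties="breslow")


def _separation_result(times, events, X, ties) -> CoxResult:
    """Monotone-likelihood report: signed infinite coefficients by the score
    direction at beta = 0."""
    _, grad, _ = _cox_loglik_breslow(np.zeros(X.shape[1]), times, events, X.to_numpy())
    signs = np.sign(grad)
    summary = pd.DataFrame(
        {
            "coef": signs * np.inf,
            "hr": np.exp(signs * np.inf),
            "se": np.inf,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
        },
        index=list(X.columns),
    )
    logger.warning("Cox fit did not converge (monotone likelihood suspected)")
    return CoxResult(summary=summary, log_likelihood=np.nan, converged=False, ties=ties)


def harrell_c(times, events, risk_scores) -> float:
    """Harrell's concordance index of a risk score against survival.

    A pair is usable when the smaller time is an event; concordance means
    the shorter-surviving member has the higher risk; risk ties count 1/2.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risk = np.asarray(risk_scores, dtype=float)
    if events.sum() == 0:
        raise ValueError("no usable pairs: no events")
    try:
        # lifelines counts concordance for higher-score = longer survival,
        # so negate the risk.
        return float(concordance_index(times, -risk, events))
    except ZeroDivisionError as exc:
        raise ValueError("no usable pairs for the concordance index") from exc


# ---------------------------------------------------------------------------
# Repeated cross-validated model comparison
# ---------------------------------------------------------------------------


@dataclass
class CVComparisonResult:
    c_indexes: pd.DataFrame  # rows = repeat x fold, one column per model
    mean_c: pd.Series
    pairwise_p: pd.DataFrame
    repeats: int
    folds: int
    seed: int


def cv_compare_models(
    data: pd.DataFrame,
    model_specs: dict[str, list[str]],
    time_col: str = "os_time",
    event_col: str = "os_event",
    repeats: int = 100,
    folds: int = 5,
    seed: int = 0,
    ties: str = "breslow",
) -> CVComparisonResult:
    """Compare Cox model specifications by repeated k-fold cross-validation.

    For each repeat an event-stratified k-fold split is drawn; every model
    is fitted on the training folds and scored by the held-out concordance
    of its linear predictor.  All models see identical folds, so the
    repeats x folds concordance vectors are paired; pairwise p values come
    from the Wilcoxon signed-rank test on the per-fold differences.  A fold
    whose test part has no usable pair triggers one refold with an offset
    seed (logged) before failing.
    """
    cols = sorted({c for cov in model_specs.values() for c in cov})
    needed = [time_col, event_col, *cols]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    cc = data[needed].dropna()
    if len(cc) < 10 * max(len(v) for v in model_specs.values()):
        raise ValueError(
            f"complete cases ({len(cc)}) below 10 x covariate count"
        )
    cc = cc.sort_index()  # order-invariance given the same seed
    times = cc[time_col].to_numpy(dtype=float)
    events = cc[event_col].to_numpy(dtype=int)

    names = list(model_specs)
    rows = []
    for rep in range(repeats):
        for attempt in range(5):
            skf = StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=(seed + 1) * 10_000 + rep * 7 + attempt
            )
            try:
                fold_rows = _run_one_repeat(
                    skf, cc, times, events, model_specs, names, ties
                )
                break
            except ValueError:
                logger.warning("repeat %d attempt %d failed; refolding", rep, attempt)
        else:
            raise ValueError(f"repeat {rep}: persistent fold failure")
        rows.extend(fold_rows)
    cidx = pd.DataFrame(rows, columns=names)
    pairwise = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = cidx[a].to_numpy() - cidx[b].to_numpy()
            if np.allclose(diff, 0):
                p = 1.0
            else:
                p = float(sps.wilcoxon(diff, zero_method="wilcox").pvalue)
            pairwise.loc[a, b] = pairwise.loc[b, a] = p
    return CVComparisonResult(
        c_indexes=cidx,
        mean_c=cidx.mean(),
        pairwise_p=pairwise,
        repeats=repeats,
        folds=folds,
        seed=seed,
    )


def _run_one_repeat(skf, cc, times, events, model_specs, names, ties):
    fold_rows = []
    for train_idx, test_idx in skf.split(np.zeros(len(cc)), events):
        if events[test_idx].sum() == 0 or events[train_idx].sum() == 0:
            raise ValueError("fold without events")
        row = []
        for name in names:
            covs = model_specs[name]
            fit = cox_fit(
                times[train_idx], events[train_idx], cc.iloc[train_idx][covs], ties=ties
            )
            if not fit.converged:
                raise ValueError("non-converged fold fit")
            risk = cc.iloc[test_idx][covs].to_numpy() @ fit.summary["coef"].to_numpy()
            row.append(harrell_c(times[test_idx], events[test_idx], risk))
        fold_rows.append(row)
    return fold_rows


# ---------------------------------------------------------------------------
# Staging systems
# ---------------------------------------------------------------------------


def stage_iss(b2m, albumin):
    """International Staging System from beta2-microglobulin (mg/L) and
    serum albumin (g/dL): III if B2M >= 5.5; I if B2M < 3.5 and albumin
    >= 3.5; otherwise II.  Missing inputs propagate as missing."""
    b2m = pd.Series(np.atleast_1d(b2m), dtype=float)
    albumin = pd.Series(np.atleast_1d(albumin), dtype=float)
    out = pd.Series(np.nan, index=b2m.index, dtype=object)
    ok = b2m.notna() & albumin.notna()
    out[ok & (b2m >= 5.5)] = 3
    out[ok & (b2m < 5.5) & (b2m < 3.5) & (albumin >= 3.5)] = 1
    out[ok & out.isna()] = 2
    out[~ok] = np.nan
    return out.astype(float)


def stage_r_iss(iss, high_risk_ca, ldh_high):
    """Revised ISS: I if ISS I, no high-risk cytogenetics (del17p, t(4;14)
    or t(14;16)) and normal LDH; III if ISS III with high-risk cytogenetics
    or elevated LDH; otherwise II."""
    iss = pd.Series(np.atleast_1d(iss), dtype=float)
    ca = pd.Series(np.atleast_1d(high_risk_ca))
    ldh = pd.Series(np.atleast_1d(ldh_high))
    out = pd.Series(np.nan, index=iss.index, dtype=float)
    ok = iss.notna() & ca.notna() & ldh.notna()
    ca_b = ca.fillna(False).astype(bool)
    ldh_b = ldh.fillna(False).astype(bool)
    out[ok & (iss == 1) & ~ca_b & ~ldh_b] = 1
    out[ok & (iss == 3) & (ca_b | ldh_b)] = 3
    out[ok & out.isna()] = 2
    return out


R2_ISS_GROUPS = ((0.0, 0.0, "Low"), (0.5, 1.0, "Low-Int"), (1.5, 2.5, "Int-High"), (3.0, 5.0, "High"))


def stage_r2_iss(iss, del17p, t4_14, gain1q, ldh_high):
    """Second revision of the ISS: additive risk points
    (ISS II: 1; ISS III: 1.5; del17p: 1; high LDH: 1; t(4;14): 1;
    gain1q: 0.5) mapped to four groups."""
    iss = pd.Series(np.atleast_1d(iss), dtype=float)
    flags = [pd.Series(np.atleast_1d(f)) for f in (del17p, t4_14, gain1q, ldh_high)]
    ok = iss.notna()
    for f in flags:
        ok &= f.notna()
    del17p_b, t4_14_b, gain1q_b, ldh_b = [f.fillna(False).astype(bool) for f in flags]
    score = (
        1.0 * (iss == 2)
        + 1.5 * (iss == 3)
        + 1.0 * del17p_b
        + 1.0 * ldh_b
        + 1.0 * t4_14_b
        + 0.5 * gain1q_b
    )
    score[~ok] = np.nan
    group = pd.Series(np.nan, index=iss.index, dtype=object)
    for lo, hi, label in R2_ISS_GROUPS:
        group[score.between(lo, hi)] = label
    return pd.DataFrame({"r2_iss_score": score, "r2_iss_group": group})


def add_stages(clinical: ClinicalTable) -> ClinicalTable:
    """Derive iss / r_iss / r2_iss columns from the raw staging inputs."""
    d = clinical.data.copy()
    if {"b2m", "albumin"} <= set(d.columns):
        iss = stage_iss(d["b2m"].to_numpy(), d["albumin"].to_numpy())
        iss.index = d.index
        d["iss"] = iss
    if "iss" in d.columns:
        hr_ca = pd.Series(False, index=d.index)
        have_ca = False
        for flag in ("del17p", "t_4_14", "t_14_16"):
            if flag in d.columns:
                hr_ca |= d[flag].fillna(False).astype(bool)
                have_ca = True
        if "ldh" in d.columns and "ldh_uln" in d.columns:
            ldh_high = d["ldh"] > d["ldh_uln"]
        elif "ldh_high" in d.columns:
            ldh_high = d["ldh_high"].astype(bool)
        else:
            ldh_high = None
        if have_ca and ldh_high is not None:
            r = stage_r_iss(d["iss"].to_numpy(), hr_ca.to_numpy(), ldh_high.to_numpy())
            r.index = d.index
            d["r_iss"] = r
            if {"del17p", "t_4_14", "gain1q"} <= set(d.columns):
                r2 = stage_r2_iss(
                    d["iss"].to_numpy(),
                    d["del17p"].to_numpy(),
                    d["t_4_14"].to_numpy(),
                    d["gain1q"].to_numpy(),
                    ldh_high.to_numpy(),
                )
                r2.index = d.index
                d[["r2_iss_score", "r2_iss_group"]] = r2
    return ClinicalTable(d)
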