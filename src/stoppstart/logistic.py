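"""Logit-link binomial regression and its diagnostics.

Implements the modelling procedure used for predictor analysis in medication
review studies: maximum-likelihood logistic regression (iteratively
reweighted least squares), forward covariate selection driven by the Wald
test, adjusted odds ratios, the Hosmer-Lemeshow calibration test on deciles
of risk, the rank-based (Mann-Whitney) ROC area, and the probability cutoff
at which sensitivity and specificity are simultaneously maximized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "ModelDiagnostics",
    "fit_logistic",
    "forward_select",
    "hosmer_lemeshow",
    "roc_auc",
    "joint_cutoff",
    "diagnostics",
]

MAX_ITER = 25
SCORE_TOL = 1e-8
LL_RTOL = 1e-10
SEPARATION_BETA = 30.0  # |beta| beyond this flags quasi-separation


class LogisticError(ValueError):
    """Raised for unusable designs (no outcome variation, rank deficiency)."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (intercept first)."""

    names: list[str]  # includes "intercept"
    coef: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    ll_trace: list[float]
    converged: bool
    n_iterations: int
    n_obs: int
    separation: bool = False

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def wald_z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def or_ci_low(self) -> np.ndarray:
        z = stats.norm.ppf(0.975)
        return np.exp(self.coef - z * self.se)

    @property
    def or_ci_high(self) -> np.ndarray:
        z = stats.norm.ppf(0.975)
        return np.exp(self.coef + z * self.se)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = self.coef[0] + X @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "wald_z": self.wald_z,
                "p": self.p_values,
                "or": self.odds_ratios,
                "or_ci_low": self.or_ci_low,
                "or_ci_high": self.or_ci_high,
            },
            index=self.names,
        )


def _check_design(X: np.ndarray, names: list[str]) -> None:
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # name the columns involved in the collinearity
        bad = []
        for j in range(p):
            others = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise LogisticError(f"rank-deficient design; collinear columns: {bad or names}")


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    weights: np.ndarray | None = None,
) -> LogisticFit:
    """Fit logit(p) = b0 + X b by iteratively reweighted least squares.

    ``X`` excludes the intercept column (added internally).  ``weights`` are
    optional frequency weights, so grouped 2x2 data can be fitted directly.
    Convergence: max |score| < 1e-8 or relative log-likelihood change
    < 1e-10, within 25 iterations.  Quasi-separation is flagged, not raised.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y).ravel()) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    if len(names) != p:
        raise LogisticError("names must match the number of design columns")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float).ravel()
    if y.shape[0] != n or w.shape[0] != n:
        raise LogisticError("X, y and weights must have matching length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise LogisticError("outcome must be binary (0/1)")
    ybar = np.average(y, weights=w)
    if ybar in (0.0, 1.0):
        raise LogisticError("outcome has no variation (all 0 or all 1)")
    if w.sum() <= p + 1:
        raise LogisticError("more parameters than observations")
    _check_design(X, list(names))

    design = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    beta[0] = math.log(ybar / (1.0 - ybar))  # intercept at the observed logit

    def loglik(b: np.ndarray) -> float:
        eta = design @ b
        return float(np.sum(w * (y * eta - np.log1p(np.exp(eta)))))

    ll = loglik(beta)
    trace = [ll]
    converged = False
    it = 0
    info = np.eye(p + 1)
    for it in range(1, MAX_ITER + 1):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wls = w * mu * (1.0 - mu)
        score = design.T @ (w * (y - mu))
        info = design.T @ (design * wls[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            info += 1e-8 * np.eye(p + 1)
            step = np.linalg.solve(info, score)
        # step-halving keeps the likelihood non-decreasing
        new_beta = beta + step
        new_ll = loglik(new_beta)
        halvings = 0
        while new_ll < ll and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            new_ll = loglik(new_beta)
            halvings += 1
        beta, prev_ll, ll = new_beta, ll, new_ll
        trace.append(ll)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        if abs(ll - prev_ll) <= LL_RTOL * (abs(prev_ll) + LL_RTOL):
            converged = True
            break

    separation = bool(np.max(np.abs(beta)) > SEPARATION_BETA)
    if separation:
        logger.warning("quasi-separation suspected (|beta| > %.0f)", SEPARATION_BETA)
        converged = False
    if not converged and not separation:
        logger.warning("logistic fit did not converge in %d iterations", it)
    # observed information at the final estimate
    eta = design @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    wls = w * mu * (1.0 - mu)
    info = design.T @ (design * wls[:, None])
    cov = np.linalg.pinv(info)
    return LogisticFit(
        names=["intercept"] + list(names),
        coef=beta,
        cov=cov,
        log_likelihood=ll,
        ll_trace=trace,
        converged=converged,
        n_iterations=it,
        n_obs=int(n),
        separation=separation,
    )


@dataclass
class SelectionStep:
    added: str
    p_wald: float
    log_likelihood: float


@dataclass
class ForwardSelectionResult:
    fit: LogisticFit
    selected: list[str]
    trace: list[SelectionStep]
    reported: list[str]  # covariates with p < p_report in the final model
    note: str = ""


def forward_select(
    frame: pd.DataFrame,
    y: np.ndarray,
    candidates: list[str] | None = None,
    p_enter: float = 0.05,
    p_report: float = 0.1,
) -> ForwardSelectionResult:
    """Forward selection on the Wald test.

    At each step the candidate with the smallest Wald p-value below
    ``p_enter`` joins the model; selection stops when none qualifies.  The
    final report lists covariates with p < ``p_report``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if candidates is None:
        candidates = list(frame.columns)
    missing = [c for c in candidates if c not in frame.columns]
    if missing:
        raise LogisticError(f"candidate covariates absent from frame: {missing}")
    selected: list[str] = []
    trace: list[SelectionStep] = []
    remaining = list(candidates)
    while remaining:
        best: tuple[float, str, LogisticFit] | None = None
        for cand in remaining:
            cols = selected + [cand]
            try:
                fit = fit_logistic(frame[cols].to_numpy(dtype=float), y, names=cols)
            except LogisticError:
                continue
            if not fit.converged:
                continue
            p_cand = float(fit.p_values[-1])
            if best is None or p_cand < best[0]:
                best = (p_cand, cand, fit)
        if best is None or best[0] >= p_enter:
            break
        p_cand, cand, fit = best
        selected.append(cand)
        remaining.remove(cand)
        trace.append(SelectionStep(added=cand, p_wald=p_cand, log_likelihood=fit.log_likelihood))

    if not selected:
        ones = np.zeros((len(y), 0))
        # intercept-only fit
        ybar = float(np.mean(y))
        beta = np.array([math.log(ybar / (1 - ybar))])
        ll = float(np.sum(y * beta[0] - np.log1p(np.exp(beta[0]))))
        fit = LogisticFit(
            names=["intercept"],
            coef=beta,
            cov=np.array([[1.0 / (len(y) * ybar * (1 - ybar))]]),
            log_likelihood=ll,
            ll_trace=[ll],
            converged=True,
            n_iterations=0,
            n_obs=len(y),
        )
        return ForwardSelectionResult(
            fit=fit,
            selected=[],
            trace=[],
            reported=[],
            note="no candidate passed the entry threshold; intercept-only model",
        )

    final = fit_logistic(frame[selected].to_numpy(dtype=float), y, names=selected)
    reported = [
        name
        for name, p in zip(final.names[1:], final.p_values[1:])
        if p < p_report
    ]
    return ForwardSelectionResult(fit=final, selected=selected, trace=trace, reported=reported)


def hosmer_lemeshow(
    probs: np.ndarray, y: np.ndarray, n_groups: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow calibration chi-square over groups of fitted risk.

    Patients are grouped into ``n_groups`` quantile bins of fitted
    probability (tied probabilities stay in one group); groups whose expected
    count is zero are merged with a neighbour.  Returns (statistic, df, p)
    with df = groups - 2.
    """
    probs = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if n_groups < 3:
        raise ValueError("n_groups must be >= 3")
    if probs.shape != y.shape:
        raise ValueError("probs and y must have the same length")
    bins = pd.qcut(probs, q=n_groups, duplicates="drop")
    grouped = pd.DataFrame({"p": probs, "y": y, "g": bins}).groupby("g", observed=True)
    table = grouped.agg(n=("y", "size"), obs=("y", "sum"), exp=("p", "sum"))
    # merge degenerate groups (expected 0 or expected = n) with a neighbour
    rows = table.to_numpy(dtype=float).tolist()
    merged: list[list[float]] = []
    for row in rows:
        n_g, obs, exp = row
        if merged and (exp <= 1e-12 or n_g - exp <= 1e-12):
            merged[-1] = [merged[-1][0] + n_g, merged[-1][1] + obs, merged[-1][2] + exp]
        else:
            merged.append([n_g, obs, exp])
    if len(merged) >= 2 and (
        merged[0][2] <= 1e-12 or merged[0][0] - merged[0][2] <= 1e-12
    ):
        first = merged.pop(0)
        merged[0] = [merged[0][0] + first[0], merged[0][1] + first[1], merged[0][2] + first[2]]
    if len(merged) < len(rows):
        logger.info("Hosmer-Lemeshow: merged %d degenerate group(s)", len(rows) - len(merged))
    stat = 0.0
    for n_g, obs, exp in merged:
        denom = exp * (1.0 - exp / n_g)
        if denom <= 0:
            continue
        stat += (obs - exp) ** 2 / denom
    df = max(1, len(merged) - 2)
    return float(stat), int(df), float(stats.chi2.sf(stat, df))


def roc_auc(probs: np.ndarray, y: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties half credit."""
    probs = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(y, dtype=int).ravel()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise LogisticError("both outcome classes must be present for the AUC")
    ranks = stats.rankdata(probs)
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def joint_cutoff(probs: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Probability cutoff maximizing min(sensitivity, specificity).

    Ties break toward the larger sensitivity+specificity sum, then toward
    the smaller threshold.  Classification rule: positive if prob >= cutoff.
    """
    probs = np.asarray(probs, dtype=float).ravel()
    y = np.asarray(y, dtype=int).ravel()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise LogisticError("both outcome classes must be present for a cutoff")
    best: tuple[float, float, float, float, float] | None = None
    for t in np.unique(probs):
        pred = probs >= t
        sens = float((pred & (y == 1)).sum()) / n_pos
        spec = float((~pred & (y == 0)).sum()) / n_neg
        key = (min(sens, spec), sens + spec, -t)
        if best is None or key > (best[0], best[1], -best[2]):
            best = (min(sens, spec), sens + spec, float(t), sens, spec)
    assert best is not None
    if best[0] == 0.0:
        logger.warning("degenerate cutoff: min(sensitivity, specificity) is 0")
    return best[2], best[3], best[4]


@dataclass
class ModelDiagnostics:
    """Fit diagnostics mirroring the footnotes of predictor tables."""

    omnibus_p: float
    hl_statistic: float
    hl_df: int
    hl_p: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float


def diagnostics(
    fit: LogisticFit, X: np.ndarray, y: np.ndarray, n_groups: int = 10
) -> ModelDiagnostics:
    """Omnibus LR test, Hosmer-Lemeshow, AUC (Hanley-McNeil CI) and cutoff."""
    y = np.asarray(y, dtype=float).ravel()
    probs = fit.predict(np.asarray(X, dtype=float))
    ybar = float(np.mean(y))
    ll_null = float(np.sum(y * math.log(ybar) + (1 - y) * math.log(1 - ybar)))
    lr = 2.0 * (fit.log_likelihood - ll_null)
    df = len(fit.coef) - 1
    omnibus_p = float(stats.chi2.sf(max(lr, 0.0), max(df, 1)))
    hl_stat, hl_df, hl_p = hosmer_lemeshow(probs, y, n_groups=n_groups)
    auc = roc_auc(probs, y)
    n1 = float((y == 1).sum())
    n0 = float((y == 0).sum())
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    half = stats.norm.ppf(0.975) * math.sqrt(max(var, 0.0))
    cutoff, sens, spec = joint_cutoff(probs, y)
    return ModelDiagnostics(
        omnibus_p=omnibus_p,
        hl_statistic=hl_stat,
        hl_df=hl_df,
        hl_p=hl_p,
        auc=auc,
        auc_ci_low=max(0.0, auc - half),
        auc_ci_high=min(1.0, auc + half),
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
    )
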