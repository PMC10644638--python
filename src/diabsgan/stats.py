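"""Correlation and logistic-regression feature analysis.

``pearson_matrix`` computes the pairwise Pearson correlation
ρ = cov(X, Y)/(σ_X σ_Y) with sample moments; zero-variance columns produce
NaN entries and are flagged rather than silently zeroed.

``fit_logistic`` fits a multivariate binary logistic regression by
iteratively reweighted least squares (Newton's method on the
log-likelihood) and reports the usual Wald-inference column set per
predictor: coefficient, standard error (from the inverse observed
information), Wald statistic (coef/se)² tested against χ²₁, two-sided
p-value, odds ratio exp(coef), and 95% CI exp(coef ± 1.96·se).  The modeled
event level is explicit: flipping it negates every coefficient and inverts
every odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationMatrix",
    "LogisticFit",
    "pearson_matrix",
    "fit_logistic",
    "significance_stars",
]


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray
    feature_names: list[str]
    undefined: list[str] = field(default_factory=list)  # zero-variance columns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.feature_names,
                            columns=self.feature_names)


def pearson_matrix(features: np.ndarray, feature_names: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlations; zero-variance columns flagged as NaN."""
    x = np.asarray(features, dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    names = feature_names or [f"x{j}" for j in range(p)]
    centered = x - x.mean(axis=0)
    sd = centered.std(axis=0, ddof=1)
    cov = centered.T @ centered / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    degenerate = sd == 0
    corr = np.clip(corr, -1.0, 1.0)  # guard rounding just past ±1; NaN passes
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    flagged = [names[j] for j in np.flatnonzero(degenerate)]
    return CorrelationMatrix(matrix=corr, feature_names=names, undefined=flagged)


@dataclass
class LogisticFit:
    """Fitted binary logistic model with Wald inference per predictor."""

    names: list[str]
    coefficients: np.ndarray  # intercept first
    std_errors: np.ndarray
    wald: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    event_level: int
    converged: bool
    n_iterations: int
    log_likelihood: float

    def to_frame(self, stars: bool = True) -> pd.DataFrame:
        """Report table: one row per term, intercept first."""
        frame = pd.DataFrame({
            "term": self.names,
            "coefficient": self.coefficients,
            "std_error": self.std_errors,
            "wald": self.wald,
            "p_value": self.p_values,
            "odds_ratio": self.odds_ratios,
            "ci_lower_95": self.ci_lower,
            "ci_upper_95": self.ci_upper,
        })
        if stars:
            frame["significance"] = [significance_stars(p) for p in self.p_values]
        return frame


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    event_level: int = 0,
    feature_names: list[str] | None = None,
    max_iter: int = 100,
    tol_score: float = 1e-8,
    tol_coef: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by Newton/IRLS.

    ``event_level`` selects which label value is modeled as the event
    (y = 1 internally).  Convergence when max |score| < ``tol_score`` or the
    max coefficient change < ``tol_coef``; iteration is capped and apparent
    perfect separation (diverging coefficients) yields a flagged
    non-converged fit rather than an exception.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"labels must be binary, got {uniq.size} levels")
    if event_level not in uniq:
        raise ValueError(f"event_level {event_level!r} not among labels {uniq}")
    y = (labels == event_level).astype(float)
    n, p = x.shape
    names = ["(intercept)"] + (feature_names or [f"x{j}" for j in range(p)])
    design = np.column_stack([np.ones(n), x])

    beta = np.zeros(p + 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = design.T @ (y - mu)
        info = design.T @ (design * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta_new = beta + step
        delta = float(np.max(np.abs(step)))
        beta = beta_new
        if float(np.max(np.abs(score))) < tol_score or delta < tol_coef:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e3:  # perfect-separation divergence guard
            break

    eta = design @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    # perfect separation: every fitted probability saturates at 0/1, the MLE
    # does not exist and coefficients diverge -> flag rather than crash
    if np.all((mu < 1e-6) | (mu > 1 - 1e-6)):
        converged = False
    loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    w = mu * (1.0 - mu)
    info = design.T @ (design * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p + 1, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (beta / se) ** 2
    p_values = sps.chi2.sf(wald, df=1)
    return LogisticFit(
        names=names,
        coefficients=beta,
        std_errors=se,
        wald=wald,
        p_values=p_values,
        odds_ratios=np.exp(beta),
        ci_lower=np.exp(beta - 1.96 * se),
        ci_upper=np.exp(beta + 1.96 * se),
        event_level=int(event_level),
        converged=converged,
        n_iterations=it,
        log_likelihood=loglik,
    )


def significance_stars(p_value: float) -> str:
    """Star markers at the 1%/5%/10% levels (strict inequalities)."""
    if not 0 <= p_value <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    if p_value < 0.01:
        return "***"
    if p_value < 0.05:
        return "**"
    if p_value < 0.10:
        return "*"
    return ""
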