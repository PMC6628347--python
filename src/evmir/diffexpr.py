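"""Two-group differential expression with empirical-Bayes variance moderation.

Expression is taken as −delta-Ct, so one cycle equals one log2 unit of
abundance and "downregulated in cases" carries a negative logFC.  Per probe g
with groups of sizes n1 (case) and n2 (control):

    logFC_g = mean(case) − mean(control)
    s_g^2   = pooled residual variance,  d_g = n1 + n2 − 2

A scaled inverse-chi-square prior  s_g^2 ~ s0^2 * d0 / chi^2_{d0}  is fitted
across probes by the method of moments on  z_g = log s_g^2  (whose moments
involve the digamma/trigamma functions), giving the prior degrees of freedom
d0 and prior variance s0^2.  The moderated statistic replaces s_g^2 with the
shrunken

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and refers  t = logFC / (s~ * sqrt(1/n1 + 1/n2))  to a t distribution on
d0 + d_g degrees of freedom.  When the between-probe spread of z_g is no
larger than its sampling noise, d0 is infinite and every probe shares s0^2.
P-values are Benjamini-Hochberg adjusted; the published significance rule is
adjusted p < 0.05 (strict) together with |logFC| >= 1 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import GROUP_CASE, GROUP_CONTROL
from .preprocess import NormalizedMatrix

__all__ = [
    "ExpressionMatrix",
    "EBayesPrior",
    "to_expression",
    "fit_group_model",
    "estimate_prior",
    "inverse_trigamma",
    "moderated_t",
    "bh_adjust",
    "select_significant",
    "ModeratedTTest",
]


@dataclass
class ExpressionMatrix:
    """Relative expression (−delta-Ct, log2-abundance scale) with group labels."""

    values: pd.DataFrame  # probes x samples
    groups: pd.Series  # sample -> case/control

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[list(self.values.columns)]


@dataclass
class EBayesPrior:
    """Scaled inverse-chi-square prior on per-probe variances."""

    d0: float  # prior degrees of freedom, may be inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):  # inf passes
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def to_expression(nm: NormalizedMatrix, meta: pd.Series) -> ExpressionMatrix:
    """Flip delta-Ct to the abundance scale: expression = −delta-Ct."""
    return ExpressionMatrix(values=-nm.dct, groups=meta)


def fit_group_model(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-probe two-group linear fit: logFC, pooled variance, residual df.

    NaN values (the optional censoring mask) are dropped per probe and group;
    a probe with fewer than two finite values in either group is flagged
    (``ok = False``) with NaN statistics and is excluded from prior
    estimation downstream.
    """
    case_cols = em.groups.index[em.groups == GROUP_CASE]
    ctrl_cols = em.groups.index[em.groups == GROUP_CONTROL]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    xc = em.values[case_cols].to_numpy(float)
    xk = em.values[ctrl_cols].to_numpy(float)
    nc = np.sum(np.isfinite(xc), axis=1)
    nk = np.sum(np.isfinite(xk), axis=1)
    ok = (nc >= 2) & (nk >= 2)

    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mc = np.nanmean(np.where(np.isfinite(xc), xc, np.nan), axis=1)
        mk = np.nanmean(np.where(np.isfinite(xk), xk, np.nan), axis=1)
        vc = np.nanvar(np.where(np.isfinite(xc), xc, np.nan), axis=1, ddof=1)
        vk = np.nanvar(np.where(np.isfinite(xk), xk, np.nan), axis=1, ddof=1)
    logfc = mc - mk
    df_res = nc + nk - 2.0
    s_sq = ((nc - 1) * vc + (nk - 1) * vk) / df_res
    logfc[~ok] = np.nan
    s_sq[~ok] = np.nan
    df_res = np.where(ok, df_res, np.nan)
    return pd.DataFrame(
        {
            "logfc": logfc,
            "s_sq": s_sq,
            "df_residual": df_res,
            "n_case": nc,
            "n_control": nk,
            "ok": ok,
        },
        index=em.values.index,
    )


def inverse_trigamma(y: float, tol: float = 1e-12, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma.

    1/trigamma is nearly linear, so convergence is fast from the starting
    value 0.5 + 1/y.
    """
    if y <= 0:
        raise ValueError("trigamma is positive; y must be > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def estimate_prior(s_sq: np.ndarray, df: np.ndarray) -> EBayesPrior:
    """Method-of-moments fit of the variance prior across probes.

    With z_g = log s_g^2, E[z_g] = log s0^2 + psi(d_g/2) − log(d_g/2) +
    bias terms in d0, and Var[z_g] = psi'(d_g/2) + psi'(d0/2).  Setting the
    empirical variance of e_g = z_g − psi(d_g/2) + log(d_g/2) against its
    expectation yields psi'(d0/2), inverted by Newton iteration; when the
    moment expression is non-positive the prior is degenerate (d0 infinite,
    all probes share s0^2 = exp(mean e)).
    """
    s_sq = np.asarray(s_sq, float)
    df = np.asarray(df, float)
    keep = np.isfinite(s_sq) & np.isfinite(df) & (df > 0)
    s_sq, df = s_sq[keep], df[keep]
    if s_sq.size < 2:
        raise ValueError("need at least 2 probes with positive df to fit the prior")
    if np.all(s_sq <= 0):
        raise ValueError("degenerate variances: all residual variances are zero")
    # probes with zero variance cannot enter the log; floor at a tiny value
    z = np.log(np.maximum(s_sq, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(np.mean(e))
    G = e.size
    mom = float(np.mean((e - e_bar) ** 2 * G / (G - 1) - special.polygamma(1, df / 2.0)))
    if mom > 0:
        d0 = 2.0 * inverse_trigamma(mom)
        s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return EBayesPrior(d0=d0, s0_sq=s0_sq)
    # zero (or negative) excess spread: infinitely strong prior; the d0->inf
    # limit of digamma(d0/2) - log(d0/2) is 0
    return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(e_bar)))


def moderated_t(
    fit: pd.DataFrame, prior: EBayesPrior, n_case: int | None = None, n_control: int | None = None
) -> pd.DataFrame:
    """Shrink per-probe variances toward the prior and test logFC = 0.

    d0 = 0 recovers the ordinary pooled two-sample t exactly; d0 = inf uses
    the prior variance for every probe.
    """
    logfc = fit["logfc"].to_numpy(float)
    s_sq = fit["s_sq"].to_numpy(float)
    d_g = fit["df_residual"].to_numpy(float)
    nc = fit["n_case"].to_numpy(float) if n_case is None else float(n_case)
    nk = fit["n_control"].to_numpy(float) if n_control is None else float(n_control)
    d0 = prior.d0
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
        df_total = np.full_like(s_sq, np.inf)
    else:
        s_tilde_sq = (d0 * prior.s0_sq + d_g * s_sq) / (d0 + d_g)
        df_total = d0 + d_g
    se = np.sqrt(s_tilde_sq * (1.0 / nc + 1.0 / nk))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = fit.copy()
    out["s_tilde_sq"] = s_tilde_sq
    out["t"] = t
    out["df_total"] = df_total
    out["p_value"] = p
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    NaN entries (flagged probes) stay NaN and do not enter the adjustment.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def select_significant(
    results: pd.DataFrame,
    adj_p_threshold: float = 0.05,
    abs_logfc_threshold: float = 1.0,
    adj_p_col: str = "adj_p_value",
    logfc_col: str = "logfc",
) -> pd.DataFrame:
    """The published significance rule: adj p < threshold (strict) AND
    |logFC| >= threshold (inclusive)."""
    if adj_p_threshold <= 0 or abs_logfc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    mask = (results[adj_p_col] < adj_p_threshold) & (
        results[logfc_col].abs() >= abs_logfc_threshold
    )
    return results[mask.fillna(False)]


class ModeratedTTest(BaseEstimator):
    """Sklearn-style estimator for moderated two-group differential expression.

    ``fit(X, y)`` takes the sklearn orientation (rows = samples, columns =
    probes/features) and binary group labels; the fitted result table is in
    ``results_`` with one row per feature.

    Parameters
    ----------
    positive_label : hashable, default "case"
        The label treated as the case group; logFC is case minus control.

    Attributes
    ----------
    results_ : DataFrame with logfc, s_sq, df_residual, s_tilde_sq, t,
        df_total, p_value, adj_p_value per feature.
    prior_ : EBayesPrior with the fitted (d0, s0_sq).
    """

    def __init__(self, positive_label="case"):
        self.positive_label = positive_label

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            values = X.T.astype(float)
        else:
            X = np.asarray(X, dtype=float)
            values = pd.DataFrame(
                X.T, index=[f"feature_{j}" for j in range(X.shape[1])]
            )
        y = np.asarray(y)
        if y.shape[0] != values.shape[1]:
            raise ValueError("X and y have inconsistent numbers of samples")
        labels = np.unique(y)
        if len(labels) != 2:
            raise ValueError("y must contain exactly two classes")
        if self.positive_label in labels:
            pos = self.positive_label
        else:
            pos = labels.max()
        groups = pd.Series(
            np.where(y == pos, GROUP_CASE, GROUP_CONTROL),
            index=values.columns,
        )
        em = ExpressionMatrix(values=values, groups=groups)
        fit = fit_group_model(em)
        ok = fit["ok"].to_numpy()
        self.prior_ = estimate_prior(
            fit.loc[ok, "s_sq"].to_numpy(), fit.loc[ok, "df_residual"].to_numpy()
        )
        res = moderated_t(fit, self.prior_)
        res["adj_p_value"] = bh_adjust(res["p_value"].to_numpy())
        self.results_ = res
        self.n_features_in_ = values.shape[0]
        return self

    def significant(self, adj_p_threshold=0.05, abs_logfc_threshold=1.0) -> pd.DataFrame:
        if not hasattr(self, "results_"):
            raise ValueError("ModeratedTTest is not fitted")
        return select_significant(self.results_, adj_p_threshold, abs_logfc_threshold)


def run_diffexpr(nm: NormalizedMatrix, meta: pd.Series) -> pd.DataFrame:
    """Convenience wrapper: normalized matrix + groups -> full DE result table."""
    em = to_expression(nm, meta)
    est = ModeratedTTest().fit(em.values.T, em.groups.to_numpy())
    res = est.results_.copy()
    res.attrs["d0"] = est.prior_.d0
    res.attrs["s0_sq"] = est.prior_.s0_sq
    return res
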