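"""Per-probe univariate logistic classification under repeated 3:2 holdout.

Each candidate probe's relative expression is fitted alone in a logistic
regression on a stratified 60% training split and scored on the held-out 40%;
the split/fit/score cycle is repeated (500 times by default) and validation
AUC, accuracy, sensitivity and specificity are aggregated.  The AUC 95% CI is
the 2.5th/97.5th percentile of the repetition AUCs.  Splits are stratified
per group (floor(0.6 * n_group) to training) so every validation fold
contains both classes; repetition r of probe p uses a deterministic random
stream derived from (master seed, crc32(p), r), making per-probe results
independent of evaluation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .io import GROUP_CASE, GROUP_CONTROL
from .diffexpr import ExpressionMatrix

__all__ = [
    "SplitScheme",
    "make_split",
    "fit_logistic",
    "roc_auc",
    "classification_metrics",
    "evaluate_feature",
    "evaluate_panel",
    "RepeatedHoldoutEvaluator",
]

#: absolute slope bound (per unit of feature sd) flagging complete separation
_SLOPE_CAP_PER_SD = 500.0


@dataclass
class SplitScheme:
    """Repeated train/validation splitting parameters (3:2 by default)."""

    train_fraction: float = 0.6
    stratified: bool = True
    seed: int = 0
    n_repetitions: int = 500

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def _probe_stream(seed: int, probe_id: str | None, repetition_index: int) -> np.random.Generator:
    entropy = [seed, repetition_index]
    if probe_id is not None:
        entropy.insert(1, zlib.crc32(str(probe_id).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def make_split(
    meta: pd.Series,
    scheme: SplitScheme,
    repetition_index: int,
    probe_id: str | None = None,
) -> tuple[list[str], list[str]]:
    """One deterministic train/validation partition of the samples.

    Stratified: per group, floor(train_fraction * n_group) samples train and
    the remainder validate.  Unstratified splits are redrawn (up to 100
    times) until both sets contain both classes.
    """
    counts = meta.value_counts()
    if counts.min() < 4 or len(counts) < 2:
        raise ValueError("each group needs at least 4 samples to split 3:2")
    rng = _probe_stream(scheme.seed, probe_id, repetition_index)
    samples = np.asarray(meta.index)
    groups = meta.to_numpy()
    if scheme.stratified:
        members_by_group = [samples[groups == g] for g in sorted(counts.index)]
        train_idx, val_idx = _stratified_split(rng, members_by_group, scheme.train_fraction)
        return list(train_idx), list(val_idx)
    n_train = int(np.floor(scheme.train_fraction * len(samples)))
    for _ in range(100):
        perm = rng.permutation(len(samples))
        train = list(samples[perm[:n_train]])
        val = list(samples[perm[n_train:]])
        if len(set(meta.loc[train])) == 2 and len(set(meta.loc[val])) == 2:
            return train, val
    raise RuntimeError("could not draw a split with both classes in both sets")


def _stratified_split(rng, members_by_group, train_fraction):
    """Per group: floor(train_fraction * n) members train, rest validate."""
    train, val = [], []
    for members in members_by_group:
        n_train = int(np.floor(train_fraction * len(members)))
        perm = rng.permutation(len(members))
        train.append(members[perm[:n_train]])
        val.append(members[perm[n_train:]])
    return np.concatenate(train), np.concatenate(val)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[float, float]:
    """Maximum-likelihood univariate logistic fit by Newton/IRLS.

    Returns (intercept, slope).  Convergence: log-likelihood change below
    ``tol`` or ``max_iter`` iterations.  A constant feature yields slope 0
    and fitted probability equal to the training prevalence.  On complete
    separation the slope diverges; it is capped at a large magnitude (rank
    statistics downstream are unaffected).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    scale = float(np.std(x))
    if scale == 0.0 or not np.isfinite(scale):
        return float(logit(np.mean(y))), 0.0
    cap = _SLOPE_CAP_PER_SD / scale
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll = _log_likelihood(X @ beta, y)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        # 2x2 Newton step; tiny jitter keeps the system solvable near separation
        XtW = X.T * w
        H = XtW @ X + 1e-12 * np.eye(2)
        g = X.T @ (y - mu)
        beta = beta + np.linalg.solve(H, g)
        if abs(beta[1]) > cap:
            beta[1] = np.sign(beta[1]) * cap
            break
        ll_new = _log_likelihood(X @ beta, y)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            break
        ll = ll_new
    return float(beta[0]), float(beta[1])


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half.

    Equals the mean over all (positive, negative) pairs of
    ``1[score_pos > score_neg] + 0.5 * 1[tie]``, computed via mid-ranks.
    """
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0 or len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(np.asarray(scores, float), method="average")
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def classification_metrics(
    probabilities, labels, threshold: float = 0.5
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) at probability >= threshold.

    Sensitivity is recall on cases (label 1), specificity recall on controls.
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(labels)
    pred = p >= threshold
    pos = y == 1
    neg = ~pos
    accuracy = float(np.mean(pred == pos))
    sensitivity = float(np.mean(pred[pos])) if pos.any() else np.nan
    specificity = float(np.mean(~pred[neg])) if neg.any() else np.nan
    return accuracy, sensitivity, specificity


def _binary_labels(groups: pd.Series) -> pd.Series:
    return (groups == GROUP_CASE).astype(float)


def evaluate_feature(
    em: ExpressionMatrix,
    probe_id: str,
    meta: pd.Series,
    scheme: SplitScheme,
    threshold: float = 0.5,
) -> dict:
    """Aggregate one probe's repeated-holdout classification statistics."""
    if probe_id not in em.values.index:
        raise KeyError(f"probe {probe_id!r} not in expression matrix")
    x_all = em.values.loc[probe_id]
    meta = meta.loc[x_all.index]
    counts = meta.value_counts()
    if counts.min() < 4 or len(counts) < 2:
        raise ValueError("each group needs at least 4 samples to split 3:2")
    if not scheme.stratified:
        raise ValueError("evaluate_feature requires a stratified scheme")
    # position-based hot loop; _stratified_split on positions reproduces
    # make_split's id partition exactly (same rng stream, same group order)
    samples = np.asarray(meta.index)
    groups = meta.to_numpy()
    positions_by_group = [
        np.flatnonzero(groups == g) for g in sorted(counts.index)
    ]
    x = x_all.to_numpy(float)
    y = _binary_labels(meta).to_numpy()
    aucs = np.empty(scheme.n_repetitions)
    accs = np.empty(scheme.n_repetitions)
    sens = np.empty(scheme.n_repetitions)
    spec = np.empty(scheme.n_repetitions)
    for r in range(scheme.n_repetitions):
        rng = _probe_stream(scheme.seed, probe_id, r)
        train, val = _stratified_split(rng, positions_by_group, scheme.train_fraction)
        b0, b1 = fit_logistic(x[train], y[train])
        prob = expit(b0 + b1 * x[val])
        yv = y[val]
        aucs[r] = roc_auc(prob, yv)
        accs[r], sens[r], spec[r] = classification_metrics(prob, yv, threshold)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return {
        "probe_id": probe_id,
        "auc_mean": float(np.mean(aucs)),
        "auc_ci_lower": float(lo),
        "auc_ci_upper": float(hi),
        "accuracy_mean": float(np.mean(accs)),
        "sensitivity_mean": float(np.mean(sens)),
        "specificity_mean": float(np.mean(spec)),
        "n_repetitions_effective": int(scheme.n_repetitions),
    }


def evaluate_panel(
    em: ExpressionMatrix,
    probe_ids,
    meta: pd.Series,
    scheme: SplitScheme,
    highlight_threshold: float = 0.9,
) -> pd.DataFrame:
    """Evaluate each probe univariately; sort by mean AUC descending and flag
    probes above the highlight threshold (strict)."""
    rows = [evaluate_feature(em, p, meta, scheme) for p in probe_ids]
    if not rows:
        return pd.DataFrame(
            columns=[
                "probe_id", "auc_mean", "auc_ci_lower", "auc_ci_upper",
                "accuracy_mean", "sensitivity_mean", "specificity_mean",
                "n_repetitions_effective", "highlight",
            ]
        ).set_index("probe_id")
    out = pd.DataFrame(rows).set_index("probe_id")
    out["highlight"] = out["auc_mean"] > highlight_threshold
    return out.sort_values("auc_mean", ascending=False, kind="mergesort")


class RepeatedHoldoutEvaluator(BaseEstimator):
    """Sklearn-style wrapper: univariate repeated-holdout evaluation of every
    feature in a samples x features matrix.

    Parameters
    ----------
    train_fraction : float, default 0.6
    n_repetitions : int, default 500
    random_state : int, default 0
    highlight_threshold : float, default 0.9
        Mean-AUC cut (strict) for the biomarker highlight flag.
    positive_label : hashable, default "case"

    Attributes
    ----------
    stats_ : DataFrame, one row per feature, sorted by auc_mean descending.
    """

    def __init__(
        self,
        train_fraction=0.6,
        n_repetitions=500,
        random_state=0,
        highlight_threshold=0.9,
        positive_label="case",
    ):
        self.train_fraction = train_fraction
        self.n_repetitions = n_repetitions
        self.random_state = random_state
        self.highlight_threshold = highlight_threshold
        self.positive_label = positive_label

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            values = X.T.astype(float)
        else:
            X = np.asarray(X, float)
            values = pd.DataFrame(X.T, index=[f"feature_{j}" for j in range(X.shape[1])])
        y = np.asarray(y)
        groups = pd.Series(
            np.where(y == self.positive_label, GROUP_CASE, GROUP_CONTROL),
            index=values.columns,
        )
        if (groups == GROUP_CASE).sum() == 0:
            # numeric labels: treat the larger as the positive class
            labels = np.unique(y)
            if len(labels) != 2:
                raise ValueError("y must contain exactly two classes")
            groups = pd.Series(
                np.where(y == labels.max(), GROUP_CASE, GROUP_CONTROL),
                index=values.columns,
            )
        em = ExpressionMatrix(values=values, groups=groups)
        scheme = SplitScheme(
            train_fraction=self.train_fraction,
            seed=self.random_state,
            n_repetitions=self.n_repetitions,
        )
        self.stats_ = evaluate_panel(
            em, list(values.index), groups, scheme, self.highlight_threshold
        )
        self.n_features_in_ = values.shape[0]
        return self
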