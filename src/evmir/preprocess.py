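"""Probe/sample quality filtering, endogenous reference selection and
delta-Ct normalization.

The published filter chain: probes undetected (Ct at the 40-cycle ceiling) in
every sample are removed; samples in which more than 80% of probes are
undetected are removed; normalization subtracts, per sample, the mean Ct of k
endogenous reference probes — the detected probes with the lowest
interquartile range of Ct across samples.  Subtracting a per-sample constant
makes delta-Ct exactly invariant to sample-level loading/efficiency offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CtMatrix, check_two_groups

__all__ = [
    "FilterReport",
    "ReferenceSet",
    "NormalizedMatrix",
    "remove_undetected_probes",
    "remove_low_quality_samples",
    "select_reference_probes",
    "delta_normalize",
    "preprocess",
    "DeltaCtNormalizer",
]


@dataclass
class FilterReport:
    """Provenance of one filtering pass."""

    removed_probe_ids: list[str] = field(default_factory=list)
    removed_sample_ids: list[str] = field(default_factory=list)
    probe_reason: str = "all_undetected"
    sample_reason: str = "gt_80pct_undetected"
    n_probes_before: int = 0
    n_probes_after: int = 0
    n_samples_before: int = 0
    n_samples_after: int = 0
    provenance: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [("probe", p, self.probe_reason) for p in self.removed_probe_ids]
        rows += [("sample", s, self.sample_reason) for s in self.removed_sample_ids]
        return pd.DataFrame(rows, columns=["axis", "id", "reason"])


@dataclass
class ReferenceSet:
    """The k probes used for delta-normalization, ordered by non-decreasing IQR."""

    probe_ids: list[str]
    undetected_count: pd.Series
    iqr: pd.Series

    def __post_init__(self) -> None:
        iqr = np.asarray(self.iqr, dtype=float)
        if np.any(np.diff(iqr) < 0):
            raise ValueError("reference IQRs must be sorted non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "undetected_count": self.undetected_count.loc[self.probe_ids].values,
                "iqr": self.iqr.loc[self.probe_ids].values,
            }
        )


@dataclass
class NormalizedMatrix:
    """Per-sample delta-Ct values plus the reference-set provenance.

    ``dct`` holds delta-Ct = Ct(probe, sample) − mean Ct of the reference
    probes in that sample; lower delta-Ct = more abundant.
    """

    dct: pd.DataFrame
    reference: ReferenceSet

    @property
    def probe_ids(self) -> list[str]:
        return list(self.dct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dct.columns)


def remove_undetected_probes(m: CtMatrix) -> tuple[CtMatrix, FilterReport]:
    """Drop probes whose Ct sits at the ceiling in every sample."""
    und = m.undetected()
    all_und = und.all(axis=1)
    keep = m.values.loc[~all_und]
    if keep.shape[0] == 0:
        raise ValueError("empty matrix: every probe is undetected in all samples")
    report = FilterReport(
        removed_probe_ids=list(m.values.index[all_und]),
        n_probes_before=m.shape[0],
        n_probes_after=keep.shape[0],
        n_samples_before=m.shape[1],
        n_samples_after=m.shape[1],
    )
    return CtMatrix(keep, m.ct_max), report


def remove_low_quality_samples(
    m: CtMatrix, fraction: float = 0.8, meta: pd.Series | None = None
) -> tuple[CtMatrix, FilterReport]:
    """Drop samples with strictly more than ``fraction`` of probes undetected.

    A "Ct value greater than 40" is read as >= the ceiling, since nothing
    exceeds the instrument ceiling.  If ``meta`` is given and removal empties
    one group entirely, that is a hard error naming the group.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    und_frac = m.undetected().mean(axis=0)
    drop = und_frac > fraction
    keep_cols = m.values.columns[~drop]
    if meta is not None:
        for group in pd.unique(meta):
            members = meta.index[meta == group]
            if len(members) and not members.isin(keep_cols).any():
                raise ValueError(f"sample filter removed every {group!r} sample")
    if len(keep_cols) == 0:
        raise ValueError("sample filter removed every sample")
    report = FilterReport(
        removed_sample_ids=list(m.values.columns[drop]),
        n_probes_before=m.shape[0],
        n_probes_after=m.shape[0],
        n_samples_before=m.shape[1],
        n_samples_after=len(keep_cols),
        provenance=(
            "low-quality samples removed (Results-section reading; the Methods "
            "text says 'retained', which would keep empty samples)"
        ),
    )
    return CtMatrix(m.values[keep_cols], m.ct_max), report


def _probe_iqr(values: pd.DataFrame) -> pd.Series:
    q1, q3 = np.percentile(values.to_numpy(float), [25, 75], axis=1, method="linear")
    return pd.Series(q3 - q1, index=values.index)


def select_reference_probes(
    m: CtMatrix, max_undetected: int = 3, k: int = 4
) -> ReferenceSet:
    """Pick the k eligible probes with the lowest Ct IQR across all samples.

    A probe is eligible when it is undetected (Ct at the ceiling) in at most
    ``max_undetected`` samples.  IQR is Q3 − Q1 with linear interpolation;
    ties break lexicographically by probe id for cross-platform determinism.
    """
    und_count = m.undetected().sum(axis=1)
    eligible = und_count[und_count <= max_undetected].index
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} probes satisfy undetected_count <= "
            f"{max_undetected}; need at least k={k}"
        )
    iqr = _probe_iqr(m.values.loc[eligible])
    ranked = sorted(eligible, key=lambda p: (iqr[p], p))
    chosen = ranked[:k]
    return ReferenceSet(
        probe_ids=chosen,
        undetected_count=und_count.loc[chosen],
        iqr=iqr.loc[chosen],
    )


def delta_normalize(m: CtMatrix, refs: ReferenceSet) -> NormalizedMatrix:
    """delta-Ct(p, s) = Ct(p, s) − mean over reference probes of Ct(ref, s).

    Reference probes remain rows of the output (their delta-Ct is their
    deviation from the reference mean).
    """
    missing = [p for p in refs.probe_ids if p not in m.values.index]
    if missing:
        raise ValueError(f"reference probes missing from matrix: {missing}")
    ref_mean = m.values.loc[refs.probe_ids].mean(axis=0)
    dct = m.values.sub(ref_mean, axis=1)
    return NormalizedMatrix(dct=dct, reference=refs)


def preprocess(
    m: CtMatrix,
    meta: pd.Series,
    sample_undetected_fraction: float = 0.8,
    reference_max_undetected: int = 3,
    reference_k: int = 4,
) -> tuple[NormalizedMatrix, pd.Series, FilterReport]:
    """The full published chain: probe filter → sample filter → probe filter
    again → reference selection → delta-normalization.

    The second probe pass removes probes that became all-undetected once
    low-quality samples left; the composite is idempotent.  Returns the
    normalized matrix, the metadata restricted to surviving samples, and a
    merged filter report.
    """
    check_two_groups(meta)
    m1, rep1 = remove_undetected_probes(m)
    m2, rep2 = remove_low_quality_samples(m1, sample_undetected_fraction, meta=meta)
    und = m2.undetected().all(axis=1)
    if und.all():
        raise ValueError("empty matrix after sample filtering")
    m3 = CtMatrix(m2.values.loc[~und], m2.ct_max)
    rep = FilterReport(
        removed_probe_ids=rep1.removed_probe_ids + list(m2.values.index[und]),
        removed_sample_ids=rep2.removed_sample_ids,
        n_probes_before=m.shape[0],
        n_probes_after=m3.shape[0],
        n_samples_before=m.shape[1],
        n_samples_after=m3.shape[1],
        provenance=rep2.provenance,
    )
    meta_kept = meta.loc[[s for s in m3.sample_ids]]
    check_two_groups(meta_kept)
    refs = select_reference_probes(m3, reference_max_undetected, reference_k)
    return delta_normalize(m3, refs), meta_kept, rep


class DeltaCtNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style delta-Ct transformer over samples x probes input.

    ``fit`` selects the reference probes (explicit list, or the lowest-IQR
    rule); ``transform`` subtracts each sample's reference-mean Ct from every
    probe.  Input is the sklearn orientation (rows = samples, columns =
    probes), the transpose of the instrument-convention ``CtMatrix``.

    Parameters
    ----------
    reference_probes : list of str, optional
        Explicit reference probe ids; when None the rule-based selection runs.
    max_undetected : int, default 3
        Eligibility bound on per-probe undetected sample count.
    k : int, default 4
        Number of reference probes to select.
    ct_max : float, default 40.0
        Censoring ceiling used to count undetected wells.

    Attributes
    ----------
    reference_set_ : ReferenceSet
        Selected references with their undetected counts and IQRs.
    feature_names_in_ : ndarray of probe ids seen in fit.
    """

    def __init__(self, reference_probes=None, max_undetected=3, k=4, ct_max=40.0):
        self.reference_probes = reference_probes
        self.max_undetected = max_undetected
        self.k = k
        self.ct_max = ct_max

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"probe_{j}" for j in range(X.shape[1])])

    def fit(self, X, y=None):
        df = self._as_frame(X)
        self.feature_names_in_ = np.asarray(df.columns)
        self.n_features_in_ = df.shape[1]
        m = CtMatrix(df.T, ct_max=self.ct_max)
        if self.reference_probes is not None:
            und = m.undetected().sum(axis=1)
            iqr = _probe_iqr(m.values.loc[list(self.reference_probes)])
            order = sorted(self.reference_probes, key=lambda p: (iqr[p], p))
            self.reference_set_ = ReferenceSet(
                probe_ids=order,
                undetected_count=und.loc[order],
                iqr=iqr.loc[order],
            )
        else:
            self.reference_set_ = select_reference_probes(
                m, self.max_undetected, self.k
            )
        return self

    def transform(self, X):
        if not hasattr(self, "reference_set_"):
            raise ValueError("DeltaCtNormalizer is not fitted")
        df = self._as_frame(X)
        missing = [p for p in self.reference_set_.probe_ids if p not in df.columns]
        if missing:
            raise ValueError(f"reference probes missing from input: {missing}")
        ref_mean = df[self.reference_set_.probe_ids].mean(axis=1)
        return df.sub(ref_mean, axis=0)
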