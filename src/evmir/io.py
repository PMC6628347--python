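"""Reading and writing Ct matrices, sample metadata and the packaged results fixture.

A Ct (cycle-threshold) matrix is probes x samples, values in ``[0, ct_max]``
cycles.  The instrument ceiling (``ct_max``, 40 cycles on an OpenArray) means
"not detected"; undetected wells arrive in exports as ``Undetermined``/``NA``/
empty tokens and are stored as the numeric ceiling so every downstream filter
phrased on "Ct value of 40" applies literally.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "read_ct_table",
    "write_ct_table",
    "read_sample_meta",
    "write_sample_meta",
    "check_two_groups",
    "load_table2_fixture",
    "TABLE2_COLUMNS",
    "GROUP_CASE",
    "GROUP_CONTROL",
]

GROUP_CASE = "case"
GROUP_CONTROL = "control"

#: tokens that encode an undetected well in instrument exports
UNDETECTED_TOKENS = ("Undetermined", "NA", "")

TABLE2_COLUMNS = [
    "probe_label",
    "logfc",
    "p_value",
    "adj_p_value",
    "auc",
    "auc_ci_lower",
    "auc_ci_upper",
    "accuracy",
    "sensitivity",
    "specificity",
]

_TABLE2_RESOURCE = "table2_ec_lavage.tsv"
_TABLE2_SHA256 = "8ac8daf2e3b0a67912d1fc453202362c4518f56ca371779f17f5ff495a79e541"
_TABLE2_NROWS = 114


@dataclass
class CtMatrix:
    """Probes x samples matrix of raw Ct cycles with a censoring ceiling.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, columns sample ids, float cycles.
    ct_max
        Instrument ceiling in cycles; every value must lie in ``[0, ct_max]``
        and a value equal to ``ct_max`` means "not detected".
    """

    values: pd.DataFrame
    ct_max: float = 40.0

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy(dtype=float)
        if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > self.ct_max):
            raise ValueError(f"Ct values must lie in [0, {self.ct_max}]")
        self.values = v.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def undetected(self) -> pd.DataFrame:
        """Boolean mask of wells at the censoring ceiling."""
        return self.values >= self.ct_max

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.values.copy(), self.ct_max)


def _sniff_delimiter(header_line: str) -> str:
    # instrument exports vary; accept tab or comma, preferring tab
    return "\t" if "\t" in header_line else ","


def read_ct_table(path: str | Path, ct_max: float = 40.0) -> CtMatrix:
    """Read a delimited Ct table (first column probe ids, header sample ids).

    ``Undetermined``, ``NA`` and empty cells map to ``ct_max``; any other
    non-numeric cell is a hard error naming its row and column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    def parse_cell(token: str, probe: str, sample: str) -> float:
        token = token.strip()
        if token in UNDETECTED_TOKENS:
            return float(ct_max)
        try:
            return float(token)
        except ValueError:
            raise ValueError(
                f"non-numeric Ct cell {token!r} at probe {probe!r}, sample {sample!r}"
            ) from None

    out = pd.DataFrame(
        [
            [parse_cell(df.iat[i, j], df.index[i], df.columns[j]) for j in range(df.shape[1])]
            for i in range(df.shape[0])
        ],
        index=df.index,
        columns=df.columns,
        dtype=float,
    )
    return CtMatrix(out, ct_max=ct_max)


def write_ct_table(matrix: CtMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a Ct table re-readable by :func:`read_ct_table` to identity.

    Values are serialized with enough digits (repr round-trip) that reading
    the file back reproduces the matrix exactly.
    """
    df = matrix.values.copy()
    df.index.name = "probe_id"
    df.to_csv(Path(path), sep=sep, float_format="%.10g")


def read_sample_meta(path: str | Path) -> pd.Series:
    """Read two-column (sample_id, group) metadata into a Series."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("sample metadata needs columns (sample_id, group)")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str), name="group")
    if s.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    bad = sorted(set(s.unique()) - {GROUP_CASE, GROUP_CONTROL})
    if bad:
        raise ValueError(f"unknown group labels {bad}; expected case/control")
    return s


def write_sample_meta(meta: pd.Series, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame({"sample_id": meta.index, "group": meta.values})
    df.to_csv(Path(path), sep=sep, index=False)


def check_two_groups(meta: pd.Series) -> None:
    """Require both case and control to be non-empty."""
    counts = meta.value_counts()
    for g in (GROUP_CASE, GROUP_CONTROL):
        if counts.get(g, 0) == 0:
            raise ValueError(f"group {g!r} is empty")


def load_table2_fixture() -> pd.DataFrame:
    """Load the packaged 114-row published-results fixture.

    Columns: probe_label, logfc (log2), p_value, adj_p_value, auc,
    auc_ci_lower, auc_ci_upper, accuracy, sensitivity, specificity.
    The file's sha256 is verified so a corrupted install fails loudly.
    """
    raw = resources.files("evmir.data").joinpath(_TABLE2_RESOURCE).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE2_SHA256:
        raise RuntimeError(
            f"packaged results fixture checksum mismatch: {digest}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t")
    df.columns = TABLE2_COLUMNS
    if len(df) != _TABLE2_NROWS:
        raise RuntimeError(f"fixture has {len(df)} rows, expected {_TABLE2_NROWS}")
    return df
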