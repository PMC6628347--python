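"""Consensus filtering of miRNA-target prediction records.

Records come from an external prediction export (one row per miRNA-gene
pair with its supporting databases and seed-match geometry); no live
databases are queried.  A pair is a valid target when it is supported by at
least 8 of the 12 canonical prediction databases, the seed match is at least
7 bp long starting at position 1 of the miRNA, and the site lies in the
3'UTR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "CANONICAL_DATABASES",
    "REGIONS",
    "TargetPredictionRecord",
    "read_target_table",
    "write_target_table",
    "filter_targets",
    "targets_per_mirna",
]

CANONICAL_DATABASES = (
    "miRWalk",
    "miRanda",
    "MicroT4",
    "miRDB",
    "miRMap",
    "miRBridge",
    "miRNAMap",
    "PICTAR2",
    "RNA22",
    "PITA",
    "TargetScan",
    "RNAhybrid",
)
_CANONICAL_BY_LOWER = {name.lower(): name for name in CANONICAL_DATABASES}

REGIONS = ("3UTR", "5UTR", "CDS", "promoter")


@dataclass(frozen=True)
class TargetPredictionRecord:
    """One predicted miRNA-gene interaction with its evidence."""

    mirna_id: str
    gene_id: str
    supporting_databases: frozenset
    seed_length: int
    seed_start: int
    region: str

    def __post_init__(self) -> None:
        if not self.supporting_databases:
            raise ValueError("supporting_databases must be non-empty")
        canonical = frozenset(
            _canonical_db(name) for name in self.supporting_databases
        )
        object.__setattr__(self, "supporting_databases", canonical)
        if self.seed_length < 1:
            raise ValueError("seed_length must be >= 1")
        if self.seed_start < 1:
            raise ValueError("seed_start must be >= 1 (1-based)")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")


def _canonical_db(name: str) -> str:
    try:
        return _CANONICAL_BY_LOWER[name.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown prediction database {name!r}; expected one of {CANONICAL_DATABASES}"
        ) from None


def read_target_table(path: str | Path) -> list[TargetPredictionRecord]:
    """Read a delimited file with columns mirna_id, gene_id, databases
    (semicolon-joined), seed_length, seed_start, region."""
    df = pd.read_csv(Path(path), sep=None, engine="python", dtype=str)
    required = ["mirna_id", "gene_id", "databases", "seed_length", "seed_start", "region"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"target table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TargetPredictionRecord(
                mirna_id=row.mirna_id,
                gene_id=row.gene_id,
                supporting_databases=frozenset(
                    tok for tok in str(row.databases).split(";") if tok.strip()
                ),
                seed_length=int(row.seed_length),
                seed_start=int(row.seed_start),
                region=str(row.region),
            )
        )
    return records


def write_target_table(records, path: str | Path, sep: str = "\t") -> None:
    rows = [
        {
            "mirna_id": r.mirna_id,
            "gene_id": r.gene_id,
            "databases": ";".join(sorted(r.supporting_databases)),
            "seed_length": r.seed_length,
            "seed_start": r.seed_start,
            "region": r.region,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(Path(path), sep=sep, index=False)


def filter_targets(
    records,
    min_databases: int = 8,
    min_seed_length: int = 7,
    required_seed_start: int = 1,
    required_region: str = "3UTR",
) -> list[TargetPredictionRecord]:
    """Keep records passing all consensus rules (conjunction).

    Support count >= min_databases, seed length >= min_seed_length, seed
    start equal to required_seed_start, region equal to required_region.
    """
    return [
        r
        for r in records
        if len(r.supporting_databases) >= min_databases
        and r.seed_length >= min_seed_length
        and r.seed_start == required_seed_start
        and r.region == required_region
    ]


def targets_per_mirna(records) -> tuple[pd.Series, int]:
    """Deduplicated target-gene counts per miRNA and the union gene-set size."""
    genes_by_mirna: dict[str, set] = {}
    union: set = set()
    for r in records:
        genes_by_mirna.setdefault(r.mirna_id, set()).add(r.gene_id)
        union.add(r.gene_id)
    counts = pd.Series(
        {m: len(g) for m, g in sorted(genes_by_mirna.items())}, dtype=int, name="n_targets"
    )
    return counts, len(union)
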