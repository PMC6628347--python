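"""Pipeline configuration: every published analysis threshold as a named field."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Thresholds of the full Ct-to-biomarker pipeline.

    Defaults reproduce the published analysis settings: censoring ceiling of
    40 cycles, sample removal above 80% undetected probes, four endogenous
    reference probes with at most three undetected samples each, significance
    at adjusted p < 0.05 with |logFC| >= 1, 3:2 train/validation splitting
    repeated 500 times, an AUC highlight cut of 0.90, and the 8-of-12
    database / 7 bp seed / position-1 / 3'UTR target-consensus rules.
    """

    ct_max: float = 40.0
    sample_undetected_fraction: float = 0.8
    reference_max_undetected: int = 3
    reference_k: int = 4
    de_adj_p_threshold: float = 0.05
    de_abs_logfc_threshold: float = 1.0
    split_train_fraction: float = 0.6
    n_repetitions: int = 500
    auc_highlight_threshold: float = 0.9
    consensus_min_databases: int = 8
    seed_min_length: int = 7
    seed_start_required: int = 1
    required_region: str = "3UTR"

    def __post_init__(self) -> None:
        if not 0 < self.sample_undetected_fraction < 1:
            raise ValueError("sample_undetected_fraction must be in (0, 1)")
        if not 0 < self.split_train_fraction < 1:
            raise ValueError("split_train_fraction must be in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        for name in ("ct_max", "de_adj_p_threshold", "de_abs_logfc_threshold",
                     "auc_highlight_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("reference_max_undetected", "reference_k",
                     "consensus_min_databases", "seed_min_length",
                     "seed_start_required"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_file(self, path: str | Path) -> None:
        """Write as flat ``key = value`` lines."""
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        types = {f.name: f.type for f in fields(cls)}
        casts = {"float": float, "int": int, "str": str}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, value = (part.strip() for part in line.partition("="))
            if key not in types:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)
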