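"""Synthetic OpenArray-style Ct data with the structure the analysis assumes.

The generator emulates a censored qPCR panel: a per-probe baseline Ct, a
per-sample global offset (loading/efficiency, removed by delta-normalization),
probe-specific case-vs-control shifts in cycles, well-level noise, a block of
probes that are never detected, and a handful of highly stable reference-like
probes.  One cycle of shift corresponds to one log2 unit of abundance, so a
negative shift in cases means upregulation.

Wells whose value exceeds ``dropout_ct_threshold`` are censored to ``ct_max``
after effects are applied, so strong downregulation can push a probe into
non-detection — the mechanism behind the very large fold-changes seen near
the detection limit of real panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CtMatrix, GROUP_CASE, GROUP_CONTROL

__all__ = ["SyntheticConfig", "generate_dataset", "default_study_config", "spiked_study_config"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic Ct generator (cycles throughout).

    ``effect_map`` maps probe id -> case-minus-control shift on the Ct scale;
    a negative shift means lower Ct, i.e. higher abundance, in cases.
    """

    n_probes: int = 754
    n_case: int = 25
    n_control: int = 25
    baseline_ct_mean: float = 27.0
    baseline_ct_sd: float = 2.0
    sample_offset_sd: float = 1.0
    noise_sd: float = 0.8
    effect_map: dict[str, float] = field(default_factory=dict)
    frac_never_detected: float = 0.5
    n_reference_like: int = 6
    reference_noise_sd: float = 0.05
    dropout_ct_threshold: float = 35.0
    ct_max: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_probes, self.n_case, self.n_control) < 0:
            raise ValueError("counts must be non-negative")
        for name in ("baseline_ct_sd", "sample_offset_sd", "noise_sd", "reference_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.frac_never_detected < 1:
            raise ValueError("frac_never_detected must be in [0, 1)")
        if self.n_reference_like < 0:
            raise ValueError("n_reference_like must be >= 0")
        if self.dropout_ct_threshold > self.ct_max:
            raise ValueError("dropout_ct_threshold cannot exceed ct_max")

    @property
    def probe_ids(self) -> list[str]:
        return [f"probe_{i:04d}" for i in range(self.n_probes)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"case_{i:02d}" for i in range(self.n_case)] + [
            f"ctrl_{i:02d}" for i in range(self.n_control)
        ]

    def validate_effects(self) -> None:
        unknown = set(self.effect_map) - set(self.probe_ids)
        if unknown:
            raise ValueError(f"effect_map keys not in probe ids: {sorted(unknown)}")


def generate_dataset(config: SyntheticConfig) -> tuple[CtMatrix, pd.Series, pd.DataFrame]:
    """Draw one dataset; returns (Ct matrix, sample groups, per-probe truth).

    Well model: ``clip(baseline_p + offset_s + delta_p*[s is case] + noise, 0,
    ct_max)`` then censored to ``ct_max`` above ``dropout_ct_threshold``.
    Never-detected probes sit at ``ct_max`` everywhere; reference-like probes
    get near-zero well noise and carry no effect.  ``truth`` echoes the
    realized case-vs-control shift per probe (0 where none was injected, and
    0 for never-detected probes, whose shift is unobservable).
    """
    config.validate_effects()
    rng = np.random.default_rng(config.seed)
    probes = config.probe_ids
    samples = config.sample_ids
    n_p, n_s = len(probes), len(samples)
    is_case = np.array([s.startswith("case") for s in samples])

    n_never = int(round(config.frac_never_detected * n_p))
    order = rng.permutation(n_p)
    never_idx = set(order[:n_never].tolist())
    # reference-like probes drawn from the detected block
    ref_idx = set(order[n_never : n_never + min(config.n_reference_like, n_p - n_never)].tolist())

    baseline = rng.normal(config.baseline_ct_mean, config.baseline_ct_sd, size=n_p)
    offsets = rng.normal(0.0, config.sample_offset_sd, size=n_s)
    noise_sd = np.full(n_p, config.noise_sd)
    noise_sd[list(ref_idx)] = config.reference_noise_sd
    noise = rng.normal(0.0, 1.0, size=(n_p, n_s)) * noise_sd[:, None]

    delta = np.zeros(n_p)
    for probe, d in config.effect_map.items():
        delta[probes.index(probe)] = d
    delta[list(ref_idx)] = 0.0  # references stay stable by construction

    values = baseline[:, None] + offsets[None, :] + delta[:, None] * is_case[None, :] + noise
    values = np.clip(values, 0.0, config.ct_max)
    values[values > config.dropout_ct_threshold] = config.ct_max
    values[list(never_idx), :] = config.ct_max

    realized = delta.copy()
    realized[list(never_idx)] = 0.0

    ct = CtMatrix(pd.DataFrame(values, index=probes, columns=samples), ct_max=config.ct_max)
    meta = pd.Series(
        np.where(is_case, GROUP_CASE, GROUP_CONTROL), index=samples, name="group"
    )
    truth = pd.DataFrame(
        {
            "probe_id": probes,
            "delta_ct": realized,
            "never_detected": [i in never_idx for i in range(n_p)],
            "reference_like": [i in ref_idx for i in range(n_p)],
        }
    ).set_index("probe_id")
    return ct, meta, truth


def default_study_config(seed: int = 0) -> SyntheticConfig:
    """Study-sized defaults: 754 probes, 25+25 samples, ~50% never detected,
    six reference-like probes."""
    return SyntheticConfig(seed=seed)


def spiked_study_config(
    n_effects: int = 20,
    delta_range: tuple[float, float] = (2.0, 4.0),
    frac_up_in_case: float = 0.25,
    seed: int = 0,
) -> SyntheticConfig:
    """Study-sized config with ``n_effects`` probes shifted by |delta| drawn
    from ``delta_range`` cycles.

    Effects are placed on detected, non-reference probes.  By default 75% of
    effects are positive Ct shifts in cases (downregulation, the dominant
    direction in EV panels of this kind) and 25% negative (upregulation).
    """
    cfg = SyntheticConfig(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    # mirror generate_dataset's partition so effects land on detected probes
    n_never = int(round(cfg.frac_never_detected * cfg.n_probes))
    order = np.random.default_rng(seed).permutation(cfg.n_probes)
    detected = order[n_never + cfg.n_reference_like :]
    chosen = rng.choice(detected, size=n_effects, replace=False)
    probes = cfg.probe_ids
    lo, hi = delta_range
    mags = rng.uniform(lo, hi, size=n_effects)
    signs = np.where(rng.random(n_effects) < frac_up_in_case, -1.0, 1.0)
    cfg.effect_map = {probes[i]: float(s * m) for i, s, m in zip(chosen, signs, mags)}
    return cfg
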