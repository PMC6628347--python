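"""End-to-end orchestration: simulate/load -> preprocess -> differential
expression -> predictor evaluation -> summary, with a manifest that fully
determines the outputs."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .diffexpr import run_diffexpr, select_significant, to_expression
from .io import CtMatrix, read_ct_table, read_sample_meta, write_ct_table, write_sample_meta
from .predict import SplitScheme, evaluate_panel
from .preprocess import preprocess
from .report import summarize
from .simulate import SyntheticConfig, generate_dataset

__all__ = ["run_pipeline", "parse_manifest", "RESULT_COLUMNS"]

#: column set of the final results table (the published-table schema)
RESULT_COLUMNS = [
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


def _write_flat(path: Path, mapping: dict) -> None:
    path.write_text("".join(f"{k} = {v}\n" for k, v in mapping.items()))


def _effect_map_str(effect_map: dict) -> str:
    return ";".join(f"{k}:{v!r}" for k, v in sorted(effect_map.items()))


def run_pipeline(
    outdir: str | Path,
    config: PipelineConfig | None = None,
    seed: int = 0,
    sim_config: SyntheticConfig | None = None,
    ct_path: str | Path | None = None,
    meta_path: str | Path | None = None,
) -> dict:
    """Run every stage, writing all artifacts under ``outdir``.

    Either ``sim_config`` (synthetic input) or both ``ct_path`` and
    ``meta_path`` (measured input) must be given.  Returns the manifest
    mapping.  Identical config + seed reproduce byte-identical outputs.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"evmir_version": __version__, "seed": seed}
    manifest.update(asdict(config))

    stage = "setup"
    try:
        if sim_config is not None:
            stage = "simulate"
            ct, meta, truth = generate_dataset(sim_config)
            write_ct_table(ct, outdir / "ct_matrix.tsv")
            write_sample_meta(meta, outdir / "sample_meta.tsv")
            truth.to_csv(outdir / "truth.tsv", sep="\t")
            for key, value in asdict(sim_config).items():
                if key == "effect_map":
                    manifest["sim_effect_map"] = _effect_map_str(value)
                else:
                    manifest[f"sim_{key}"] = value
        elif ct_path is not None and meta_path is not None:
            stage = "load"
            ct = read_ct_table(ct_path, ct_max=config.ct_max)
            meta = read_sample_meta(meta_path)
            manifest["input_ct"] = str(ct_path)
            manifest["input_meta"] = str(meta_path)
        else:
            raise ValueError("need sim_config or both ct_path and meta_path")

        manifest["n_probes_input"] = ct.shape[0]
        manifest["n_samples_input"] = ct.shape[1]
        detected = int((~ct.undetected().all(axis=1)).sum())
        manifest["n_probes_detected"] = detected
        manifest["detected_fraction_pct"] = round(100.0 * detected / ct.shape[0], 1)

        stage = "preprocess"
        nm, meta_kept, report = preprocess(
            ct,
            meta,
            sample_undetected_fraction=config.sample_undetected_fraction,
            reference_max_undetected=config.reference_max_undetected,
            reference_k=config.reference_k,
        )
        nm.dct.rename_axis("probe_id").to_csv(outdir / "delta_ct.tsv", sep="\t")
        report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
        nm.reference.to_frame().to_csv(outdir / "reference_set.tsv", sep="\t", index=False)
        manifest["n_probes_retained"] = len(nm.probe_ids)
        manifest["n_samples_retained"] = len(nm.sample_ids)
        manifest["reference_probes"] = ";".join(nm.reference.probe_ids)

        stage = "diffexpr"
        de = run_diffexpr(nm, meta_kept)
        de_out = de[["logfc", "p_value", "adj_p_value", "t", "df_total"]].rename_axis(
            "probe_id"
        )
        de_out.to_csv(outdir / "de_results.tsv", sep="\t", float_format="%.6g")
        sig = select_significant(
            de, config.de_adj_p_threshold, config.de_abs_logfc_threshold
        )
        manifest["n_significant"] = len(sig)

        stage = "predict"
        em = to_expression(nm, meta_kept)
        scheme = SplitScheme(
            train_fraction=config.split_train_fraction,
            seed=seed,
            n_repetitions=config.n_repetitions,
        )
        stats = evaluate_panel(
            em, list(sig.index), meta_kept, scheme, config.auc_highlight_threshold
        )
        results = pd.DataFrame(
            {
                "probe_label": stats.index,
                "logfc": de.loc[stats.index, "logfc"].values,
                "p_value": de.loc[stats.index, "p_value"].values,
                "adj_p_value": de.loc[stats.index, "adj_p_value"].values,
                "auc": stats["auc_mean"].values,
                "auc_ci_lower": stats["auc_ci_lower"].values,
                "auc_ci_upper": stats["auc_ci_upper"].values,
                "accuracy": stats["accuracy_mean"].values,
                "sensitivity": stats["sensitivity_mean"].values,
                "specificity": stats["specificity_mean"].values,
            }
        )
        results.to_csv(outdir / "results.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["n_highlight"] = int(stats["highlight"].sum())

        stage = "summarize"
        if len(results):
            summary = summarize(results, auc_threshold=config.auc_highlight_threshold)
        else:
            summary = {"n_rows": 0}
        _write_flat(outdir / "summary.txt", summary)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _write_flat(outdir / "manifest.txt", manifest)
    return manifest


def parse_manifest(path: str | Path) -> tuple[PipelineConfig, int, SyntheticConfig | None]:
    """Recover (config, seed, sim_config) from a manifest file, so a run can
    be reproduced from its manifest alone."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    from dataclasses import fields

    cfg_kwargs = {}
    casts = {"float": float, "int": int, "str": str}
    for f in fields(PipelineConfig):
        if f.name in kv:
            cfg_kwargs[f.name] = casts[f.type](kv[f.name])
    config = PipelineConfig(**cfg_kwargs)
    seed = int(kv["seed"])
    sim = None
    if "sim_n_probes" in kv:
        sim_kwargs = {}
        for f in fields(SyntheticConfig):
            key = f"sim_{f.name}"
            if f.name == "effect_map":
                emap = {}
                for token in kv.get("sim_effect_map", "").split(";"):
                    if token:
                        probe, _, d = token.partition(":")
                        emap[probe] = float(d)
                sim_kwargs["effect_map"] = emap
            elif key in kv:
                cast = {"int": int, "float": float}.get(f.type, str)
                sim_kwargs[f.name] = cast(kv[key])
        sim = SyntheticConfig(**sim_kwargs)
    return config, seed, sim
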