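"""End-to-end orchestration from a single plain-text (YAML) config.

Stages run in dependency order: simulate/load expression -> score ->
call -> proportions -> group contrasts -> age-plateau fits -> regional
meta-analysis, plus an optional imaging branch (simulate/load -> QC trim
-> marker calls -> cluster proportions -> peri-plaque contrast).  Every
output CSV starts with a ``#`` header comment carrying the stage name
and a parameter digest; a rerun with an identical config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, meta, plateau, scoring, spatial, stats
from .io import read_expression, read_gmt, read_imaging_cells, read_plaques
from .simulate import (
    ExpressionSimConfig,
    ImagingSimConfig,
    simulate_expression,
    simulate_imaging,
)

logger = logging.getLogger("senescape")

STAGE_OUTPUTS = [
    "scores.csv",
    "calls.csv",
    "proportions.csv",
    "effects.csv",
    "agefit.csv",
    "meta.csv",
]


def _digest(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, stage: str, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# senescape stage={stage} params_digest={_digest(params)}\n")
        df.to_csv(fh, index=False)


def read_stage_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def validate_config(config: dict) -> None:
    """Fail before any stage runs if a referenced path is missing."""
    for section in ("expression", "imaging"):
        sec = config.get(section) or {}
        for key, value in sec.items():
            if key.endswith("_path") or key in {"matrix", "genes", "cells", "meta", "gmt", "cells_path", "plaques"}:
                if not Path(value).exists():
                    raise FileNotFoundError(f"{section}.{key}: no such file {value}")


def run_pipeline(config: dict, outdir) -> Path:
    """Execute all configured stages; returns the run directory.

    On stage failure, partial outputs are retained alongside a
    ``FAILED`` marker file naming the stage, and the error re-raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    validate_config(config)
    seed = int(config.get("seed", 0))
    provenance = {"config": config, "seeds": {"master": seed}, "stages": []}
    timings: list[str] = []
    current_stage = "setup"
    try:
        # --- expression branch -------------------------------------------
        t0 = time.perf_counter()
        current_stage = "input"
        expr_cfg = config.get("expression", {}) or {}
        if "matrix" in expr_cfg:
            dataset = read_expression(
                expr_cfg["matrix"], expr_cfg["genes"], expr_cfg["cells"], expr_cfg["meta"]
            )
            collection = read_gmt(expr_cfg["gmt"], min_genes=int(expr_cfg.get("min_genes", 10)))
            truth = None
        else:
            sim = ExpressionSimConfig(**{**expr_cfg.get("simulate", {}), "seed": seed})
            dataset, collection, truth = simulate_expression(sim)
            _write_csv(truth, outdir / "truth_expression.csv", "simulate", {"seed": seed})
        sample_meta = (
            truth.attrs["sample_meta"]
            if truth is not None
            else dataset.cell_meta.reset_index()
            .drop_duplicates("sample_id")[
                [c for c in ("sample_id", "diagnosis", "region", "age", "amyloid_load")
                 if c in dataset.cell_meta.reset_index().columns]
            ]
        )
        timings.append(f"input: {time.perf_counter() - t0:.2f}s, {dataset.n_cells} cells")

        current_stage = "score"
        t0 = time.perf_counter()
        sc_cfg = config.get("scoring", {}) or {}
        scores = scoring.score_cells(
            dataset,
            collection,
            method=sc_cfg.get("method", "auc"),
            max_rank_frac=float(sc_cfg.get("max_rank_frac", 0.05)),
            n_bins=int(sc_cfg.get("n_bins", 24)),
            n_ctrl=int(sc_cfg.get("n_ctrl", 100)),
            seed=seed,
        )
        _write_csv(scores, outdir / "scores.csv", "score", sc_cfg)
        timings.append(f"score: {time.perf_counter() - t0:.2f}s, {len(scores)} rows")

        current_stage = "call"
        t0 = time.perf_counter()
        call_cfg = config.get("calling", {}) or {}
        calls = calling.call_senescent(
            scores,
            dataset.cell_meta,
            group_by=call_cfg.get("group_by", "cell_type"),
            k_mad=float(call_cfg.get("k_mad", 3.0)),
            mad_scale=float(call_cfg.get("mad_scale", calling.NORMAL_MAD_SCALE)),
        )
        _write_csv(calls, outdir / "calls.csv", "call", call_cfg)
        props = calling.sample_proportions(
            calls,
            dataset.cell_meta,
            stratify_by=call_cfg.get("stratify_by", "cell_type"),
            min_cells=int(call_cfg.get("min_cells", 3)),
        )
        _write_csv(props, outdir / "proportions.csv", "proportions", call_cfg)
        timings.append(f"call: {time.perf_counter() - t0:.2f}s, {len(calls)} rows")

        current_stage = "contrast"
        t0 = time.perf_counter()
        con_cfg = config.get("contrast", {}) or {}
        effects = stats.contrast_proportions(
            props,
            sample_meta,
            contrast=con_cfg.get("contrast", "diagnosis"),
            stratify_by=con_cfg.get("stratify_by", "cell_type"),
            n_boot=int(con_cfg.get("n_boot", 2000)),
            seed=seed,
        )
        _write_csv(effects, outdir / "effects.csv", "contrast", con_cfg)
        timings.append(f"contrast: {time.perf_counter() - t0:.2f}s, {len(effects)} rows")

        current_stage = "agefit"
        t0 = time.perf_counter()
        age_cfg = config.get("agefit", {}) or {}
        cell_type = age_cfg.get("cell_type", "Micro")
        per_sample = scoring.mean_score_per_group(
            scores[scores["cell_id"].isin(
                dataset.cell_meta.index[dataset.cell_meta["cell_type"] == cell_type]
            )],
            dataset.cell_meta,
            group_by="sample_id",
        ).merge(sample_meta, on="sample_id")
        fit_rows = []
        for diag, grp in per_sample.groupby("diagnosis"):
            try:
                fit = plateau.fit_linear_plateau(grp["age"], grp["mean_score"])
                fit_rows.append(
                    {"diagnosis": diag, "intercept": fit.intercept, "slope": fit.slope,
                     "breakpoint": fit.breakpoint, "plateau": fit.plateau,
                     "rss": fit.rss, "p_value": fit.p_value, "n": fit.n, "skipped": ""}
                )
            except ValueError as exc:
                fit_rows.append({"diagnosis": diag, "skipped": str(exc)})
        _write_csv(pd.DataFrame(fit_rows), outdir / "agefit.csv", "agefit", age_cfg)
        timings.append(f"agefit: {time.perf_counter() - t0:.2f}s")

        current_stage = "meta"
        t0 = time.perf_counter()
        effects_list = []
        for region, grp in per_sample.groupby("region"):
            arms = grp["diagnosis"].value_counts()
            if arms.get("AD", 0) >= 2 and arms.get("NDC", 0) >= 2:
                effects_list.append(
                    meta.dataset_effect(
                        grp["mean_score"], grp["diagnosis"], dataset_id=str(region)
                    )
                )
        if effects_list:
            pooled = meta.pool_random_effects(effects_list)
            meta_df = meta.forest_table(effects_list, pooled)
        else:
            meta_df = pd.DataFrame(columns=["dataset_id", "g", "ci_low", "ci_high", "pooled"])
        _write_csv(meta_df, outdir / "meta.csv", "meta", {})
        timings.append(f"meta: {time.perf_counter() - t0:.2f}s, {len(effects_list)} datasets")

        # --- imaging branch (optional) -----------------------------------
        img_cfg = config.get("imaging")
        if img_cfg is not None:
            current_stage = "imaging"
            t0 = time.perf_counter()
            img_cfg = img_cfg or {}
            if "cells_path" in img_cfg:
                cells = read_imaging_cells(img_cfg["cells_path"], img_cfg.get("schema"))
                plaques = read_plaques(
                    img_cfg["plaques"], float(img_cfg.get("scale_um_per_px", 1.0))
                )
            else:
                sim = ImagingSimConfig(**{**img_cfg.get("simulate", {}), "seed": seed + 1})
                cells, plaques, img_truth = simulate_imaging(sim)
                _write_csv(img_truth, outdir / "truth_imaging.csv", "imaging", {"seed": seed + 1})
            trimmed, _rec = spatial.qc_trim(
                cells, trim_frac=float(img_cfg.get("trim_frac", 0.01))
            )
            rules = {
                ch: ("otsu",) for ch in trimmed.channels
            }
            marker_calls = spatial.call_markers(trimmed, rules)
            proximity = spatial.classify_peri_plaque(
                trimmed, plaques,
                radius_um=float(img_cfg.get("radius_um", 10.0)),
                mode=img_cfg.get("mode", "centroid"),
            )
            _write_csv(proximity, outdir / "proximity.csv", "imaging", img_cfg)
            cluster_markers = {
                ct: marker for ct, marker in
                (img_cfg.get("cluster_markers") or
                 {"Micro": "Iba1", "Astro": "GFAP", "Oligo": "OLIG2", "Neuron": "MAP2"}).items()
            }
            if "cluster_label" in trimmed.table.columns:
                imc_props = spatial.senescent_proportion_per_cluster(
                    marker_calls,
                    trimmed.table["cluster_label"],
                    cluster_markers,
                    min_cells=int(img_cfg.get("min_cells", 3)),
                )
                _write_csv(imc_props, outdir / "imc_proportions.csv", "imaging", img_cfg)
            peri_props, peri_tests = spatial.peri_vs_nonplaque_contrast(
                proximity, marker_calls
            )
            _write_csv(peri_props, outdir / "peri_proportions.csv", "imaging", img_cfg)
            with open(outdir / "peri_tests.json", "w") as fh:
                json.dump(peri_tests, fh, indent=2, sort_keys=True)
            timings.append(f"imaging: {time.perf_counter() - t0:.2f}s")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={current_stage}: {exc}\n")
        raise

    provenance["stages"] = [t.split(":")[0] for t in timings]
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(timings) + "\n")
    return outdir
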