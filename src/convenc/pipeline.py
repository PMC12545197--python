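"""Orchestration of the full sweep over modes, layers and context lengths.

Ties the stages together: design assembly -> banded ridge LOSO fits ->
cross-modality scoring -> variance partitioning -> weight correlations, for
every (mode, layer, context) cell of a configuration, with per-cell caching
keyed by a configuration hash so interrupted sweeps resume.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import encoding, features, partitioning, weights
from .features import DesignMatrix, assemble_design, fir_expand
from .simulate import BoldData, EmbeddingStore

log = logging.getLogger("convenc")

#: The full analysis menu: 13 layers (input layer and every third transformer
#: layer of a 36-layer model) x 6 context lengths.
FULL_LAYERS = tuple(range(0, 37, 3))
FULL_CONTEXTS = (1, 2, 4, 8, 16, 32)


@dataclass
class RunConfig:
    """Validated sweep configuration, serialized verbatim into every output."""

    layers: tuple[int, ...] = (0,)
    contexts: tuple[int, ...] = (1,)
    modes: tuple[str, ...] = ("separate", "production_only", "comprehension_only")
    alpha_min_exp: float = -2.0
    alpha_max_exp: float = 7.0
    n_alphas: int = 10
    n_inner_folds: int = 5
    n_perm: int = 0
    block_tr: int = 20
    threshold_r: float = 0.05
    fdr_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.layers = tuple(int(l) for l in self.layers)
        self.contexts = tuple(int(c) for c in self.contexts)
        self.modes = tuple(self.modes)
        for l in self.layers:
            if l not in FULL_LAYERS:
                log.warning("layer %d is outside the standard menu %s", l, FULL_LAYERS)
        for c in self.contexts:
            if c not in FULL_CONTEXTS:
                log.warning("context %d s is outside the standard menu %s", c, FULL_CONTEXTS)
        bad = set(self.modes) - set(features.MODES)
        if bad:
            raise ValueError(f"unknown modes: {sorted(bad)}")

    @property
    def alphas(self) -> np.ndarray:
        return np.logspace(self.alpha_min_exp, self.alpha_max_exp, self.n_alphas)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def enumerate_cells(layers=FULL_LAYERS, contexts=FULL_CONTEXTS) -> list[tuple[int, int]]:
    """All (layer, context) feature combinations of the full analysis grid."""
    return [(l, c) for l in layers for c in contexts]


def _cell_dir(out_dir: Path, config: RunConfig, layer: int, context: int) -> Path:
    return Path(out_dir) / f"cell_layer{layer}_context{context}"


def run_cell(
    config: RunConfig,
    store: EmbeddingStore,
    bold: BoldData,
    layer: int,
    context: int,
) -> dict:
    """Fit all configured modes for one (layer, context) cell.

    Returns a dict with per-mode encoding results, cross-modality scores,
    the variance partition and tuning correlations.
    """
    Y, _ = features.preprocess_bold(bold.values, bold.run_index)
    results: dict[str, encoding.EncodingResult] = {}
    designs: dict[str, DesignMatrix] = {}
    for mode in config.modes:
        design = fir_expand(assemble_design(store, mode, layer, context))
        res = encoding.run_loso(
            design,
            Y,
            alphas=config.alphas,
            n_inner_folds=config.n_inner_folds,
            n_perm=config.n_perm,
            block_tr=config.block_tr,
            seed=config.seed,
        )
        results[mode] = res
        designs[mode] = design

    out: dict = {"results": results, "designs": designs, "layer": layer, "context": context}
    if "separate" in results:
        sep = results["separate"]
        swapped = encoding.swap_band_weights(sep)
        out["r_cross"] = encoding.score_loso(designs["separate"], Y, swapped)
        out["tuning_correlation"] = weights.cross_modal_tuning_correlation(sep, designs["separate"])
    if {"separate", "production_only", "comprehension_only"} <= set(results):
        pmap = partitioning.compute_partition(
            results["separate"].mean_r,
            results["production_only"].mean_r,
            results["comprehension_only"].mean_r,
        )
        partitioning.best_partition_label(pmap, results["separate"].mean_r, config.threshold_r)
        out["partition"] = pmap
    return out


def _cell_tables(cell: dict) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}
    vox = pd.DataFrame({f"r_{mode}": res.mean_r for mode, res in cell["results"].items()})
    if "r_cross" in cell:
        vox["r_cross"] = cell["r_cross"]
        vox["tuning_correlation"] = cell["tuning_correlation"]
    sep = cell["results"].get("separate")
    if sep is not None and sep.q is not None:
        vox["p_combined"] = sep.combined_p
        vox["q"] = sep.q
    vox.index.name = "voxel"
    tables["voxels"] = vox
    if "partition" in cell:
        tables["partition"] = cell["partition"].frame()
    return tables


def run_sweep(config: RunConfig, store: EmbeddingStore, bold: BoldData, out_dir) -> dict:
    """Execute every (layer, context) cell, caching each under ``out_dir``.

    A cell whose output directory already holds tables written under the same
    config hash is skipped; a rerun with the same config therefore produces
    byte-identical result tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") != config.config_hash:
            raise ValueError(
                "output directory holds results for a different configuration; refusing to mix"
            )
    else:
        manifest = {"config_hash": config.config_hash, "config": json.loads(config.to_json()), "cells": {}}

    cells = {}
    for layer in config.layers:
        for context in config.contexts:
            cdir = _cell_dir(out_dir, config, layer, context)
            key = f"layer{layer}_context{context}"
            if manifest["cells"].get(key) == "done" and cdir.exists():
                log.info("cell %s cached; skipping", key)
                continue
            t0 = time.perf_counter()
            try:
                cell = run_cell(config, store, bold, layer, context)
            except Exception:
                manifest["cells"][key] = "failed"
                manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
                raise
            cdir.mkdir(parents=True, exist_ok=True)
            for name, table in _cell_tables(cell).items():
                table.round(10).to_csv(cdir / f"{name}.tsv", sep="\t")
            (cdir / "config.json").write_text(config.to_json())
            manifest["cells"][key] = "done"
            manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
            cells[key] = cell
            log.info("cell %s finished in %.1f s", key, time.perf_counter() - t0)
    return cells


def write_report(out_dir) -> pd.DataFrame:
    """Summarize all completed cells of a sweep directory.

    One row per cell: voxel-mean accuracy per mode, cross-modality accuracy,
    partition component means (square-root scale). Also records, per
    modality, the context length maximizing the mean unique variance — the
    timescale-selectivity summary.
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if not manifest_path.exists():
        raise ValueError("no manifest found; nothing to report")
    manifest = json.loads(manifest_path.read_text())
    rows = []
    for key, status in manifest["cells"].items():
        if status != "done":
            continue
        layer, context = key.replace("layer", "").split("_context")
        cdir = out_dir / f"cell_{key}"
        vox = pd.read_csv(cdir / "voxels.tsv", sep="\t", index_col=0)
        row = {"layer": int(layer), "context": int(context)}
        for col in vox.columns:
            if col.startswith("r_") or col == "tuning_correlation":
                row[f"mean_{col}"] = vox[col].mean()
        ppath = cdir / "partition.tsv"
        if ppath.exists():
            part = pd.read_csv(ppath, sep="\t", index_col=0)
            for col in ("sqrt_unique_production", "sqrt_unique_comprehension", "sqrt_shared"):
                row[f"mean_{col}"] = part[col].mean()
        rows.append(row)
    if not rows:
        raise ValueError("no completed cells to report")
    summary = pd.DataFrame(rows).sort_values(["layer", "context"]).reset_index(drop=True)

    peaks = {}
    if "mean_sqrt_unique_production" in summary:
        for modality in ("production", "comprehension"):
            col = f"mean_sqrt_unique_{modality}"
            best = summary.loc[summary.groupby("layer")[col].idxmax()]
            peaks[f"peak_context_{modality}"] = float(best["context"].mean())
    summary.attrs["peaks"] = peaks
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    (out_dir / "summary_peaks.json").write_text(json.dumps(peaks, indent=2, sort_keys=True))
    return summary
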