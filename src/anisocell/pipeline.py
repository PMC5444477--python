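"""End-to-end pipeline: generate → render → segment → measure → compare.

Configuration lives in a YAML file (see :func:`default_config` for the
schema with defaults); every stage can also be run standalone on prior
outputs via the CLI. All randomness flows from one master seed, split per
replicate and stage; the run manifest records the config hash and every
derived seed.

Two comparison routes are supported (``compare_on``):

``truth``
    The growth statistics run on the generator's ground-truth per-cell
    tables — the oracle-exact route used for statistical validation.
``measured``
    The tables come from the full image route (render → segment → clip →
    measure → assign layers/positions), with the growth spec then applied
    to the measured cells; this exercises every stage end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .core import LabeledVolume
from .geometry import (
    alternating_layer_selection,
    assign_layers,
    assign_position,
    fit_bezier_axis,
    measure_labeled_volume,
)
from .segmentation import (
    SegmentationConfig,
    autoseed_watershed,
    blur_stack,
    clip_boundary_cells,
    filter_small_segments,
    fuse_labels,
    jaccard_recovery,
)
from .stats import LayerGrowthModel
from .synthetic import (
    GrowthSpec,
    OrganSpec,
    apply_growth,
    apply_growth_records,
    build_tissue,
    render_membrane_stack,
)

log = logging.getLogger("anisocell")


def default_config() -> dict:
    """Default pipeline configuration (YAML-serialisable dict).

    The default scene is a compact organ segment — four concentric layers,
    roughly a 64³ stack with ~230 cells per replicate, four replicates and
    two time points — sized so a full run finishes in well under a minute
    while exercising every stage.
    """
    return {
        "seed": 0,
        "compare_on": "truth",
        "organ": {
            "organ_radius": 21.0,
            "segment_length": 40.0,
            "n_layers": 4,
            "per_layer_cell_dims": [
                [8.0, 4.0, 5.0],
                [10.0, 5.0, 6.0],
                [10.0, 5.5, 6.5],
                [9.0, 4.5, 6.0],
            ],
            "voxel_spacing": [0.7, 0.7, 0.7],
            "axis_curvature": 0.0,
        },
        "growth": {
            "sigma": 0.1,
            "n_replicates": 4,
            "time_t0": 4.0,
            "time_t1": 18.0,
            "ratios": {
                "long": {"H1": 1.5, "H2": 1.2},
                "rad": {"H1": 1.2, "H2": 1.1},
                "circ": {"H1": 1.05, "H2": 1.05},
            },
            "per_layer": {},
        },
        "segmentation": {
            "blur_radius": 0.5,
            "seed_h_depth": 0.15,
            "merge_threshold": 0.0,
            "min_volume": 50.0,
            "mesh_cube_size": 0.3,
            "smooth_passes": 0,
        },
        "render": {"blur_sigma": 0.7, "noise_sd": 0.05},
        "geometry": {
            "bezier_degree": 3,
            "position_cut": 0.5,
            "layer_selection": "all",
            "n_slabs": 1,
        },
        "stats": {"alpha": 0.05, "m": None, "ci_level": None, "n_iter": 1000},
    }


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML config, merged over the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def organ_spec(cfg: dict) -> OrganSpec:
    o = cfg["organ"]
    return OrganSpec(
        organ_radius=o["organ_radius"],
        segment_length=o["segment_length"],
        n_layers=o["n_layers"],
        per_layer_cell_dims=o.get("per_layer_cell_dims"),
        voxel_spacing=tuple(o["voxel_spacing"]),
        axis_curvature=o.get("axis_curvature", 0.0),
    )


def growth_spec(cfg: dict) -> GrowthSpec:
    g = cfg["growth"]
    n_layers = cfg["organ"]["n_layers"]
    ratios: dict[tuple[int, str, str], float] = {}
    base = g.get("ratios", {})
    per_layer = g.get("per_layer", {}) or {}
    positions = set()
    for metric, by_pos in base.items():
        positions.update(by_pos)
    for layer in range(1, n_layers + 1):
        for metric in ("long", "rad", "circ"):
            by_pos = base.get(metric, {})
            override = per_layer.get(layer, per_layer.get(str(layer), {})).get(metric, {})
            for pos in positions:
                r = override.get(pos, by_pos.get(pos, 1.0))
                ratios[(layer, pos, metric)] = float(r)
    return GrowthSpec(ratios=ratios, sigma=g.get("sigma", 0.1),
                      n_replicates=g.get("n_replicates", 4))


def seg_config(cfg: dict) -> SegmentationConfig:
    return SegmentationConfig(**cfg["segmentation"])


def _stage_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def generate_stage(cfg: dict, outdir: Path) -> dict:
    """Generate ground-truth tissues for every replicate and both time points."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = organ_spec(cfg)
    growth = growth_spec(cfg)
    g = cfg["growth"]
    seeds = _stage_seeds(cfg["seed"], 2 * growth.n_replicates)
    paths = {"replicates": []}
    for rep in range(1, growth.n_replicates + 1):
        s_build, s_grow = seeds[2 * (rep - 1)], seeds[2 * (rep - 1) + 1]
        tissue = build_tissue(spec, seed=s_build, replicate_id=rep,
                              time_hai=g.get("time_t0", 4.0),
                              position_cut=cfg["geometry"]["position_cut"])
        grown = apply_growth(tissue, growth, seed=s_grow,
                             time_hai=g.get("time_t1", 18.0))
        stack = render_membrane_stack(
            tissue.label_volume,
            blur_sigma=cfg["render"]["blur_sigma"],
            noise_sd=cfg["render"]["noise_sd"],
            seed=s_build,
        )
        base = outdir / f"rep{rep}"
        aio.write_labels(base.with_name(base.name + "_labels.tif"), tissue.label_volume,
                         seed=s_build, replicate=rep)
        aio.write_stack(base.with_name(base.name + "_membrane.tif"), stack,
                        spacing=tissue.label_volume.spacing, seed=s_build)
        aio.write_axis_json(base.with_name(base.name + "_axis.json"), tissue.axis_points)
        aio.write_cells_csv(base.with_name(base.name + "_truth_t0.csv"), tissue.records)
        aio.write_cells_csv(base.with_name(base.name + "_truth_t1.csv"), grown.records)
        paths["replicates"].append(
            {
                "replicate": rep,
                "seeds": {"build": s_build, "grow": s_grow},
                "labels": str(base) + "_labels.tif",
                "membrane": str(base) + "_membrane.tif",
                "axis": str(base) + "_axis.json",
                "truth_t0": str(base) + "_truth_t0.csv",
                "truth_t1": str(base) + "_truth_t1.csv",
            }
        )
        log.info("generated replicate %d: %d cells", rep, len(tissue.records))
    return paths


def segment_stage(cfg: dict, stack_path, out_path, truth_path=None) -> dict:
    """Segment one membrane stack; optional recovery QC against truth labels."""
    stack, spacing = aio.read_stack(stack_path)
    sc = seg_config(cfg)
    blurred = blur_stack(stack.astype(np.float32), sc.blur_radius)
    labels = autoseed_watershed(blurred, sc)
    if sc.merge_threshold > 0:
        labels = fuse_labels(labels, blurred, merge_threshold=sc.merge_threshold)
    labels = clip_boundary_cells(labels)
    vol = LabeledVolume(labels, spacing)
    aio.write_labels(out_path, vol, source=str(stack_path))
    info = {"stack": str(stack_path), "labels": str(out_path),
            "n_cells": int(len(vol.label_ids()))}
    if truth_path is not None:
        truth = aio.read_labels(truth_path)
        interior = clip_boundary_cells(truth.labels)
        ids = np.unique(interior)
        ids = ids[ids > 0]
        rec = jaccard_recovery(labels, truth.labels, truth_ids=ids.tolist())
        info["recovery"] = {
            "n_truth_interior": int(len(ids)),
            "frac_jaccard_ge_0.8": float((rec["jaccard"] >= 0.8).mean()) if len(rec) else 0.0,
            "median_jaccard": float(rec["jaccard"].median()) if len(rec) else 0.0,
        }
        log.info("segmentation recovery: %s", info["recovery"])
    return info


def measure_stage(cfg: dict, labels_path, axis_path, out_csv,
                  replicate_id=1, time_hai=4.0) -> dict:
    """Measure all cells of a label volume against a fitted Bezier axis."""
    vol = aio.read_labels(labels_path)
    pts = aio.read_axis_json(axis_path)
    axis = fit_bezier_axis(pts, degree=cfg["geometry"]["bezier_degree"])
    rec = measure_labeled_volume(vol, axis, replicate_id=replicate_id, time_hai=time_hai)
    rec = filter_small_segments(rec, seg_config(cfg).min_volume)
    rec = assign_position(rec)
    n_layers = cfg["organ"]["n_layers"]
    rec = assign_layers(rec, n_layers, n_slabs=cfg["geometry"].get("n_slabs", 1))
    aio.write_cells_csv(out_csv, rec)
    return {"labels": str(labels_path), "cells_csv": str(out_csv),
            "n_cells": int(len(rec)), "axis_fit_rms_um": axis.fit_rms}


def compare_stage(cfg: dict, t0_csv_paths, t1_csv_paths, out_csv, out_json) -> dict:
    """Pool per-cell tables across replicates and run the growth comparison."""
    t0 = pd.concat([aio.read_cells_csv(p) for p in t0_csv_paths], ignore_index=True)
    t1 = pd.concat([aio.read_cells_csv(p) for p in t1_csv_paths], ignore_index=True)
    st = cfg["stats"]
    layers = None
    if cfg["geometry"].get("layer_selection") == "alternating":
        wanted = alternating_layer_selection(cfg["organ"]["n_layers"])
        present = set(t0["layer"].unique()) & set(t1["layer"].unique())
        layers = [l for l in wanted if l in present]
    model = LayerGrowthModel(t0, t1, layers=layers, alpha=st["alpha"],
                             m=st["m"], ci_level=st["ci_level"])
    results = model.fit()
    results.to_csv(out_csv)
    results.to_json(out_json)
    log.info("compare: %d comparisons, corrected level %.1f%%",
             len(results.table), 100 * model.corrected_level)
    return {"results_csv": str(out_csv), "results_json": str(out_json),
            "corrected_level": model.corrected_level,
            "n_comparisons": int(len(results.table))}


def run(cfg: dict, outdir) -> dict:
    """Run the full pipeline; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": cfg["seed"],
        "stages": {},
    }
    try:
        gen = generate_stage(cfg, outdir / "generate")
        manifest["stages"]["generate"] = gen

        seg_infos, measured_t0 = [], []
        for rep_info in gen["replicates"]:
            rep = rep_info["replicate"]
            seg_out = outdir / "segment" / f"rep{rep}_segmented.tif"
            seg_out.parent.mkdir(parents=True, exist_ok=True)
            seg_infos.append(
                segment_stage(cfg, rep_info["membrane"], seg_out,
                              truth_path=rep_info["labels"])
            )
            meas_csv = outdir / "measure" / f"rep{rep}_cells_t0.csv"
            meas_csv.parent.mkdir(parents=True, exist_ok=True)
            src_labels = (seg_out if cfg["compare_on"] == "measured"
                          else rep_info["labels"])
            measure_stage(cfg, src_labels, rep_info["axis"], meas_csv,
                          replicate_id=rep, time_hai=cfg["growth"].get("time_t0", 4.0))
            measured_t0.append(str(meas_csv))
        manifest["stages"]["segment"] = seg_infos
        manifest["stages"]["measure"] = {"cells_t0": measured_t0}

        if cfg["compare_on"] == "measured":
            # apply the growth spec to the measured cells to obtain t1 tables
            growth = growth_spec(cfg)
            seeds = _stage_seeds(cfg["seed"] + 1, len(measured_t0))
            t1_paths = []
            for s, p in zip(seeds, measured_t0):
                rec = aio.read_cells_csv(p)
                grown_rec = apply_growth_records(
                    rec, growth, seed=s, time_hai=cfg["growth"].get("time_t1", 18.0)
                )
                out = Path(p).with_name(Path(p).name.replace("_t0", "_t1"))
                aio.write_cells_csv(out, grown_rec)
                t1_paths.append(str(out))
            t0_paths = measured_t0
        else:
            t0_paths = [r["truth_t0"] for r in gen["replicates"]]
            t1_paths = [r["truth_t1"] for r in gen["replicates"]]

        cmp_dir = outdir / "compare"
        cmp_dir.mkdir(parents=True, exist_ok=True)
        manifest["stages"]["compare"] = compare_stage(
            cfg, t0_paths, t1_paths, cmp_dir / "results.csv", cmp_dir / "results.json"
        )
    except Exception as exc:
        failed = len(manifest["stages"])
        stage_names = ["generate", "segment/measure", "compare"]
        name = stage_names[min(failed, len(stage_names) - 1)]
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
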