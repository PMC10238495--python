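"""End-to-end pipeline orchestration with config, logging and manifests.

A run executes the enabled stages in method order — preprocess (entropy
slice filtering + projection), segment-cells, track-cells, label-ridges,
static metrics (persistence length, pattern wavelength, branch lengths) —
on an input stack, writing every artifact into the output directory and a
manifest JSON listing each output with its SHA-256 checksum.  The config is
serialized alongside the outputs for provenance.  All non-CNN stages are
pure functions of (inputs, config, seed), so re-running with the same
config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import cells, geometry, labeling, patterns, preprocessing, tracking

logger = logging.getLogger("ridgemetrics")

DEFAULT_CONFIG = {
    "seed": 0,
    "pixel_size_um": 0.1977,
    "preprocess": {"enabled": True, "global_threshold": 5.0,
                   "local_threshold": float("inf")},
    "segment_cells": {"enabled": True, "min_area": 100.0, "min_solidity": 0.8,
                      "close_radius": 2, "butterworth_n": 1, "butterworth_d0": 3.0},
    "track_cells": {"enabled": True, "cutoff_um": 2.5},
    "label_ridges": {"enabled": True},
    "metrics": {"enabled": True, "temperature_K": 300.0},
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


def load_config(overrides: dict | None = None) -> dict:
    """Default config updated with overrides; unknown top-level keys rejected."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))   # deep copy
    if overrides:
        unknown = set(overrides) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in overrides.items():
            if isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(stack: np.ndarray, out_dir, config: dict | None = None) -> dict:
    """Run the enabled stages on an XYZT (or ZYX) stack; return the manifest.

    Raises with the failing stage's name on error; the partial manifest is
    attached to the exception.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": {}, "artifacts": []}
    psz = cfg["pixel_size_um"]

    def record(path: Path, stage: str):
        manifest["artifacts"].append(
            {"path": str(path.relative_to(out)), "stage": stage,
             "sha256": _sha256(path)})

    (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))
    record(out / "config.json", "config")

    stage = "preprocess"
    try:
        if cfg["preprocess"]["enabled"]:
            frames, selection = preprocessing.select_and_project(
                stack, cfg["preprocess"]["global_threshold"],
                cfg["preprocess"]["local_threshold"], dx=psz, dy=psz)
            proj = np.stack([f.values for f in frames]).astype(np.float32)
            tifffile.imwrite(out / "projection.tif", proj)
            record(out / "projection.tif", stage)
            pd.DataFrame([{"t": t, "kept_z": ",".join(map(str, zs))}
                          for t, zs in enumerate(selection.kept_indices)]
                         ).to_csv(out / "kept_slices.csv", index=False)
            record(out / "kept_slices.csv", stage)
            manifest["stages"][stage] = {"n_frames": len(frames)}
        else:
            frames = None

        stage = "segment_cells"
        all_cells = []
        if cfg["segment_cells"]["enabled"]:
            if frames is None:
                raise RuntimeError("segment_cells requires the preprocess stage")
            sc = cfg["segment_cells"]
            rows = []
            for t, frame in enumerate(frames):
                smooth = cells.gaussian_smooth(frame)
                hp = cells.butterworth_highpass(smooth, n=sc["butterworth_n"],
                                                D0=sc["butterworth_d0"])
                mask = cells.close_membranes(hp, close_radius=sc["close_radius"])
                regs = cells.extract_cells(mask, smooth, sc["min_area"],
                                           sc["min_solidity"])
                all_cells.append(regs)
                for i, c in enumerate(regs):
                    tifffile.imwrite(out / f"cell_{t:04d}_{i:04d}.tif",
                                     c.patterned_image.values.astype(np.float32))
                    record(out / f"cell_{t:04d}_{i:04d}.tif", stage)
                    rows.append({"t": t, "cell_id": i, "area_px2": c.area,
                                 "solidity": c.solidity,
                                 "x_px": c.centroid[0], "y_px": c.centroid[1]})
            pd.DataFrame(rows).to_csv(out / "cells.csv", index=False)
            record(out / "cells.csv", stage)
            manifest["stages"][stage] = {"n_cells": sum(map(len, all_cells))}

        stage = "track_cells"
        if cfg["track_cells"]["enabled"] and all_cells:
            frames_xy = [[(c.centroid[0] * psz, c.centroid[1] * psz)
                          for c in regs] for regs in all_cells]
            tracks = tracking.track_cells(frames_xy,
                                          cutoff=cfg["track_cells"]["cutoff_um"])
            rows = [{"track_id": tr.track_id, "t": t, "cell_id": cid,
                     "x_um": xy[0], "y_um": xy[1]}
                    for tr in tracks for (t, cid, xy) in tr.samples]
            pd.DataFrame(rows).to_csv(out / "tracks.csv", index=False)
            record(out / "tracks.csv", stage)
            manifest["stages"][stage] = {"n_tracks": len(tracks)}

        stage = "label_ridges"
        labeled = []
        if cfg["label_ridges"]["enabled"] and all_cells:
            for t, regs in enumerate(all_cells):
                for i, c in enumerate(regs):
                    pair = labeling.label_cell(c.patterned_image)
                    labeled.append((t, i, pair))
                    tifffile.imwrite(out / f"label_{t:04d}_{i:04d}.tif",
                                     pair.label.astype(np.uint8))
                    record(out / f"label_{t:04d}_{i:04d}.tif", stage)
            manifest["stages"][stage] = {"n_labeled": len(labeled)}

        stage = "metrics"
        if cfg["metrics"]["enabled"] and labeled:
            rows, ks_pool = [], []
            for t, i, pair in labeled:
                if not pair.label.any():
                    continue
                try:
                    spec = patterns.pattern_wavelength(pair.label, psz)
                    lam = spec.lam
                except ValueError:
                    lam = float("nan")
                bs = patterns.branch_stats(pair.label, psz)
                traces, _ = geometry.trace_branches(pair.label, psz, psz)
                for tr in traces:
                    sm = geometry.orient_and_smooth(tr)
                    dense = geometry.spline_interpolate(sm, factor=3)
                    ks_pool.append(geometry.curvature_series(dense).kappa_s)
                rows.append({"t": t, "cell_id": i, "lambda_um": lam,
                             "mean_branch_len_um": bs.mean_branch_length,
                             "n_branches": bs.n_branches})
            pd.DataFrame(rows).to_csv(out / "pattern_metrics.csv", index=False)
            record(out / "pattern_metrics.csv", stage)
            summary = {}
            if ks_pool:
                pool = np.concatenate(ks_pool)
                if len(pool) >= 3 and np.mean(pool ** 2) > 0:
                    est = geometry.fit_lp(pool, cfg["metrics"]["temperature_K"])
                    summary = {"lp_um": est.lp, "ei_Nm2": est.ei,
                               "n_segments": est.n_segments,
                               "fc_1um_pN": geometry.critical_force(
                                   est.lp, 1.0, cfg["metrics"]["temperature_K"])}
            (out / "summary.json").write_text(json.dumps(summary, indent=2))
            record(out / "summary.json", stage)
            manifest["stages"][stage] = summary
    except Exception as exc:
        exc.partial_manifest = manifest
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %d artifacts", len(manifest["artifacts"]))
    return manifest
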