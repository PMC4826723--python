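"""End-to-end orchestration: read -> preprocess -> segment -> torsion -> report.

``run_pipeline`` executes the full analysis described by a :class:`RunConfig`
and writes, into the run directory:

* ``curves_<upper>-<lower>.csv`` — columns t_ms, T_full, T_endo, T_epi;
* ``summary.json`` — per slice pair and layer: peak torsion, its time, layer
  radii, and the transmural summary;
* ``config.yaml`` — the effective configuration of the run;
* ``run.log`` — stage timings and warnings.

Given identical inputs, configuration and seeds, the summary JSON is
byte-identical between runs.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .preprocess import preprocess_series
from .segmentation import MyoSegmentation, load_contours, segment_series
from .torsion import (
    LAYERS,
    compute_rotation_trace,
    correct_translation,
    torsion_curve,
    transmural_summary,
)
from .velocity_io import SliceSet, read_tpm

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("tpmtorsion")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and preserved artifacts."""

    def __init__(self, stage: str, message: str, artifacts: list[str]):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.artifacts = artifacts


def _stage(name: str, log_lines: list[str]):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            status = "failed" if exc else "ok"
            log_lines.append(f"{name}: {status} ({dt:.2f} s)")
            return False

    return _Timer()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full torsion analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    artifacts: list[str] = []

    def fail(stage: str, exc: Exception):
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(stage, str(exc), artifacts) from exc

    # --- read ------------------------------------------------------------
    series = {}
    try:
        with _stage("read", log_lines):
            for lab, path in config.series_paths.items():
                series[lab] = read_tpm(path, format_hint=config.input_format)
    except Exception as exc:  # noqa: BLE001
        fail("read", exc)

    # --- preprocess ------------------------------------------------------
    reports = {}
    try:
        with _stage("preprocess", log_lines):
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                for lab in series:
                    series[lab], reports[lab] = preprocess_series(
                        series[lab],
                        roi=config.roi,
                        sd_threshold_mm_s=config.sd_threshold_mm_s,
                        filter_method=config.filter_method,
                        random_state=config.random_state,
                    )
            log_lines += [f"warning: {w.message}" for w in caught]
    except Exception as exc:  # noqa: BLE001
        fail("preprocess", exc)

    # --- segment ---------------------------------------------------------
    segs: dict[str, MyoSegmentation] = {}
    try:
        with _stage("segment", log_lines):
            for lab in series:
                if lab not in config.contour_paths:
                    raise FileNotFoundError(f"no contour file configured for slice {lab!r}")
                pair = load_contours(config.contour_paths[lab])
                segs[lab] = segment_series(
                    series[lab],
                    pair,
                    refine=config.refine,
                    rk_order=config.rk_order,
                    alpha=config.snake_alpha,
                    beta=config.snake_beta,
                    w_ext=config.snake_w_ext,
                )
    except Exception as exc:  # noqa: BLE001
        fail("segment", exc)

    # --- torsion ---------------------------------------------------------
    try:
        with _stage("torsion", log_lines):
            sliceset = SliceSet(series={
                lab: correct_translation(series[lab], segs[lab].mask) for lab in series
            })
            summary: dict = {"slice_pairs": {}}
            for upper, lower in config.pairs():
                if upper not in series or lower not in series:
                    continue
                h = sliceset.distance_mm(upper, lower)
                curves = {}
                for layer in LAYERS:
                    tu = compute_rotation_trace(sliceset.series[upper], segs[upper], layer)
                    tl = compute_rotation_trace(sliceset.series[lower], segs[lower], layer)
                    curves[layer] = torsion_curve(tu, tl, h)
                trans = transmural_summary(curves["endo"], curves["epi"])
                key = f"{upper}-{lower}"
                pd.DataFrame({
                    "t_ms": curves["full"].t_ms,
                    "T_full": curves["full"].values,
                    "T_endo": curves["endo"].values,
                    "T_epi": curves["epi"].values,
                }).to_csv(out / f"curves_{key}.csv", index=False)
                artifacts.append(f"curves_{key}.csv")
                summary["slice_pairs"][key] = {
                    "h_mm": h,
                    "layers": {
                        layer: {
                            "T_max": curves[layer].T_max,
                            "t_peak_ms": curves[layer].t_peak_ms,
                        }
                        for layer in LAYERS
                    },
                    "dT_max": trans.dT_max,
                    "dPctT_max": None if np.isnan(trans.dPctT_max) else trans.dPctT_max,
                }
            summary["preprocess"] = reports
    except Exception as exc:  # noqa: BLE001
        fail("torsion", exc)

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    artifacts.append("summary.json")
    config.to_yaml(out / "config.yaml")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
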