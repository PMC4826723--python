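"""Run configuration: every tunable of the pipeline in one serialisable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    Defaults marked "protocol" match the acquisition/analysis protocol the
    package implements (stationary-tissue SD threshold 5 mm/s, 3x3 low-pass
    filter, 5-ms curve resampling, EF cut at 50%); the rest are package
    choices.
    """

    # inputs: slice label -> series path, and slice label -> contour JSON path
    series_paths: dict[str, str] = field(default_factory=dict)
    contour_paths: dict[str, str] = field(default_factory=dict)
    input_format: str | None = None

    # preprocessing
    roi: tuple[int, int, int, int] = (0, 0, 0, 0)  # (row0, col0, row1, col1)
    sd_threshold_mm_s: float = 5.0  # protocol
    filter_method: str = "mean"  # protocol (3x3 low-pass); or "median"/"none"

    # segmentation
    refine: bool = False
    rk_order: int = 4
    snake_alpha: float = 0.1
    snake_beta: float = 0.1
    snake_w_ext: float = 1.0

    # torsion
    slice_pairs: list[str] = field(
        default_factory=lambda: ["base-apex", "base-mid", "mid-apex"]
    )
    resample_dt_ms: float = 5.0  # protocol
    layer_radius: str = "per_layer"  # or "whole_mask"

    # statistics
    ef_threshold_pct: float = 50.0  # protocol
    relative_error_mode: str = "pairwise"

    # misc
    random_state: int = 0
    out_dir: str = "tpm_run"

    def pairs(self) -> list[tuple[str, str]]:
        return [tuple(p.split("-", 1)) for p in self.slice_pairs]  # type: ignore[misc]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.roi = tuple(cfg.roi)  # type: ignore[assignment]
        return cfg
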