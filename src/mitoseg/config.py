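"""Pipeline configuration.

All numeric defaults are the operating point of the published three-step
segmentation procedure for serial block-face EM at ~10 nm XY / 50-70 nm Z
voxel size: 11x11 raw-intensity patches for the texture classifier, seven
isocontour levels spaced 14% apart, perimeter gates of 0.6-6 um matching
mitochondrial cross-section sizes, a 0.4 um center-distance gate for
adjacent-plane contour pairs, a saliency probability threshold of 0.25,
10-pixel erosion of salient-contour interiors for level-set seeding, and
geodesic active contour scalings of 160 (advection), 6.75 (curvature) and
1 (propagation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig", "load_config"]


def _default_iso_levels() -> list[float]:
    return [0.12, 0.26, 0.40, 0.54, 0.68, 0.82, 0.96]


def _default_threshold_grid() -> list[float]:
    # 0.05, 0.10, ..., 1.0
    return [round(0.05 * k, 2) for k in range(1, 21)]


@dataclass
class PipelineConfig:
    """Knobs for every stage of the pipeline, with the published defaults.

    Lengths are physical (micrometers) so the same configuration applies to
    any voxel spacing; ``erosion_px`` and ``patch_size`` are in pixels
    because the corresponding operations are defined on the XY pixel grid.
    """

    # step 1: patch classifier
    patch_size: int = 11
    n_pos_patches: int = 689
    n_neg_patches: int = 902

    # step 2: contour detection and pair classification
    iso_levels: list[float] = field(default_factory=_default_iso_levels)
    perimeter_min_um: float = 0.6
    perimeter_max_um: float = 6.0
    pair_gate_D_um: float = 0.4
    contour_set_size_M: int = 2
    pair_threshold_T: float = 0.25
    saliency_fraction: float = 0.90
    duplication_n: int = 0

    # step 3: level set
    erosion_px: int = 10
    levelset_advection: float = 160.0
    levelset_curvature: float = 6.75
    levelset_propagation: float = 1.0
    levelset_max_iterations: int = 200
    levelset_rms_tolerance: float = 0.002
    levelset_fast_march_stop: float = 25.0

    # threshold selection: minimize E = alpha*FPR + beta*(1 - TPR)
    alpha: float = 7.0
    beta: float = 1.0
    threshold_grid: list[float] = field(default_factory=_default_threshold_grid)

    # shared
    rf_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError(f"patch_size must be odd and >= 3, got {self.patch_size}")
        levels = np.asarray(self.iso_levels, dtype=float)
        if levels.size == 0 or np.any(levels <= 0) or np.any(levels >= 1):
            raise ValueError("iso_levels must lie strictly inside (0, 1)")
        if np.any(np.diff(levels) <= 0):
            raise ValueError("iso_levels must be strictly increasing")
        if not 0 < self.perimeter_min_um < self.perimeter_max_um:
            raise ValueError(
                "perimeter gates must satisfy 0 < perimeter_min_um < perimeter_max_um"
            )
        if not 0.0 <= self.pair_threshold_T <= 1.0:
            raise ValueError("pair_threshold_T must lie in [0, 1]")
        if self.contour_set_size_M not in (1, 2):
            raise ValueError("contour_set_size_M must be 1 or 2")
        if self.pair_gate_D_um <= 0:
            raise ValueError("pair_gate_D_um must be positive")
        if not 0.0 < self.saliency_fraction <= 1.0:
            raise ValueError("saliency_fraction must lie in (0, 1]")
        if self.duplication_n < 0:
            raise ValueError("duplication_n must be >= 0")
        if self.erosion_px < 0:
            raise ValueError("erosion_px must be >= 0")
        for name in ("levelset_advection", "levelset_curvature", "levelset_propagation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")

    def replace(self, **kwargs) -> "PipelineConfig":
        """Return a copy with some fields overridden (re-validated)."""
        return dataclasses.replace(self, **kwargs)


def _parse_threshold_grid(value) -> list[float]:
    """Accept either an explicit list or a 'start:step:stop' string."""
    if isinstance(value, str):
        start, step, stop = (float(v) for v in value.split(":"))
        n = int(round((stop - start) / step)) + 1
        return [round(start + k * step, 10) for k in range(n)]
    return [float(v) for v in value]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat key-value (YAML) configuration file.

    Absent keys take the published defaults; unknown keys and invariant
    violations are rejected with a descriptive error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such configuration file: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"configuration must be a flat key-value mapping, got {type(raw)!r}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "threshold_grid" in raw:
        raw["threshold_grid"] = _parse_threshold_grid(raw["threshold_grid"])
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:  # wrong value type for a field
        raise ValueError(f"malformed configuration {path}: {exc}") from exc
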