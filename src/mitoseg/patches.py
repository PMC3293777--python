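"""Step 1 — random-forest texture classification of raw 2D pixel patches.

Each voxel is described by the raw gray values of the N x N patch centered
on it within its own XY slice (no 3D context, so the step tolerates large
Z gaps). A random forest trained on a few hundred labeled patches per
class turns a whole volume into a per-voxel probability map; the
probability is the fraction of trees voting for the organelle class.
Borders are mirror-padded so the map keeps the input shape. Patches are
used raw — no normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.ensemble import RandomForestClassifier

from .io import IntensityVolume, LabelVolume

__all__ = [
    "PatchTrainingSet",
    "PatchModel",
    "ProbabilityMap",
    "extract_patch",
    "sample_training_patches",
    "train_patch_model",
    "predict_probability_map",
]


@dataclass
class PatchTrainingSet:
    """Flattened N x N patches with binary center labels."""

    vectors: np.ndarray  # (n, N*N)
    labels: np.ndarray   # (n,) in {0, 1}
    patch_size: int
    indices: np.ndarray | None = None  # (n, 3) source (z, y, x), for provenance

    @property
    def counts(self) -> tuple[int, int]:
        return int((self.labels == 1).sum()), int((self.labels == 0).sum())


@dataclass
class PatchModel:
    """A trained texture classifier over N^2-long raw gray vectors."""

    classifier: RandomForestClassifier
    patch_size: int
    metadata: dict = field(default_factory=dict)

    def predict_prob(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(vectors)
        if vectors.shape[1] != self.patch_size**2:
            raise ValueError(
                f"expected vectors of length {self.patch_size**2}, got {vectors.shape[1]}"
            )
        proba = self.classifier.predict_proba(vectors)
        pos = list(self.classifier.classes_).index(1)
        return proba[:, pos]

    def save(self, path: str | Path) -> None:
        joblib.dump({"kind": "patch_model", "model": self}, path)

    @staticmethod
    def load(path: str | Path) -> "PatchModel":
        payload = joblib.load(path)
        if payload.get("kind") != "patch_model":
            raise ValueError(f"{path} does not contain a patch model")
        return payload["model"]


@dataclass
class ProbabilityMap:
    """Per-voxel organelle probability in [0, 1], aligned to its source volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float32)
        if data.ndim != 3:
            raise ValueError("probability map must be 3D (z, y, x)")
        if data.size and (data.min() < 0 or data.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        self.data = data
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        return tuple(s / 1000.0 for s in self.spacing)


def _check_patch_size(N: int, slice_shape: tuple[int, int]) -> None:
    if N % 2 == 0 or N < 1:
        raise ValueError(f"patch size must be odd, got {N}")
    if N > 2 * min(slice_shape):
        raise ValueError(f"patch size {N} too large for slice {slice_shape}")


def extract_patch(
    volume: IntensityVolume, z: int, y: int, x: int, N: int
) -> np.ndarray:
    """Row-major flattening of the N x N neighborhood of (y, x) in slice z.

    Slice borders are mirror-padded, so any in-plane center is valid.
    """
    sl = volume.data[z]
    _check_patch_size(N, sl.shape)
    half = N // 2
    padded = np.pad(sl, half, mode="reflect")
    return padded[y : y + N, x : x + N].reshape(-1).copy()


def sample_training_patches(
    volume: IntensityVolume,
    labels: LabelVolume,
    n_pos: int,
    n_neg: int,
    N: int,
    seed: int,
) -> PatchTrainingSet:
    """Draw patch examples at uniformly sampled positive/negative voxels.

    Sampling is volume-wide, without replacement within each class, and
    deterministic for a given seed.
    """
    if volume.shape != labels.shape:
        raise ValueError("volume and labels must be aligned")
    _check_patch_size(N, volume.data.shape[1:])
    rng = np.random.default_rng(seed)
    flat = labels.data.reshape(-1)
    pos_idx = np.flatnonzero(flat == 1)
    neg_idx = np.flatnonzero(flat == 0)
    if len(pos_idx) < n_pos:
        raise ValueError(f"need {n_pos} positive voxels, found {len(pos_idx)}")
    if len(neg_idx) < n_neg:
        raise ValueError(f"need {n_neg} negative voxels, found {len(neg_idx)}")
    chosen = np.concatenate(
        [
            rng.choice(pos_idx, size=n_pos, replace=False),
            rng.choice(neg_idx, size=n_neg, replace=False),
        ]
    )
    zyx = np.column_stack(np.unravel_index(chosen, labels.shape))
    vectors = np.stack(
        [extract_patch(volume, z, y, x, N) for z, y, x in zyx]
    ).astype(np.float32)
    y_arr = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return PatchTrainingSet(vectors=vectors, labels=y_arr, patch_size=N, indices=zyx)


def train_patch_model(ts: PatchTrainingSet, rf_trees: int, seed: int) -> PatchModel:
    """Fit the random forest on a patch training set (both classes required)."""
    classes = np.unique(ts.labels)
    if len(classes) < 2:
        raise ValueError("patch training requires positive and negative examples")
    clf = RandomForestClassifier(
        n_estimators=rf_trees, random_state=seed, n_jobs=1, oob_score=True
    )
    clf.fit(ts.vectors, ts.labels)
    n_pos, n_neg = ts.counts
    return PatchModel(
        classifier=clf,
        patch_size=ts.patch_size,
        metadata={
            "n_pos": n_pos,
            "n_neg": n_neg,
            "rf_trees": rf_trees,
            "seed": seed,
            "oob_score": float(clf.oob_score_),
        },
    )


def predict_probability_map(
    model: PatchModel, volume: IntensityVolume
) -> ProbabilityMap:
    """Classify every voxel's centered 2D patch into a dense probability map.

    Slices are processed independently; within a slice, patches are
    materialized with a sliding window over the mirror-padded image and
    scored in chunks to bound memory.
    """
    N = model.patch_size
    _check_patch_size(N, volume.data.shape[1:])
    half = N // 2
    nz, ny, nx = volume.shape
    out = np.empty((nz, ny, nx), dtype=np.float32)
    pos = list(model.classifier.classes_).index(1)
    chunk = 50_000
    for z in range(nz):
        padded = np.pad(volume.data[z], half, mode="reflect")
        windows = sliding_window_view(padded, (N, N)).reshape(ny * nx, N * N)
        probs = np.empty(ny * nx, dtype=np.float32)
        for start in range(0, ny * nx, chunk):
            block = np.ascontiguousarray(
                windows[start : start + chunk], dtype=np.float32
            )
            probs[start : start + chunk] = model.classifier.predict_proba(block)[:, pos]
        out[z] = probs.reshape(ny, nx)
    return ProbabilityMap(out, volume.spacing)
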