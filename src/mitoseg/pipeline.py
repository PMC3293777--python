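"""End-to-end orchestration: train, segment, and slab splitting.

Training fits the two classifiers on a labeled volume: the patch model on
randomly sampled patches, then — on the training volume's own probability
map — contour detection, ground-truth saliency labeling (a contour is
salient when >= 90% of its interior pixels are labeled), pair gating and
featurization, optional positive duplication, and the pair/contour random
forest. The saliency threshold ``T`` is selected on a half/half split of
the training slices. Segmentation replays steps 1-3 with the trained
models and exposes every intermediate for inspection.

Volumes too large for memory are split into slabs of full XY extent and
limited Z with a small overlap so adjacent-plane pairing still sees both
neighbors at slab borders; slab results are recombined by voxelwise OR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from .config import PipelineConfig
from .contours import (
    Contour,
    ContourModel,
    ContourPair,
    attach_features,
    balance_training_pairs,
    classify_salient,
    detect_isocontours,
    enumerate_pairs,
    filter_by_perimeter,
    label_salient_ground_truth,
    rasterize_interior,
    train_contour_model,
)
from .io import IntensityVolume, LabelVolume
from .levelset import (
    LevelSetParams,
    edge_potential,
    run_geodesic_active_contour,
    seeds_from_contours,
)
from .metrics import select_threshold
from .patches import (
    PatchModel,
    ProbabilityMap,
    predict_probability_map,
    sample_training_patches,
    train_patch_model,
)

__all__ = [
    "TrainedPipeline",
    "SegmentationResult",
    "train_pipeline",
    "segment",
    "split_slabs",
    "segment_slabbed",
    "detect_and_featurize",
]


@dataclass
class TrainedPipeline:
    """Both stage models plus the configuration they were trained under."""

    patch_model: PatchModel
    contour_model: ContourModel
    config: PipelineConfig
    provenance: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump({"kind": "trained_pipeline", "bundle": self}, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedPipeline":
        payload = joblib.load(path)
        if payload.get("kind") != "trained_pipeline":
            raise ValueError(f"{path} does not contain a trained pipeline bundle")
        return payload["bundle"]


@dataclass
class SegmentationResult:
    """Final labels plus the per-stage intermediates."""

    labels: LabelVolume
    probability_map: ProbabilityMap
    contours: list[Contour]
    salient_contours: list[Contour]
    pairs: list[ContourPair]
    seeds: np.ndarray


@dataclass
class _Prepared:
    """T-independent intermediates of a segmentation run."""

    volume: IntensityVolume
    probability_map: ProbabilityMap
    contours_by_plane: dict[int, list[Contour]]
    pairs: list[ContourPair]
    pair_probs: np.ndarray | None
    contour_probs: np.ndarray | None
    contour_model: ContourModel
    speed: np.ndarray


def detect_and_featurize(
    volume: IntensityVolume,
    prob: ProbabilityMap,
    config: PipelineConfig,
) -> dict[int, list[Contour]]:
    """Detect, perimeter-gate and featurize contours on every slice.

    Iso levels reference the volume-wide probability maximum so thresholds
    are consistent across slices. Contours with an empty rasterized
    interior are dropped — they cannot be labeled or seeded.
    """
    sy, sx = volume.spacing[1], volume.spacing[2]
    ref = float(prob.data.max())
    by_plane: dict[int, list[Contour]] = {}
    for z in range(volume.shape[0]):
        cs = detect_isocontours(
            prob.data[z], config.iso_levels, (sy, sx), plane_i=z, ref_value=ref
        )
        cs = filter_by_perimeter(cs, config.perimeter_min_um, config.perimeter_max_um)
        cs = [
            c
            for c in cs
            if rasterize_interior(c, prob.data[z].shape, (sy, sx)).any()
        ]
        attach_features(cs, volume.data[z], prob.data[z], (sy, sx))
        if cs:
            by_plane[z] = cs
    return by_plane


def _clamped_counts(labels: LabelVolume, config: PipelineConfig) -> tuple[int, int]:
    """Requested patch counts, clamped to what the label volume can supply."""
    n_pos_avail = int(labels.data.sum())
    n_neg_avail = int(labels.data.size - n_pos_avail)
    n_pos = min(config.n_pos_patches, n_pos_avail)
    n_neg = min(config.n_neg_patches, n_neg_avail)
    if n_pos == 0:
        raise ValueError("training labels contain no positive voxels")
    if n_neg == 0:
        raise ValueError("training labels contain no negative voxels")
    return n_pos, n_neg


def _fit_stage_models(
    volume: IntensityVolume, labels: LabelVolume, config: PipelineConfig
) -> tuple[PatchModel, ContourModel]:
    """Fit the patch model, then the contour/pair model on its own map."""
    n_pos, n_neg = _clamped_counts(labels, config)
    ts = sample_training_patches(
        volume, labels, n_pos, n_neg, config.patch_size, config.seed
    )
    patch_model = train_patch_model(ts, config.rf_trees, config.seed)
    prob = predict_probability_map(patch_model, volume)
    by_plane = detect_and_featurize(volume, prob, config)
    sy, sx = volume.spacing[1], volume.spacing[2]
    gt: dict[int, int] = {}
    for z, cs in by_plane.items():
        for c in cs:
            gt[id(c)] = label_salient_ground_truth(
                c, labels.data[z], config.saliency_fraction, (sy, sx)
            )
    if config.contour_set_size_M == 2:
        pairs = enumerate_pairs(by_plane, config.pair_gate_D_um)
        if not pairs:
            raise ValueError("no contour pairs pass the distance gate on training data")
        X = np.stack([p.feature_vector for p in pairs])
        y = np.array([gt[id(p.a)] & gt[id(p.b)] for p in pairs], dtype=int)
    else:
        cs = [c for z in sorted(by_plane) for c in by_plane[z]]
        X = np.stack([c.features.as_array() for c in cs])
        y = np.array([gt[id(c)] for c in cs], dtype=int)
    X, y = balance_training_pairs(X, y, config.duplication_n)
    contour_model = train_contour_model(
        X, y, config.contour_set_size_M, config.rf_trees, config.seed
    )
    return patch_model, contour_model


def _levelset_params(config: PipelineConfig) -> LevelSetParams:
    return LevelSetParams(
        advection_scaling=config.levelset_advection,
        curvature_scaling=config.levelset_curvature,
        propagation_scaling=config.levelset_propagation,
        max_iterations=config.levelset_max_iterations,
        rms_convergence_tolerance=config.levelset_rms_tolerance,
        fast_march_stop=config.levelset_fast_march_stop,
    )


def prepare_segmentation(
    volume: IntensityVolume,
    patch_model: PatchModel,
    contour_model: ContourModel,
    config: PipelineConfig,
) -> _Prepared:
    """Run every threshold-independent stage once (map, contours, pair scores)."""
    prob = predict_probability_map(patch_model, volume)
    by_plane = detect_and_featurize(volume, prob, config)
    pairs: list[ContourPair] = []
    pair_probs = contour_probs = None
    if contour_model.set_size_M == 2:
        pairs = enumerate_pairs(by_plane, config.pair_gate_D_um)
        if pairs:
            pair_probs = contour_model.predict_prob(
                np.stack([p.feature_vector for p in pairs])
            )
            for p, pr in zip(pairs, pair_probs):
                p.saliency_prob = float(pr)
    else:
        cs = [c for z in sorted(by_plane) for c in by_plane[z]]
        if cs:
            contour_probs = contour_model.predict_prob(
                np.stack([c.features.as_array() for c in cs])
            )
    speed = edge_potential(prob, _levelset_params(config))
    return _Prepared(
        volume=volume,
        probability_map=prob,
        contours_by_plane=by_plane,
        pairs=pairs,
        pair_probs=pair_probs,
        contour_probs=contour_probs,
        contour_model=contour_model,
        speed=speed,
    )


def finalize_segmentation(prepared: _Prepared, config: PipelineConfig) -> SegmentationResult:
    """Apply the saliency threshold, seed, and run the level set."""
    T = config.pair_threshold_T
    volume = prepared.volume
    if prepared.contour_model.set_size_M == 2:
        salient_map: dict[int, Contour] = {}
        for p, pr in zip(prepared.pairs, prepared.pair_probs if prepared.pairs else []):
            if pr >= T:
                salient_map[id(p.a)] = p.a
                salient_map[id(p.b)] = p.b
        salient = list(salient_map.values())
    else:
        cs = [c for z in sorted(prepared.contours_by_plane) for c in prepared.contours_by_plane[z]]
        probs = prepared.contour_probs if cs else []
        salient = [c for c, pr in zip(cs, probs) if pr >= T]
    seeds = seeds_from_contours(
        salient, volume.shape, volume.spacing, config.erosion_px
    )
    if seeds.any():
        labels = run_geodesic_active_contour(
            seeds,
            prepared.speed,
            _levelset_params(config),
            volume.spacing,
            fast_march_speed=prepared.probability_map.data,
        )
    else:
        labels = LabelVolume(np.zeros(volume.shape, dtype=np.uint8), volume.spacing)
    all_contours = [
        c for z in sorted(prepared.contours_by_plane) for c in prepared.contours_by_plane[z]
    ]
    return SegmentationResult(
        labels=labels,
        probability_map=prepared.probability_map,
        contours=all_contours,
        salient_contours=salient,
        pairs=prepared.pairs,
        seeds=seeds,
    )


def train_pipeline(
    volume: IntensityVolume,
    labels: LabelVolume,
    config: PipelineConfig | None = None,
    select_T: bool = True,
) -> TrainedPipeline:
    """Train both stage models and (optionally) select the threshold ``T``.

    With ``select_T`` the threshold is chosen on a half/half split of the
    training slices before the final models are refit on all of them.
    """
    config = config or PipelineConfig()
    if volume.shape != labels.shape:
        raise ValueError("volume and labels must be aligned")
    provenance: dict = {"seed": config.seed, "n_train_slices": volume.shape[0]}
    if select_T:
        T, table = select_threshold(volume, labels, config)
        config = config.replace(pair_threshold_T=T)
        provenance["threshold_table"] = table
        provenance["selected_T"] = T
    patch_model, contour_model = _fit_stage_models(volume, labels, config)
    provenance["patch_counts"] = dict(
        zip(("n_pos", "n_neg"), (patch_model.metadata["n_pos"], patch_model.metadata["n_neg"]))
    )
    provenance["contour_examples"] = contour_model.metadata["n_examples"]
    return TrainedPipeline(
        patch_model=patch_model,
        contour_model=contour_model,
        config=config,
        provenance=provenance,
    )


def segment(volume: IntensityVolume, tp: TrainedPipeline) -> SegmentationResult:
    """Run steps 1 -> 2 -> 3 on a volume with a trained pipeline."""
    prepared = prepare_segmentation(volume, tp.patch_model, tp.contour_model, tp.config)
    return finalize_segmentation(prepared, tp.config)


def split_slabs(
    volume: IntensityVolume, max_z: int, overlap_z: int = 2
) -> list[tuple[int, int]]:
    """(start, stop) Z ranges of slabs of full XY extent covering the volume.

    Consecutive slabs share ``overlap_z`` slices so adjacent-plane pairing
    is unaffected at slab borders.
    """
    if max_z < 2:
        raise ValueError("max_z must be >= 2")
    if not 0 <= overlap_z < max_z:
        raise ValueError("overlap_z must satisfy 0 <= overlap_z < max_z")
    nz = volume.shape[0]
    starts = [0]
    while starts[-1] + max_z < nz:
        starts.append(starts[-1] + max_z - overlap_z)
    return [(s, min(s + max_z, nz)) for s in starts]


def segment_slabbed(
    volume: IntensityVolume,
    tp: TrainedPipeline,
    max_z: int,
    overlap_z: int = 2,
) -> LabelVolume:
    """Segment slab by slab and reassemble by voxelwise OR over overlaps."""
    out = np.zeros(volume.shape, dtype=np.uint8)
    for start, stop in split_slabs(volume, max_z, overlap_z):
        slab = IntensityVolume(volume.data[start:stop], volume.spacing)
        res = segment(slab, tp)
        out[start:stop] |= res.labels.data
    return LabelVolume(out, volume.spacing)
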