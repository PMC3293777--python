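"""Isocontour detection, contour/pair features, and saliency classification.

Step 2 of the pipeline. Closed isocontours are extracted from each XY slice
of the step-1 probability map at several levels, gated by perimeter, and
described by seven features (perimeter, mean raw gray on the contour, mean
probability inside, area, ellipse overlap, fitted ellipse width and
height). Contours on adjacent planes whose centers lie within a gate
distance ``D`` form pairs carrying a 22-long feature vector — the seven
features of each member, the center distance, and the seven signed
differences — which a random forest scores for saliency; pairs below a
probability threshold ``T`` are discarded and a contour is salient when it
survives in at least one pair.

All contour vertices are physical XY coordinates in micrometers; the voxel
spacing maps them back onto the pixel grid for rasterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Contour",
    "ContourFeatures",
    "ContourPair",
    "ContourModel",
    "detect_isocontours",
    "filter_by_perimeter",
    "contour_features",
    "attach_features",
    "rasterize_interior",
    "enumerate_pairs",
    "label_salient_ground_truth",
    "balance_training_pairs",
    "train_contour_model",
    "cross_validated_scores",
    "classify_salient",
]

N_CONTOUR_FEATURES = 7
N_PAIR_FEATURES = 2 * N_CONTOUR_FEATURES + 1 + N_CONTOUR_FEATURES  # 22


@dataclass
class ContourFeatures:
    """The seven per-contour features, physical units."""

    perimeter_um: float
    mean_gray_on_contour: float
    mean_prob_inside: float
    area_um2: float
    ellipse_overlap: float
    ellipse_width_um: float
    ellipse_height_um: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.perimeter_um,
                self.mean_gray_on_contour,
                self.mean_prob_inside,
                self.area_um2,
                self.ellipse_overlap,
                self.ellipse_width_um,
                self.ellipse_height_um,
            ],
            dtype=float,
        )


@dataclass
class Contour:
    """A closed planar polygon on XY slice ``plane_i``.

    ``vertices_um`` has columns ``(y_um, x_um)`` with the first vertex
    repeated at the end (explicit closure).
    """

    plane_i: int
    index_j: int
    vertices_um: np.ndarray
    iso_level: float
    features: ContourFeatures | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices_um, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError(f"contour needs an (n>=3, 2) vertex array, got {v.shape}")
        if not np.allclose(v[0], v[-1]):
            v = np.vstack([v, v[0]])
        self.vertices_um = v

    @property
    def points_um(self) -> np.ndarray:
        """Circumference points without the duplicated closing vertex."""
        return self.vertices_um[:-1]

    @property
    def center_um(self) -> np.ndarray:
        """(y, x) center: the average of all circumference points."""
        return self.points_um.mean(axis=0)

    @property
    def perimeter_um(self) -> float:
        d = np.diff(self.vertices_um, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def area_um2(self) -> float:
        """Unsigned polygon area by the shoelace formula."""
        y, x = self.vertices_um[:, 0], self.vertices_um[:, 1]
        return float(abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])) / 2.0)

    def vertices_px(self, spacing_yx_nm: tuple[float, float]) -> np.ndarray:
        """Vertices as fractional (row, col) pixel coordinates."""
        sy, sx = spacing_yx_nm
        v = self.vertices_um * 1000.0
        return np.column_stack([v[:, 0] / sy, v[:, 1] / sx])


@dataclass
class ContourPair:
    """Two contours on adjacent planes within the center-distance gate."""

    a: Contour
    b: Contour
    center_distance_um: float
    feature_vector: np.ndarray
    saliency_prob: float | None = None

    def __post_init__(self) -> None:
        if self.b.plane_i != self.a.plane_i + 1:
            raise ValueError("pair members must sit on adjacent planes (a below b)")
        fv = np.asarray(self.feature_vector, dtype=float)
        if fv.shape != (N_PAIR_FEATURES,):
            raise ValueError(f"pair feature vector must have length {N_PAIR_FEATURES}")
        self.feature_vector = fv


@dataclass
class ContourModel:
    """Random forest over 22-long pair vectors (M=2) or 7-long contour vectors (M=1)."""

    classifier: RandomForestClassifier
    set_size_M: int
    n_features: int
    metadata: dict = field(default_factory=dict)

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        proba = self.classifier.predict_proba(X)
        pos = list(self.classifier.classes_).index(1)
        return proba[:, pos]


# ---------------------------------------------------------------------------
# detection and filtering


def detect_isocontours(
    prob_slice: np.ndarray,
    levels: Sequence[float],
    spacing_yx_nm: tuple[float, float],
    plane_i: int = 0,
    ref_value: float | None = None,
) -> list[Contour]:
    """Extract closed isocontours of a probability slice at several levels.

    Each level ``l`` thresholds at ``l * ref_value`` where ``ref_value``
    defaults to the slice maximum (pass the volume-wide maximum to keep
    levels consistent across slices). Marching squares gives subpixel
    vertices; curves that would run off the image are closed along the
    border by padding with a value below every threshold. Contours from all
    levels are pooled without deduplication.
    """
    prob_slice = np.asarray(prob_slice, dtype=float)
    if prob_slice.ndim != 2 or prob_slice.size == 0:
        raise ValueError("probability slice must be a non-empty 2D array")
    levels = np.asarray(levels, dtype=float)
    if np.any(np.diff(levels) <= 0) or np.any(levels <= 0) or np.any(levels >= 1):
        raise ValueError("levels must be strictly increasing fractions in (0, 1)")
    ref = float(prob_slice.max()) if ref_value is None else float(ref_value)
    contours: list[Contour] = []
    if ref <= 0:
        return contours
    padded = np.pad(prob_slice, 1, constant_values=-1.0)
    sy, sx = spacing_yx_nm
    h, w = prob_slice.shape
    j = 0
    for level in levels:
        thr = level * ref
        if thr >= padded.max():
            continue
        for verts in measure.find_contours(padded, thr):
            rc = verts - 1.0
            rc[:, 0] = np.clip(rc[:, 0], 0.0, h - 1.0)
            rc[:, 1] = np.clip(rc[:, 1], 0.0, w - 1.0)
            um = np.column_stack([rc[:, 0] * sy / 1000.0, rc[:, 1] * sx / 1000.0])
            # padding guarantees closure; degenerate slivers are dropped
            if um.shape[0] < 4:
                continue
            contours.append(Contour(plane_i=plane_i, index_j=j, vertices_um=um, iso_level=float(level)))
            j += 1
    return contours


def filter_by_perimeter(
    contours: Sequence[Contour], min_um: float, max_um: float
) -> list[Contour]:
    """Keep contours with ``min_um <= perimeter <= max_um`` (inclusive)."""
    if min_um >= max_um:
        raise ValueError("perimeter gate requires min_um < max_um")
    return [c for c in contours if min_um <= c.perimeter_um <= max_um]


# ---------------------------------------------------------------------------
# rasterization and features


def rasterize_interior(
    contour: Contour,
    shape: tuple[int, int],
    spacing_yx_nm: tuple[float, float],
) -> np.ndarray:
    """Boolean mask of pixel centers inside the polygon, on a slice grid.

    Evaluated on the contour's bounding box only, then embedded into the
    full ``shape`` so repeated calls on small contours stay cheap.
    """
    rc = contour.vertices_px(spacing_yx_nm)
    mask = np.zeros(shape, dtype=bool)
    r0 = max(int(np.floor(rc[:, 0].min())), 0)
    r1 = min(int(np.ceil(rc[:, 0].max())) + 1, shape[0])
    c0 = max(int(np.floor(rc[:, 1].min())), 0)
    c1 = min(int(np.ceil(rc[:, 1].max())) + 1, shape[1])
    if r1 <= r0 or c1 <= c0:
        return mask
    local = measure.grid_points_in_poly((r1 - r0, c1 - c0), rc - [r0, c0])
    mask[r0:r1, c0:c1] = local
    return mask


def _moment_ellipse(points_xy: np.ndarray) -> tuple[float, float, float, float, float]:
    """Moment-based ellipse (xc, yc, a, b, theta) from circumference points."""
    mu = points_xy.mean(axis=0)
    cov = np.cov((points_xy - mu).T)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    evals = np.clip(evals, 1e-12, None)
    # uniform points on an ellipse boundary have variance a^2/2 along the axis
    b, a = np.sqrt(2.0 * evals)
    theta = float(np.arctan2(evecs[1, -1], evecs[0, -1]))
    return float(mu[0]), float(mu[1]), float(a), float(b), theta


def fit_ellipse(points_yx_um: np.ndarray) -> tuple[float, float, float, float, float]:
    """Fit an ellipse to circumference points; returns (xc, yc, a, b, theta) in um.

    Direct least-squares conic fit; degenerate or non-elliptical fits fall
    back to a moment-based ellipse, which always exists for >= 3 points.
    """
    xy = points_yx_um[:, ::-1]  # (x, y)
    try:
        model = measure.EllipseModel.from_estimate(xy)
        ok = bool(model)
    except Exception:
        ok = False
    if ok:
        xc, yc = (float(v) for v in model.center)
        a, b = (float(v) for v in model.axis_lengths)
        theta = float(model.theta)
        span = max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]))
        if (
            np.isfinite([xc, yc, a, b, theta]).all()
            and 0 < a < 50 * span
            and 0 < b < 50 * span
        ):
            if b > a:
                a, b = b, a
                theta += np.pi / 2.0
            return xc, yc, a, b, float(theta)
    return _moment_ellipse(xy)


def _rasterize_ellipse_on_grid(
    params: tuple[float, float, float, float, float],
    rows: np.ndarray,
    cols: np.ndarray,
    spacing_yx_nm: tuple[float, float],
) -> np.ndarray:
    xc, yc, a, b, theta = params
    sy, sx = spacing_yx_nm
    y = rows[:, None] * sy / 1000.0
    x = cols[None, :] * sx / 1000.0
    ct, st = np.cos(theta), np.sin(theta)
    u = (x - xc) * ct + (y - yc) * st
    v = -(x - xc) * st + (y - yc) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def ellipse_overlap(
    contour: Contour,
    params: tuple[float, float, float, float, float],
    spacing_yx_nm: tuple[float, float],
) -> float:
    """Jaccard overlap between the contour interior and the fitted ellipse.

    Both shapes are rasterized at the voxel pitch on a grid covering their
    joint bounding box (independent of slice bounds).
    """
    sy, sx = spacing_yx_nm
    xc, yc, a, b, theta = params
    rc = contour.vertices_px(spacing_yx_nm)
    r_ell = max(a, b) * 1000.0
    r0 = int(np.floor(min(rc[:, 0].min(), (yc * 1000.0 - r_ell) / sy))) - 1
    r1 = int(np.ceil(max(rc[:, 0].max(), (yc * 1000.0 + r_ell) / sy))) + 2
    c0 = int(np.floor(min(rc[:, 1].min(), (xc * 1000.0 - r_ell) / sx))) - 1
    c1 = int(np.ceil(max(rc[:, 1].max(), (xc * 1000.0 + r_ell) / sx))) + 2
    poly = measure.grid_points_in_poly((r1 - r0, c1 - c0), rc - [r0, c0])
    ell = _rasterize_ellipse_on_grid(
        params, np.arange(r0, r1), np.arange(c0, c1), spacing_yx_nm
    )
    union = np.logical_or(poly, ell).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(poly, ell).sum() / union)


def contour_features(
    contour: Contour,
    raw_slice: np.ndarray,
    prob_slice: np.ndarray,
    spacing_yx_nm: tuple[float, float],
) -> ContourFeatures:
    """Compute the seven-feature descriptor of a contour.

    Mean gray samples the raw image bilinearly at the vertex positions;
    mean probability averages the probability map over the rasterized
    interior (falling back to the contour samples when the interior holds
    no pixel center); the ellipse is a direct least-squares fit with
    moment-based fallback, its width/height the full major/minor axes.
    """
    pts = contour.points_um
    if np.unique(np.round(pts, 9), axis=0).shape[0] < 3:
        raise ValueError("degenerate polygon: fewer than 3 distinct vertices")
    rc = contour.vertices_px(spacing_yx_nm)[:-1]
    coords = [rc[:, 0], rc[:, 1]]
    mean_gray = float(
        ndimage.map_coordinates(
            np.asarray(raw_slice, dtype=float), coords, order=1, mode="nearest"
        ).mean()
    )
    interior = rasterize_interior(contour, np.asarray(prob_slice).shape, spacing_yx_nm)
    if interior.any():
        mean_prob = float(np.asarray(prob_slice, dtype=float)[interior].mean())
    else:
        mean_prob = float(
            ndimage.map_coordinates(
                np.asarray(prob_slice, dtype=float), coords, order=1, mode="nearest"
            ).mean()
        )
    params = fit_ellipse(pts)
    overlap = ellipse_overlap(contour, params, spacing_yx_nm)
    _, _, a, b, _ = params
    return ContourFeatures(
        perimeter_um=contour.perimeter_um,
        mean_gray_on_contour=mean_gray,
        mean_prob_inside=mean_prob,
        area_um2=contour.area_um2,
        ellipse_overlap=overlap,
        ellipse_width_um=2.0 * a,
        ellipse_height_um=2.0 * b,
    )


def attach_features(
    contours: Sequence[Contour],
    raw_slice: np.ndarray,
    prob_slice: np.ndarray,
    spacing_yx_nm: tuple[float, float],
) -> list[Contour]:
    """Compute and store features for every contour of one slice (in place)."""
    for c in contours:
        c.features = contour_features(c, raw_slice, prob_slice, spacing_yx_nm)
    return list(contours)


# ---------------------------------------------------------------------------
# pairing and classification


def enumerate_pairs(
    contours_by_plane: Mapping[int, Sequence[Contour]], D_um: float
) -> list[ContourPair]:
    """All adjacent-plane contour pairs whose centers are closer than ``D_um``.

    The gate is strict (``distance < D``). Each pair's 22-long vector is
    ``[features(a), features(b), center_distance, features(a) - features(b)]``
    with ``a`` on the lower plane.
    """
    pairs: list[ContourPair] = []
    for plane in sorted(contours_by_plane):
        lower = contours_by_plane.get(plane, [])
        upper = contours_by_plane.get(plane + 1, [])
        if not lower or not upper:
            continue
        ca = np.array([c.center_um for c in lower])
        cb = np.array([c.center_um for c in upper])
        dists = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
        for ia, ib in zip(*np.nonzero(dists < D_um)):
            a, b = lower[ia], upper[ib]
            if a.features is None or b.features is None:
                raise ValueError("contour features must be computed before pairing")
            fa, fb = a.features.as_array(), b.features.as_array()
            vec = np.concatenate([fa, fb, [dists[ia, ib]], fa - fb])
            pairs.append(
                ContourPair(
                    a=a, b=b, center_distance_um=float(dists[ia, ib]), feature_vector=vec
                )
            )
    return pairs


def label_salient_ground_truth(
    contour: Contour,
    label_slice: np.ndarray,
    fraction: float,
    spacing_yx_nm: tuple[float, float],
) -> int:
    """1 iff at least ``fraction`` of the pixels inside the contour are labeled."""
    label_slice = np.asarray(label_slice)
    interior = rasterize_interior(contour, label_slice.shape, spacing_yx_nm)
    n_inside = int(interior.sum())
    if n_inside == 0:
        raise ValueError("contour rasterizes to an empty interior")
    n_pos = int((label_slice[interior] > 0).sum())
    return int(n_pos / n_inside >= fraction)


def balance_training_pairs(
    X: np.ndarray, y: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate each positive example ``n`` extra times (so it appears 1+n times).

    Negatives are untouched; duplicates follow their original immediately,
    keeping the order deterministic. Used to hold the positive:negative
    ratio near the configured target when positives are scarce.
    """
    if n < 0:
        raise ValueError("duplication count n must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if n == 0 or not (y == 1).any():
        return X.copy(), y.copy()
    reps = np.where(y == 1, 1 + n, 1)
    return np.repeat(X, reps, axis=0), np.repeat(y, reps)


def train_contour_model(
    X: np.ndarray,
    y: np.ndarray,
    M: int,
    rf_trees: int,
    seed: int,
) -> ContourModel:
    """Train the saliency random forest on contour (M=1) or pair (M=2) vectors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    expected = N_CONTOUR_FEATURES if M == 1 else N_PAIR_FEATURES
    if M not in (1, 2):
        raise ValueError("contour set size M must be 1 or 2")
    if X.ndim != 2 or X.shape[1] != expected:
        raise ValueError(f"M={M} requires {expected}-long feature vectors, got {X.shape}")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both salient and non-salient examples")
    clf = RandomForestClassifier(n_estimators=rf_trees, random_state=seed, n_jobs=1)
    clf.fit(X, y)
    return ContourModel(
        classifier=clf,
        set_size_M=M,
        n_features=expected,
        metadata={"n_examples": int(len(y)), "n_pos": int((y == 1).sum()), "seed": seed},
    )


def cross_validated_scores(
    X: np.ndarray,
    y: np.ndarray,
    M: int,
    rf_trees: int,
    seed: int,
    n_splits: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled out-of-fold saliency scores from stratified k-fold CV.

    Returns ``(y_true, scores)`` suitable for an ROC curve; this is the
    companion accuracy report for :func:`train_contour_model`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    y_all, s_all = [], []
    for tr, te in skf.split(X, y):
        model = train_contour_model(X[tr], y[tr], M=M, rf_trees=rf_trees, seed=seed)
        s_all.append(model.predict_prob(X[te]))
        y_all.append(y[te])
    return np.concatenate(y_all), np.concatenate(s_all)


def classify_salient(
    model: ContourModel,
    pairs: Sequence[ContourPair] | Sequence[Contour],
    T: float,
) -> list[Contour]:
    """Contours surviving the saliency threshold ``T``.

    For M=2, every pair is scored and pairs with probability >= T are kept;
    a contour is salient when it participates in at least one kept pair
    (both members of a kept pair are marked). For M=1 a contour is salient
    when its own probability >= T. Pair/contour ``saliency_prob`` is filled
    in as a side effect.
    """
    if not pairs:
        return []
    if model.set_size_M == 2:
        if not isinstance(pairs[0], ContourPair):
            raise ValueError("an M=2 model classifies ContourPair objects")
        X = np.stack([p.feature_vector for p in pairs])
        probs = model.predict_prob(X)
        salient: dict[int, Contour] = {}
        for p, prob in zip(pairs, probs):
            p.saliency_prob = float(prob)
            if prob >= T:
                salient[id(p.a)] = p.a
                salient[id(p.b)] = p.b
        return list(salient.values())
    if not isinstance(pairs[0], Contour):
        raise ValueError("an M=1 model classifies Contour objects")
    X = np.stack([c.features.as_array() for c in pairs])
    probs = model.predict_prob(X)
    return [c for c, prob in zip(pairs, probs) if prob >= T]
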