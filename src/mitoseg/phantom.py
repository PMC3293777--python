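"""Synthetic EM-like phantoms with voxel-exact ground truth.

The generator emulates the statistical structure of serial block-face SEM
neuropil at ~10 nm XY pixels and 50-70 nm Z steps: dark ellipsoidal
organelles (0.3-1.5 um extent) with an internal stripe texture standing in
for cristae, embedded in a brighter background cluttered with dark
membrane-like curves and small vesicle discs, plus additive Gaussian
noise. The confusers are deliberate — they make the patch classifier
produce false positives that the contour-pair stage must remove. Labels
are 1 exactly on voxels inside generated ellipsoids.

It is a statistical stand-in, not a physical simulation: no staining or
detector model, no slice-to-slice registration error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate

from .contours import Contour
from .io import IntensityVolume, LabelVolume

__all__ = ["PhantomParams", "generate_phantom", "generate_toy_polygons"]


@dataclass
class PhantomParams:
    """Geometry, intensity and clutter parameters of the phantom.

    Defaults match the study volume the pipeline is normally trained on:
    350x350 pixels in XY over 30 slices at (50, 10, 10) nm spacing, with
    organelle cross-section perimeters mostly inside the 0.6-6 um working
    band of the contour stage.
    """

    shape: tuple[int, int, int] = (30, 350, 350)
    spacing: tuple[float, float, float] = (50.0, 10.0, 10.0)
    n_organelles: int = 12
    organelle_axes_um: tuple[float, float] = (0.2, 0.5)   # in-plane semi-axes
    organelle_z_axes_um: tuple[float, float] = (0.15, 0.35)
    organelle_gray: float = 105.0
    stripe_amplitude: float = 18.0
    cristae_period_px: float = 7.0
    membrane_curves_per_slice: float = 5.0
    membrane_gray: float = 70.0
    membrane_thickness_px: float = 3.0
    vesicle_count: int = 120
    vesicle_radius_um: tuple[float, float] = (0.03, 0.09)
    vesicle_gray: float = 95.0
    background_gray: float = 140.0
    noise_sigma: float = 30.0
    seed: int = 0


def _add_ellipsoid(
    label: np.ndarray,
    intensity: np.ndarray,
    center: tuple[float, float, float],
    semi_axes_vox: tuple[float, float, float],
    angle: float,
    stripe: tuple[float, float, float] | None,
    gray: float,
    stripe_amp: float,
) -> None:
    """Stamp a rotated (in-plane) ellipsoid; optionally stripe its interior."""
    cz, cy, cx = center
    az, ay, ax = semi_axes_vox
    shape = intensity.shape
    z0 = max(int(np.floor(cz - az)), 0)
    z1 = min(int(np.ceil(cz + az)) + 1, shape[0])
    y0 = max(int(np.floor(cy - max(ay, ax))), 0)
    y1 = min(int(np.ceil(cy + max(ay, ax))) + 1, shape[1])
    x0 = max(int(np.floor(cx - max(ay, ax))), 0)
    x1 = min(int(np.ceil(cx + max(ay, ax))) + 1, shape[2])
    if z1 <= z0 or y1 <= y0 or x1 <= x0:
        return
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    ct, st = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    inside = (u / ax) ** 2 + (v / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0
    if stripe is not None:
        s_angle, period, phase = stripe
        w = (xx * np.cos(s_angle) + yy * np.sin(s_angle)) * 2.0 * np.pi / period
        tex = gray + stripe_amp * np.sign(np.sin(w + phase))
    else:
        tex = np.full(inside.shape, gray)
    sub = intensity[z0:z1, y0:y1, x0:x1]
    sub[inside] = np.broadcast_to(tex, inside.shape)[inside]
    if label is not None and stripe is not None:
        label[z0:z1, y0:y1, x0:x1][inside] = 1


def _draw_membrane(
    intensity: np.ndarray, rng: np.random.Generator, params: PhantomParams
) -> None:
    """One smooth dark curve drifting slowly across slices (a membrane sheet)."""
    nz, ny, nx = intensity.shape
    k = 5
    ctrl_y = rng.uniform(0, ny, size=k)
    ctrl_x = np.linspace(0, nx - 1, k) + rng.uniform(-20, 20, size=k)
    drift = rng.uniform(-1.5, 1.5, size=2)  # voxels per slice in (y, x)
    t = np.linspace(0, 1, k)
    tt = np.linspace(0, 1, 4 * max(ny, nx))
    base_y = interpolate.CubicSpline(t, ctrl_y)(tt)
    base_x = interpolate.CubicSpline(t, ctrl_x)(tt)
    half = max(int(round(params.membrane_thickness_px / 2)), 0)
    offs = range(-half, half + 1)
    for z in range(nz):
        ys = base_y + drift[0] * z
        xs = base_x + drift[1] * z
        for dy in offs:
            for dx in offs:
                r = np.round(ys + dy).astype(int)
                c = np.round(xs + dx).astype(int)
                ok = (r >= 0) & (r < ny) & (c >= 0) & (c < nx)
                intensity[z, r[ok], c[ok]] = params.membrane_gray


def generate_phantom(params: PhantomParams) -> tuple[IntensityVolume, LabelVolume]:
    """Generate one phantom volume and its ground-truth label volume.

    Deterministic for a given ``params.seed``; all randomness flows through
    a single generator created here.
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape
    sz, sy, sx = params.spacing
    intensity = np.full(params.shape, params.background_gray, dtype=float)
    label = np.zeros(params.shape, dtype=np.uint8)

    if params.n_organelles > 0:
        ax_max_vox = params.organelle_axes_um[1] * 1000.0 / min(sy, sx)
        az_max_vox = params.organelle_z_axes_um[1] * 1000.0 / sz
        if 2 * ax_max_vox > min(ny, nx) or 2 * az_max_vox > nz:
            raise ValueError(
                "infeasible geometry: largest organelle does not fit inside the volume"
            )

    # background clutter first so organelle texture overwrites overlaps
    n_membranes = rng.poisson(params.membrane_curves_per_slice)
    for _ in range(max(n_membranes, 1) if params.membrane_curves_per_slice > 0 else 0):
        _draw_membrane(intensity, rng, params)
    for _ in range(params.vesicle_count):
        r_um = rng.uniform(*params.vesicle_radius_um)
        center = (
            rng.uniform(0, nz - 1),
            rng.uniform(0, ny - 1),
            rng.uniform(0, nx - 1),
        )
        axes = (r_um * 1000.0 / sz, r_um * 1000.0 / sy, r_um * 1000.0 / sx)
        _add_ellipsoid(None, intensity, center, axes, 0.0, None, params.vesicle_gray, 0.0)

    for _ in range(params.n_organelles):
        a_um = rng.uniform(*params.organelle_axes_um)
        b_um = rng.uniform(params.organelle_axes_um[0], a_um)
        c_um = rng.uniform(*params.organelle_z_axes_um)
        ax_vox = a_um * 1000.0 / sx
        ay_vox = b_um * 1000.0 / sy
        az_vox = c_um * 1000.0 / sz
        margin_xy = 1.05 * max(ax_vox, ay_vox)
        margin_z = max(az_vox * 0.5, 1.0)
        center = (
            rng.uniform(margin_z, nz - 1 - margin_z) if nz > 2 * margin_z else (nz - 1) / 2,
            rng.uniform(margin_xy, ny - 1 - margin_xy),
            rng.uniform(margin_xy, nx - 1 - margin_xy),
        )
        stripe = (
            rng.uniform(0, np.pi),
            params.cristae_period_px,
            rng.uniform(0, 2 * np.pi),
        )
        _add_ellipsoid(
            label,
            intensity,
            center,
            (az_vox, ay_vox, ax_vox),
            rng.uniform(0, np.pi),
            stripe,
            params.organelle_gray,
            params.stripe_amplitude,
        )

    intensity += rng.normal(0.0, params.noise_sigma, size=params.shape)
    intensity = np.clip(np.round(intensity), 0, 255).astype(np.uint8)
    return (
        IntensityVolume(intensity, params.spacing),
        LabelVolume(label, params.spacing),
    )


def generate_toy_polygons(
    kind: str,
    size_um: float,
    plane: int = 0,
    center_um: tuple[float, float] = (1.0, 1.0),
    n_vertices: int = 360,
) -> Contour:
    """Closed, simple polygons with analytically known perimeter and area.

    ``kind`` is one of ``circle`` (radius ``size_um``), ``ellipse``
    (semi-axes ``size_um`` x ``size_um/2``), ``square`` (side ``size_um``)
    or ``irregular`` (an eight-pointed star). These serve as exact fixtures
    for the contour feature computations.
    """
    if size_um <= 0:
        raise ValueError("size_um must be positive")
    cy, cx = center_um
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    if kind == "circle":
        y = cy + size_um * np.sin(th)
        x = cx + size_um * np.cos(th)
    elif kind == "ellipse":
        y = cy + 0.5 * size_um * np.sin(th)
        x = cx + size_um * np.cos(th)
    elif kind == "square":
        s = size_um / 2.0
        t = np.linspace(0.0, 4.0, n_vertices, endpoint=False)
        y = np.empty_like(t)
        x = np.empty_like(t)
        for i, ti in enumerate(t):
            edge, f = int(ti), ti - int(ti)
            if edge == 0:
                y[i], x[i] = cy - s, cx - s + size_um * f
            elif edge == 1:
                y[i], x[i] = cy - s + size_um * f, cx + s
            elif edge == 2:
                y[i], x[i] = cy + s, cx + s - size_um * f
            else:
                y[i], x[i] = cy + s - size_um * f, cx - s
    elif kind == "irregular":
        radii = np.where(np.arange(n_vertices) % 2 == 0, size_um, 0.45 * size_um)
        y = cy + radii * np.sin(th)
        x = cx + radii * np.cos(th)
    else:
        raise ValueError(f"unknown polygon kind {kind!r}")
    verts = np.column_stack([y, x])
    return Contour(plane_i=plane, index_j=0, vertices_um=verts, iso_level=0.5)
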