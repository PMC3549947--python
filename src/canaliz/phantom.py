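"""Synthetic tooth phantoms with known root-canal geometry.

Generates the two modalities the pipelines consume:

* micro-CT: ordered stacks of 2D cross-sections (dentin disk, enamel rim,
  dark canal cross-sections, granular noise, ring artifact, optional
  burned-in text glyphs), and
* CBCT: low-resolution HU-scaled volumes where the canal is only a few
  voxels wide, with partial-volume blur emulated by supersampled
  rasterization followed by block averaging.

Both renderers return the volume together with the ground truth (canal and
tooth masks, the true centerline graph, per-slice canal cross-section
centers), so every downstream stage can be validated without clinical data.

Coordinates are voxel-center, 0-based ``(x, y, z)`` with ``z`` the stacking
axis; in-memory grids are indexed ``[z, row(y), col(x)]``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .skeleton import SkeletonGraph, assemble_graph, resample_polyline, symmetric_distance

__all__ = [
    "Branch",
    "CanalSpec",
    "IntensityModel",
    "PhantomVolume",
    "GroundTruth",
    "build_centerline",
    "render_microct_stack",
    "render_cbct_volume",
    "score_skeleton",
    "preset",
    "PRESET_NAMES",
]

# HU anchors for the CBCT modality; only the ordering matters downstream.
HU_AIR = -1000.0
HU_CANAL = 0.0
HU_DENTIN = 1500.0
HU_CEMENTUM = 1800.0
HU_ENAMEL = 2500.0

CENTERLINE_SPACING = 0.25  # voxel units, arc-length resampling step


@dataclass
class Branch:
    """One canal branch: an interpolated curve with a radius profile.

    ``parent`` is the index of the branch this one attaches to (its first
    control point must lie on the parent curve); ``None`` for root branches.
    """

    control_points: np.ndarray  # (n, 3) voxel coordinates (x, y, z)
    radii: np.ndarray  # (n,) per-control-point radius in voxels
    parent: int | None = None

    def __post_init__(self):
        self.control_points = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.radii.size == 1:
            self.radii = np.full(len(self.control_points), float(self.radii[0]))


@dataclass
class CanalSpec:
    """Parametric canal geometry: branches plus apex taper."""

    branches: list  # list[Branch]
    apex_taper: float = 1.0  # multiplies the last control radius of leaf branches

    def validate(self) -> None:
        if not self.branches:
            raise ValueError("CanalSpec needs at least one branch")
        for k, br in enumerate(self.branches):
            if len(br.control_points) < 2:
                raise ValueError(f"branch {k}: needs >= 2 control points")
            if len(br.radii) != len(br.control_points):
                raise ValueError(f"branch {k}: radii length mismatch")
            if np.any(br.radii <= 0):
                raise ValueError(f"branch {k}: radii must be positive")
            _check_simple_polygon(br.control_points, k)
        for k, br in enumerate(self.branches):
            if br.parent is None:
                continue
            if not 0 <= br.parent < len(self.branches) or br.parent == k:
                raise ValueError(f"branch {k}: invalid parent index {br.parent}")
            parent_curve = _interpolate_curve(self.branches[br.parent].control_points)
            d = np.min(np.linalg.norm(parent_curve - br.control_points[0], axis=1))
            if d > 1.0:
                raise ValueError(
                    f"branch {k}: start point is {d:.2f} voxels away from parent curve"
                )

    def leaf_indices(self) -> list:
        parents = {br.parent for br in self.branches if br.parent is not None}
        return [k for k in range(len(self.branches)) if k not in parents]


@dataclass
class IntensityModel:
    """Tissue intensity means, noise and artifact amplitudes for a modality."""

    dentin: float
    enamel: float
    canal: float
    cementum: float
    background: float
    noise_sd: float = 0.0
    ring_amplitude: float = 0.0
    ring_period: float = 6.0
    text_glyphs: bool = False
    glyph_value: float = 240.0

    @classmethod
    def microct_default(cls, noise_sd: float = 5.0, ring_amplitude: float = 3.0,
                        text_glyphs: bool = False) -> "IntensityModel":
        return cls(dentin=160.0, enamel=205.0, canal=25.0, cementum=178.0,
                   background=12.0, noise_sd=noise_sd, ring_amplitude=ring_amplitude,
                   text_glyphs=text_glyphs)

    @classmethod
    def cbct_default(cls, noise_sd: float = 60.0) -> "IntensityModel":
        return cls(dentin=HU_DENTIN, enamel=HU_ENAMEL, canal=HU_CANAL,
                   cementum=HU_CEMENTUM, background=HU_AIR, noise_sd=noise_sd)


@dataclass
class PhantomVolume:
    voxels: np.ndarray  # (nz, ny, nx) float intensities
    spacing_mm: tuple
    modality: str  # "microct" | "cbct"
    intensity_model: IntensityModel

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class GroundTruth:
    canal_mask: np.ndarray  # (nz, ny, nx) bool
    tooth_mask: np.ndarray  # (nz, ny, nx) bool
    centerline: SkeletonGraph
    per_slice_spots: list  # for each z: list of (row, col) true spot centers


# ---------------------------------------------------------------------------
# centerline construction
# ---------------------------------------------------------------------------

def _check_simple_polygon(points: np.ndarray, branch_idx: int) -> None:
    """Reject self-intersecting control polygons (non-adjacent segments meet)."""
    n = len(points)
    if np.any(np.linalg.norm(np.diff(points, axis=0), axis=1) < 1e-9):
        raise ValueError(f"branch {branch_idx}: repeated consecutive control points")
    for i in range(n - 1):
        for j in range(i + 2, n - 1):
            if _segment_distance(points[i], points[i + 1], points[j], points[j + 1]) < 1e-9:
                raise ValueError(
                    f"branch {branch_idx}: control polygon self-intersects "
                    f"(segments {i} and {j})"
                )


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between two 3D segments."""
    u, v, w = p2 - p1, q2 - q1, p1 - q1
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # refine s for the clamped t
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return float(np.linalg.norm(p1 + s * u - (q1 + t * v)))


def _interpolate_curve(control_points: np.ndarray, spacing: float = CENTERLINE_SPACING):
    """Natural cubic interpolation through control points, arc-length resampled."""
    cp = np.asarray(control_points, dtype=float)
    if len(cp) == 2:
        dense = cp
    else:
        chord = np.linalg.norm(np.diff(cp, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(chord)])
        spline = CubicSpline(t, cp, bc_type="natural")
        dense = spline(np.linspace(0.0, t[-1], max(8 * len(cp), 64)))
    return resample_polyline(dense, spacing)


def _branch_samples(spec: CanalSpec, idx: int, spacing: float = CENTERLINE_SPACING):
    """Resampled curve points and per-point radii for one branch."""
    br = spec.branches[idx]
    pts = _interpolate_curve(br.control_points, spacing)
    radii = np.asarray(br.radii, dtype=float).copy()
    if idx in spec.leaf_indices():
        radii[-1] *= spec.apex_taper
    # radius interpolated over arc length between control points
    cp = br.control_points
    chord = np.linalg.norm(np.diff(cp, axis=0), axis=1)
    t_ctrl = np.concatenate([[0.0], np.cumsum(chord)])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t_pts = np.concatenate([[0.0], np.cumsum(seg)])
    t_pts = t_pts * (t_ctrl[-1] / t_pts[-1] if t_pts[-1] > 0 else 1.0)
    r = np.interp(t_pts, t_ctrl, radii)
    return pts, r


def build_centerline(spec: CanalSpec, spacing: float = CENTERLINE_SPACING) -> SkeletonGraph:
    """True medial curve(s) of the canal spec as a skeleton graph."""
    spec.validate()
    polylines = [_branch_samples(spec, k, spacing)[0] for k in range(len(spec.branches))]
    return assemble_graph(polylines, join_tol=0.75)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _rasterize_tube(shape, points, radii) -> np.ndarray:
    """Union-of-balls rasterization of a tube along sampled centerline points."""
    nz, ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    for (x, y, z), r in zip(points, radii):
        z0, z1 = max(0, int(np.floor(z - r))), min(nz - 1, int(np.ceil(z + r)))
        y0, y1 = max(0, int(np.floor(y - r))), min(ny - 1, int(np.ceil(y + r)))
        x0, x1 = max(0, int(np.floor(x - r))), min(nx - 1, int(np.ceil(x + r)))
        if z0 > z1 or y0 > y1 or x0 > x1:
            continue
        zz, yy, xx = np.ogrid[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1]
        ball = (zz - z) ** 2 + (yy - y) ** 2 + (xx - x) ** 2 <= r * r
        mask[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1] |= ball
    return mask


def _canal_mask(spec: CanalSpec, shape, scale: float = 1.0) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for k in range(len(spec.branches)):
        pts, r = _branch_samples(spec, k, spacing=CENTERLINE_SPACING * max(1.0, scale))
        if scale != 1.0:
            pts = pts * scale + (scale - 1.0) / 2.0
            r = r * scale
        mask |= _rasterize_tube(shape, pts, r)
    return mask


def _tooth_masks(shape, dentin_radius: float, enamel_thickness: float,
                 taper: float, center=None):
    """Per-slice dentin disk with enamel rim; radius tapers toward the apex."""
    nz, ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    if center is not None:
        cx, cy = center
    yy, xx = np.mgrid[0:ny, 0:nx]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    tooth = np.zeros(shape, dtype=bool)
    enamel = np.zeros(shape, dtype=bool)
    radii = dentin_radius * (1.0 - (1.0 - taper) * np.arange(nz) / max(1, nz - 1))
    for z in range(nz):
        disk = dist <= radii[z]
        tooth[z] = disk
        enamel[z] = disk & (dist > radii[z] - enamel_thickness)
    return tooth, enamel, dist, radii


def _per_slice_spots(canal_mask: np.ndarray) -> list:
    structure = np.ones((3, 3), dtype=bool)
    spots = []
    for z in range(canal_mask.shape[0]):
        lab, n = ndimage.label(canal_mask[z], structure=structure)
        centers = ndimage.center_of_mass(canal_mask[z], lab, range(1, n + 1))
        spots.append([(float(r), float(c)) for r, c in centers])
    return spots


def _burn_glyphs(img_stack: np.ndarray, value: float) -> None:
    """Burned-in text-like glyph blocks near the top-left corner of each slice."""
    glyphs = [(3, 3, 8, 6), (3, 9, 8, 12), (3, 15, 8, 18)]  # (r0, c0, r1, c1)
    for r0, c0, r1, c1 in glyphs:
        img_stack[:, r0:r1, c0:c1] = value
        # hollow the middle column to make strokes thin like text
        img_stack[:, r0 + 1:r1 - 1, c0 + 1:c1 - 1] = value


def render_microct_stack(spec: CanalSpec, shape=(200, 64, 64),
                         model: IntensityModel | None = None, seed: int = 0,
                         dentin_radius: float | None = None,
                         enamel_thickness: float = 2.0,
                         tooth_taper: float = 0.65):
    """Render a micro-CT slice stack for a canal spec, with ground truth.

    Identical ``(spec, model, seed)`` triples produce bit-identical stacks.
    """
    spec.validate()
    if model is None:
        model = IntensityModel.microct_default()
    nz, ny, nx = shape
    if dentin_radius is None:
        dentin_radius = 0.42 * min(nx, ny)
    max_canal_r = max(float(np.max(br.radii)) for br in spec.branches)
    if max_canal_r >= dentin_radius:
        raise ValueError(
            f"canal radius {max_canal_r} must be smaller than dentin radius {dentin_radius}"
        )

    canal = _canal_mask(spec, shape)
    tooth, enamel, dist, radii = _tooth_masks(shape, dentin_radius, enamel_thickness,
                                              tooth_taper)
    interior = tooth & ~enamel
    if np.any(canal & ~interior):
        raise ValueError("canal geometry extends outside the dentin interior")

    img = np.full(shape, model.background, dtype=float)
    img[interior] = model.dentin
    img[enamel] = model.enamel
    # thin cementum ring just inside the enamel, slightly lighter than dentin
    cem = np.zeros(shape, dtype=bool)
    for z in range(nz):
        cem[z] = (dist <= radii[z] - enamel_thickness) & \
                 (dist > radii[z] - enamel_thickness - 1.0)
    img[cem] = model.cementum
    img[canal] = model.canal

    if model.ring_amplitude > 0:
        light = tooth & ~canal
        ring = model.ring_amplitude * np.sin(
            2.0 * np.pi * dist / model.ring_period
            + 0.7 * np.arange(nz)[:, None, None]
        )
        img += np.where(light, ring, 0.0)

    rng = np.random.default_rng(seed)
    if model.noise_sd > 0:
        img += rng.normal(0.0, model.noise_sd, shape)
    if model.text_glyphs:
        _burn_glyphs(img, model.glyph_value)
    np.clip(img, 0.0, 255.0, out=img)

    volume = PhantomVolume(voxels=img, spacing_mm=(0.016, 0.016, 0.016),
                           modality="microct", intensity_model=model)
    truth = GroundTruth(canal_mask=canal, tooth_mask=tooth,
                        centerline=build_centerline(spec),
                        per_slice_spots=_per_slice_spots(canal))
    return volume, truth


def render_cbct_volume(spec: CanalSpec, shape=(64, 48, 48),
                       model: IntensityModel | None = None, seed: int = 0,
                       spacing_mm: float = 0.2, supersample: int = 4,
                       dentin_radius: float | None = None,
                       enamel_thickness: float = 1.5,
                       tooth_taper: float = 0.7):
    """Render a CBCT volume (HU scale) with partial-volume blur.

    The spec's geometry is given in output voxel units; it is rasterized at
    ``supersample`` times the resolution and block-averaged down, so voxels
    straddling a tissue boundary take intermediate HU values.
    """
    spec.validate()
    if model is None:
        model = IntensityModel.cbct_default()
    if not 0.1 <= spacing_mm <= 0.3:
        warnings.warn(
            f"CBCT voxel spacing {spacing_mm} mm outside the typical 0.1-0.3 mm range",
            stacklevel=2,
        )
    nz, ny, nx = shape
    ss = int(supersample)
    if dentin_radius is None:
        dentin_radius = 0.40 * min(nx, ny)
    max_canal_r = max(float(np.max(br.radii)) for br in spec.branches)
    if max_canal_r >= dentin_radius:
        raise ValueError(
            f"canal radius {max_canal_r} must be smaller than dentin radius {dentin_radius}"
        )

    hi_shape = (nz * ss, ny * ss, nx * ss)
    canal_hi = _canal_mask(spec, hi_shape, scale=float(ss))
    tooth_hi, enamel_hi, _, _ = _tooth_masks(
        hi_shape, dentin_radius * ss, enamel_thickness * ss, tooth_taper)
    interior_hi = tooth_hi & ~enamel_hi
    if np.any(canal_hi & ~interior_hi):
        raise ValueError("canal geometry extends outside the dentin interior")

    hu_hi = np.full(hi_shape, model.background, dtype=float)
    hu_hi[interior_hi] = model.dentin
    hu_hi[enamel_hi] = model.enamel
    hu_hi[canal_hi] = model.canal

    def down(a):
        return a.reshape(nz, ss, ny, ss, nx, ss).mean(axis=(1, 3, 5))

    hu = down(hu_hi)
    rng = np.random.default_rng(seed)
    if model.noise_sd > 0:
        hu += rng.normal(0.0, model.noise_sd, shape)

    canal_mask = down(canal_hi.astype(float)) >= 0.5
    tooth_mask = down(tooth_hi.astype(float)) >= 0.5

    volume = PhantomVolume(voxels=hu, spacing_mm=(spacing_mm,) * 3,
                           modality="cbct", intensity_model=model)
    truth = GroundTruth(canal_mask=canal_mask, tooth_mask=tooth_mask,
                        centerline=build_centerline(spec),
                        per_slice_spots=_per_slice_spots(canal_mask))
    return volume, truth


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_skeleton(extracted: SkeletonGraph, truth: SkeletonGraph,
                   spacing: float = 0.25) -> dict:
    """Score an extracted skeleton against the ground-truth centerline.

    Distances are symmetric (mean of point-to-nearest-curve distances in
    both directions), in voxel units.  ``topology_match`` is true iff both
    endpoint and junction counts agree with the truth.
    """
    if extracted is None or extracted.is_empty:
        raise ValueError("extracted skeleton is empty")
    if truth is None or truth.is_empty:
        raise ValueError("truth skeleton is empty")
    mean_d, max_d = symmetric_distance(extracted, truth, spacing)
    topo = (extracted.n_endpoints == truth.n_endpoints
            and extracted.n_junctions == truth.n_junctions)
    return {
        "mean_dist": mean_d,
        "max_dist": max_d,
        "n_endpoints": extracted.n_endpoints,
        "n_junctions": extracted.n_junctions,
        "topology_match": bool(topo),
    }


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("straight", "curved", "y-bifurcation", "molar3")


def preset(name: str, shape=(200, 64, 64), canal_radius: float = 4.0,
           rng: np.random.Generator | None = None, jitter: float = 0.0,
           span: str | None = None) -> CanalSpec:
    """Canal specs emulating common root-canal shapes.

    ``jitter`` adds deterministic random in-plane displacement (voxels) to
    interior control points, for randomized phantom batteries.  ``span``
    selects "full" (the canal runs through the whole recorded stack, as a
    micro-CT record cut at both ends) or "interior" (the canal ends inside
    the volume, as a whole tooth in a CBCT field of view); single-canal
    presets default to "full", branched ones to "interior".
    """
    nz, ny, nx = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    if span is None:
        span = "full" if name in ("straight", "curved") else "interior"
    if name in ("y-bifurcation", "molar3"):
        span = "interior"  # apices must be real canal endings
    r = float(canal_radius)
    if span == "full":
        z0, z1 = 0.0, nz - 1.0
    else:
        # leave room for the rounded canal endings (the chamber of molar3
        # is 1.5x the nominal radius), so the canal never leaves the volume
        z0, z1 = np.ceil(2.0 + 1.6 * r), nz - 1.0 - np.ceil(2.0 + r)

    def J(*pts):
        pts = np.asarray(pts, dtype=float)
        if jitter > 0 and rng is not None and len(pts) > 2:
            pts[1:-1, :2] += rng.normal(0.0, jitter, size=(len(pts) - 2, 2))
        return pts

    if name == "straight":
        branches = [Branch(J((cx, cy, z0), (cx, cy, (z0 + z1) / 2), (cx, cy, z1)),
                           [r, r, r])]
    elif name == "curved":
        b = 0.10 * nx
        branches = [Branch(J((cx - b / 2, cy, z0), (cx + b, cy, (z0 + z1) / 2),
                             (cx - b, cy, z1)), [r, 0.9 * r, 0.8 * r])]
    elif name == "y-bifurcation":
        zb = z0 + 0.45 * (z1 - z0)
        dx = 0.14 * nx
        rc = 0.8 * r
        branches = [
            Branch(J((cx, cy, z0), (cx, cy, (z0 + zb) / 2), (cx, cy, zb)), [r, r, r]),
            Branch(J((cx, cy, zb), (cx + 0.6 * dx, cy, (zb + z1) / 2), (cx + dx, cy, z1)),
                   [rc, rc, rc], parent=0),
            Branch(J((cx, cy, zb), (cx - 0.6 * dx, cy, (zb + z1) / 2), (cx - dx, cy, z1)),
                   [rc, rc, rc], parent=0),
        ]
    elif name == "molar3":
        zb1 = z0 + 0.35 * (z1 - z0)
        zb2 = z0 + 0.60 * (z1 - z0)
        dx, dy = 0.14 * nx, 0.12 * ny
        rc = 0.75 * r
        branches = [
            # pulp chamber: wider than the root branches
            Branch(J((cx, cy, z0), (cx, cy, (z0 + zb1) / 2), (cx, cy, zb1)),
                   [1.5 * r, 1.4 * r, 1.2 * r]),
            Branch(J((cx, cy, zb1), (cx + 0.6 * dx, cy + 0.3 * dy, (zb1 + z1) / 2),
                     (cx + dx, cy + 0.5 * dy, z1)), [rc, rc, rc], parent=0),
            # stem that bifurcates again deeper
            Branch(J((cx, cy, zb1), (cx - 0.4 * dx, cy, (zb1 + zb2) / 2),
                     (cx - 0.5 * dx, cy, zb2)), [r, 0.95 * r, 0.9 * r], parent=0),
            Branch(J((cx - 0.5 * dx, cy, zb2), (cx - 0.8 * dx, cy + 0.5 * dy, (zb2 + z1) / 2),
                     (cx - dx, cy + dy, z1)), [rc, rc, rc], parent=2),
            Branch(J((cx - 0.5 * dx, cy, zb2), (cx - 0.6 * dx, cy - 0.6 * dy, (zb2 + z1) / 2),
                     (cx - 0.7 * dx, cy - dy, z1)), [rc, rc, rc], parent=2),
        ]
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return CanalSpec(branches=branches)
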