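"""CBCT volume processing: context-sensitive denoising and fuzzy-chain
regional segmentation of tooth and root canal.

Two voxels are similar when they are close both spatially and in observed
intensity.  The fuzzy relation

    mu_Psi(x_i, x_j) = delta(x_i, x_j) * sigma(x_i, x_j)

with the spatial term ``delta = 1 / (1 + kappa_delta * d(x_i, x_j))`` and
the intensity term ``sigma = 1 / (1 + kappa_sigma * |log(v(x_i)/v(x_j))|)``
links voxel pairs; two voxels belong to the same segment whenever they are
alpha-chained — connected by a sequence of neighbor voxels whose every
consecutive pair has ``mu_Psi >= alpha``.  Unlike classical region growing
with a variance criterion, chains can step across isolated noisy voxels
while the intensity term still blocks chains across tissue boundaries.

The same ``delta * sigma`` weights drive the context-sensitive averaging
prefilter, which suppresses high-frequency noise without degrading edges
(cross-edge weights vanish because of the log-intensity ratio).

Raw Hounsfield units can be non-positive (air is about -1000 HU), which
the log-ratio term cannot accept; intensities are affinely shifted so the
volume minimum maps to 1 before any ``sigma`` evaluation.  Region means in
the region table stay on the raw HU scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "FuzzyChainParams",
    "RegionLabeling",
    "shift_positive",
    "mu_psi",
    "context_filter",
    "alpha_chain_segment",
    "pick_tooth_and_canal",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class FuzzyChainParams:
    """Trade-off parameters of the fuzzy chain relation.

    ``kappa_delta`` weighs physical distance (high values forbid long
    spatial hops, recovering conventional region growing; low values let
    the relation join similar regions that are not physically connected —
    only relevant with the long-range neighborhood enabled).
    ``kappa_sigma`` weighs the log-intensity ratio (high values yield
    piecewise-constant regions).  ``alpha`` is the chain cut level.
    """

    kappa_delta: float = 0.25
    kappa_sigma: float = 8.0
    alpha: float = 0.5
    long_range_radius: float | None = None  # enable non-neighbor hops up to this radius

    def __post_init__(self):
        if self.kappa_delta < 0 or self.kappa_sigma < 0:
            raise ValueError("kappa parameters must be >= 0")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class RegionLabeling:
    """Partition of the voxel set into alpha-chain equivalence classes."""

    labels: np.ndarray  # 3D int array, 0..n_regions-1
    sizes: np.ndarray  # (n_regions,) voxel counts
    mean_intensity: np.ndarray  # (n_regions,) mean raw HU per region
    params: FuzzyChainParams
    tooth_label: int | None = None
    canal_labels: list = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return len(self.sizes)

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def region_table(self):
        """Rows of (label, size, mean HU), largest regions first."""
        order = np.argsort(-self.sizes)
        return [(int(k), int(self.sizes[k]), float(self.mean_intensity[k]))
                for k in order]


def shift_positive(volume: np.ndarray) -> np.ndarray:
    """Affine shift mapping the volume minimum to 1 (makes the log total)."""
    v = np.asarray(volume, dtype=float)
    return v - v.min() + 1.0


def mu_psi(pos_i, val_i, pos_j, val_j, params: FuzzyChainParams) -> float:
    """Fuzzy similarity of two voxels (positions in voxel units, shifted
    positive intensities)."""
    val_i, val_j = float(val_i), float(val_j)
    if val_i <= 0 or val_j <= 0:
        raise ValueError("intensities must be shifted positive before mu_psi")
    d = float(np.linalg.norm(np.asarray(pos_i, float) - np.asarray(pos_j, float)))
    delta = 1.0 / (1.0 + params.kappa_delta * d)
    sigma = 1.0 / (1.0 + params.kappa_sigma * abs(np.log(val_i / val_j)))
    return delta * sigma


def context_filter(volume: np.ndarray, spatial_kappa: float = 0.5,
                   intensity_kappa: float = 10.0, window_radius: int = 1) -> np.ndarray:
    """Context-sensitive averaging: each voxel becomes the weighted mean of
    its window, weighted by the same delta*sigma similarity as the chain
    relation, so averaging happens along homogeneous tissue only."""
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    vol = np.asarray(volume, dtype=float)
    pos = shift_positive(vol)
    logv = np.log(pos)
    acc = vol.copy()  # center voxel: delta=sigma=1
    wacc = np.ones_like(vol)
    r = window_radius
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                dist = np.sqrt(dz * dz + dy * dy + dx * dx)
                delta = 1.0 / (1.0 + spatial_kappa * dist)
                sv = _shift(vol, dz, dy, dx)
                slog = _shift(logv, dz, dy, dx)
                sigma = 1.0 / (1.0 + intensity_kappa * np.abs(logv - slog))
                w = delta * sigma
                valid = ~np.isnan(sv)
                acc[valid] += (w * np.where(valid, sv, 0.0))[valid]
                wacc[valid] += w[valid]
    return acc / wacc


def _shift(a: np.ndarray, dz: int, dy: int, dx: int) -> np.ndarray:
    """Shifted copy of ``a``; out-of-volume entries are NaN."""
    out = np.full_like(a, np.nan)
    src = [slice(max(0, -d), a.shape[k] - max(0, d)) for k, d in enumerate((dz, dy, dx))]
    dst = [slice(max(0, d), a.shape[k] - max(0, -d)) for k, d in enumerate((dz, dy, dx))]
    out[tuple(dst)] = a[tuple(src)]
    return out


def _neighbor_offsets(params: FuzzyChainParams):
    if params.long_range_radius is None:
        return [(0, 0, 1), (0, 1, 0), (1, 0, 0)]
    r = int(np.floor(params.long_range_radius))
    offs = []
    for dz in range(0, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if (dz, dy, dx) <= (0, 0, 0):
                    continue
                if dz * dz + dy * dy + dx * dx <= params.long_range_radius ** 2:
                    offs.append((dz, dy, dx))
    return offs


def alpha_chain_segment(volume: np.ndarray,
                        params: FuzzyChainParams | None = None) -> RegionLabeling:
    """Partition a volume into alpha-chain equivalence classes.

    Chains step between face neighbors by default (every chain edge has
    unit length, so the spatial term is a constant per edge); setting
    ``params.long_range_radius`` admits hops up to that Euclidean radius,
    with the spatial term decaying accordingly.  Segmentation is the
    connected-components computation on the graph whose edges are the
    voxel pairs with ``mu_Psi >= alpha``.
    """
    if params is None:
        params = FuzzyChainParams()
    vol = np.asarray(volume, dtype=float)
    pos = shift_positive(vol)
    logv = np.log(pos)
    n = vol.size
    flat_index = np.arange(n).reshape(vol.shape)
    rows, cols = [], []
    for off in _neighbor_offsets(params):
        dist = float(np.linalg.norm(off))
        delta = 1.0 / (1.0 + params.kappa_delta * dist)
        if delta < params.alpha:
            continue  # even identical intensities cannot link at this span
        src = [slice(max(0, -off[k]), vol.shape[k] - max(0, off[k]))
               for k in range(3)]
        dst = [slice(max(0, off[k]), vol.shape[k] - max(0, -off[k]))
               for k in range(3)]
        dlog = np.abs(logv[tuple(src)] - logv[tuple(dst)])
        sigma = 1.0 / (1.0 + params.kappa_sigma * dlog)
        link = (delta * sigma) >= params.alpha
        rows.append(flat_index[tuple(src)][link].ravel())
        cols.append(flat_index[tuple(dst)][link].ravel())
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    else:
        rows = np.empty(0, dtype=int)
        cols = np.empty(0, dtype=int)
    graph = coo_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n))
    _, flat_labels = connected_components(graph, directed=False)
    labels = flat_labels.reshape(vol.shape)
    sizes = np.bincount(flat_labels)
    sums = np.bincount(flat_labels, weights=vol.ravel())
    return RegionLabeling(labels=labels, sizes=sizes,
                          mean_intensity=sums / sizes, params=params)


# ---------------------------------------------------------------------------
# tooth / canal selection
# ---------------------------------------------------------------------------

def _region_adjacency(labels: np.ndarray):
    """Set of face-adjacent region label pairs."""
    pairs = set()
    for axis in range(3):
        a = np.take(labels, range(labels.shape[axis] - 1), axis=axis)
        b = np.take(labels, range(1, labels.shape[axis]), axis=axis)
        diff = a != b
        pairs.update(zip(a[diff].ravel().tolist(), b[diff].ravel().tolist()))
    out = set()
    for p, q in pairs:
        out.add((min(p, q), max(p, q)))
    return out


def pick_tooth_and_canal(volume: np.ndarray, labeling: RegionLabeling,
                         seed_point, tooth_min_hu: float = 800.0,
                         canal_recovery_hu: float = 500.0,
                         min_canal_voxels: int = 4,
                         merge_regions: bool = False,
                         merge_tol: float = 0.15, merge_dist: int = 2):
    """Select the seeded tooth and the canal region(s) enclosed by it.

    The tooth starts from the region containing the seed (an error if that
    region is not radiodense enough to be hard tissue) and absorbs every
    face-adjacent region whose mean radiodensity is at least
    ``tooth_min_hu`` (dentin, enamel, cementum and dense partial-volume
    shells).  Canal candidates are the remaining sub-threshold regions
    enclosed by the tooth: iteratively, a candidate survives while all its
    outside face-neighbors belong to the tooth or to other candidates.
    Voxels inside the picked tooth region darker than
    ``canal_recovery_hu`` are reclaimed as canal as well — a chain that
    stepped across a partial-volume ramp can occasionally absorb the canal
    tunnel into the tooth region, and those voxels are canal by the very
    definition used here (low-intensity matter enclosed by the tooth).

    With ``merge_regions`` (the manual unification intervention for
    fragmented dentin), regions whose mean is within ``merge_tol`` of the
    seeded region's mean and which lie within ``merge_dist`` voxels of the
    current tooth are absorbed as well.

    Returns ``(tooth_mask, canal_masks)`` with canal components sorted by
    size; ``labeling`` is annotated with the chosen labels.
    """
    vol = np.asarray(volume, dtype=float)
    labels = labeling.labels
    x, y, z = (int(round(v)) for v in np.asarray(seed_point, dtype=float))
    if not (0 <= z < labels.shape[0] and 0 <= y < labels.shape[1]
            and 0 <= x < labels.shape[2]):
        raise ValueError(f"seed point {seed_point} outside the volume")
    seed_label = int(labels[z, y, x])
    seed_mean = float(labeling.mean_intensity[seed_label])
    if seed_mean < tooth_min_hu:
        raise ValueError(
            f"seed not on a tooth: seeded region mean {seed_mean:.0f} HU "
            f"is below the hard-tissue floor {tooth_min_hu:.0f} HU")

    adjacency = _region_adjacency(labels)
    neighbors = {}
    for p, q in adjacency:
        neighbors.setdefault(p, set()).add(q)
        neighbors.setdefault(q, set()).add(p)

    tooth = {seed_label}
    frontier = [seed_label]
    while frontier:
        cur = frontier.pop()
        for nb in neighbors.get(cur, ()):
            if nb not in tooth and labeling.mean_intensity[nb] >= tooth_min_hu:
                tooth.add(nb)
                frontier.append(nb)
    tooth_mask = np.isin(labels, list(tooth))

    if merge_regions:
        changed = True
        while changed:
            changed = False
            grown = ndimage.binary_dilation(tooth_mask, structure=_STRUCT6,
                                            iterations=merge_dist)
            near = set(np.unique(labels[grown & ~tooth_mask]).tolist())
            for lab in near:
                if lab in tooth:
                    continue
                if abs(labeling.mean_intensity[lab] - seed_mean) <= merge_tol * abs(seed_mean):
                    tooth.add(lab)
                    changed = True
            if changed:
                tooth_mask = np.isin(labels, list(tooth))

    # enclosed low-density regions = canal candidates
    border_labels = set(np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel()])).tolist())
    candidates = {
        int(lab) for lab in np.unique(labels)
        if lab not in tooth and lab not in border_labels
        and labeling.mean_intensity[lab] < tooth_min_hu
    }
    changed = True
    while changed:
        changed = False
        for lab in sorted(candidates):
            outside = neighbors.get(lab, set()) - tooth - candidates
            if outside:
                candidates.discard(lab)
                changed = True
    canal_mask = np.isin(labels, list(candidates)) if candidates else \
        np.zeros_like(tooth_mask)
    recovered = tooth_mask & (vol < canal_recovery_hu)
    canal_mask |= recovered
    tooth_mask = tooth_mask & ~canal_mask
    comp_lab, ncomp = ndimage.label(canal_mask, structure=_STRUCT6)
    comps = []
    for k in range(1, ncomp + 1):
        m = comp_lab == k
        if m.sum() >= min_canal_voxels:
            comps.append(m)
    comps.sort(key=lambda m: -int(m.sum()))
    labeling.tooth_label = seed_label
    labeling.canal_labels = sorted(candidates)
    return tooth_mask, comps
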