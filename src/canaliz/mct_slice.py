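"""Per-slice processing of micro-CT records.

The stages, in pipeline order:

1. preprocessing — median filtering, burned-in text removal, trimming to
   the region of interest (the dark outer frame is discarded but its offset
   is recorded so geometry can be restored to original coordinates);
2. double partitioning — a *local* binary partition from a 4-class
   histogram-based enhanced fuzzy c-means (EnFCM) clustering of the slice,
   and a *global* partition by thresholding with tau_global estimated once
   from a small sample of slices with a 2-class EnFCM;
3. decision making — an entropy-minimizing decision tree (grown until all
   leaves are homogeneous) picks the correct binary partition from the
   four threshold features (tau_global and the three inter-prototype
   half-gaps tau_1..tau_3);
4. dark-spot detection and selection — connected dark regions inside the
   tooth cross-section (outer space discarded), selected by protocol
   P1/P2k/P3, with gravity or thinning based center points;
5. automatic shape regularization — island filling, boundary smoothing and
   unification of nearly-touching fragments.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk as _disk_se, thin as _thin

__all__ = [
    "SliceImage",
    "FcmResult",
    "ThresholdFeatures",
    "SlicePartition",
    "Spot",
    "DecisionTree",
    "preprocess_slice",
    "gray_histogram",
    "enfcm_histogram",
    "estimate_global_threshold",
    "partition_slice",
    "train_partition_tree",
    "best_split",
    "choose_partition",
    "detect_spots",
    "spot_center",
    "spot_center_from_mask",
    "select_spots",
    "regularize_spots",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class SliceImage:
    pixels: np.ndarray  # 2D float intensities (ROI only)
    roi_offset: tuple  # (row, col) of the ROI within the original slice
    z_index: int = 0


@dataclass
class FcmResult:
    c: int
    prototypes: np.ndarray  # (c,) sorted strictly ascending
    memberships: np.ndarray  # (c, L) per-gray-level membership grades
    levels: np.ndarray  # (L,) gray levels the memberships refer to
    m: float

    def __post_init__(self):
        if np.any(np.diff(self.prototypes) <= 0):
            raise ValueError("prototypes must be strictly ascending")


@dataclass
class ThresholdFeatures:
    tau_global: float
    tau_gaps: np.ndarray  # (3,) half-gaps (v_{i+1}-v_i)/2 for i=1..3
    tau_local: float  # midpoint threshold at the maximal gap
    argmax_index: int  # 1-based index i of the maximal gap

    def as_vector(self) -> np.ndarray:
        return np.concatenate([[self.tau_global], np.asarray(self.tau_gaps, float)])


@dataclass
class SlicePartition:
    labeled4: np.ndarray | None  # 4-class image from the local EnFCM
    binary_local: np.ndarray | None  # True = dark
    binary_global: np.ndarray  # True = dark
    chosen: str | None = None  # "local" | "global"
    decision_source: str | None = None  # "tree" | "heuristic" | "override"
    degenerate: bool = False  # histogram too flat for a 4-class partition

    @property
    def chosen_binary(self) -> np.ndarray:
        if self.chosen == "local" and self.binary_local is not None:
            return self.binary_local
        return self.binary_global


@dataclass
class Spot:
    """A connected dark region inside the binary slice (one canal section)."""

    pixels: np.ndarray  # (n, 2) int (row, col) within the ROI
    area: int
    center: tuple  # (row, col) floats
    center_method: str  # "gravity" | "thinning"
    min_radius: float  # shortest center-to-boundary distance, voxels
    center_outside: bool = False  # gravity center fell outside the spot

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


# ---------------------------------------------------------------------------
# MCT1 - preprocessing
# ---------------------------------------------------------------------------

def _border_background_level(img: np.ndarray) -> float:
    border = np.concatenate([img[0], img[-1], img[1:-1, 0], img[1:-1, -1]])
    return float(np.median(border))


def remove_corner_text(img: np.ndarray, corner_margin: int = 24,
                       min_contrast: float = 0.6) -> np.ndarray:
    """Remove burned-in text: high-contrast components confined to a corner."""
    bg = _border_background_level(img)
    span = float(img.max()) - bg
    if span <= 0:
        return img
    bright = img > bg + min_contrast * span
    lab, n = ndimage.label(bright, structure=_STRUCT8)
    if n == 0:
        return img
    out = img.copy()
    nr, nc = img.shape
    for k, sl in enumerate(ndimage.find_objects(lab), start=1):
        if sl is None:
            continue
        r0, r1 = sl[0].start, sl[0].stop
        c0, c1 = sl[1].start, sl[1].stop
        in_corner = ((r1 <= corner_margin or r0 >= nr - corner_margin)
                     and (c1 <= corner_margin or c0 >= nc - corner_margin))
        if in_corner:
            comp = ndimage.binary_dilation(lab == k, structure=_STRUCT8)
            out[comp] = bg
    return out


def preprocess_slice(raw: np.ndarray, median_radius: int = 1, z_index: int = 0,
                     content_tol: float = 0.25, min_contrast: float = 5.0,
                     corner_margin: int = 24,
                     remove_text: bool = True) -> SliceImage | None:
    """Median filter, text removal and ROI trimming for one raw slice.

    Returns ``None`` when the slice contains no content above background
    (the slice is skipped downstream).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty image")
    if median_radius > 0:
        img = ndimage.median_filter(raw, footprint=_disk_se(median_radius).astype(bool))
    else:
        img = raw.copy()
    if remove_text:
        img = remove_corner_text(img, corner_margin=corner_margin)
    bg = _border_background_level(img)
    span = float(img.max()) - bg
    if span <= 0:
        # constant image: keep as-is, the whole frame is the ROI
        return SliceImage(pixels=img, roi_offset=(0, 0), z_index=z_index)
    content = img > bg + max(content_tol * span, min_contrast)
    if not content.any():
        return None
    rows = np.any(content, axis=1)
    cols = np.any(content, axis=0)
    r0, r1 = int(np.argmax(rows)), int(len(rows) - np.argmax(rows[::-1]))
    c0, c1 = int(np.argmax(cols)), int(len(cols) - np.argmax(cols[::-1]))
    return SliceImage(pixels=img[r0:r1, c0:c1], roi_offset=(r0, c0), z_index=z_index)


# ---------------------------------------------------------------------------
# MCT2 - EnFCM double partitioning
# ---------------------------------------------------------------------------

def gray_histogram(img: np.ndarray):
    """Occupied gray levels and their counts (intensities rounded to integers)."""
    levels, counts = np.unique(np.round(np.asarray(img, dtype=float)), return_counts=True)
    return levels, counts


def _weighted_quantile_init(levels, counts, c):
    cum = np.cumsum(counts) / np.sum(counts)
    q = (np.arange(c) + 0.5) / c
    return np.interp(q, cum, levels)


def _memberships(levels: np.ndarray, v: np.ndarray, m: float) -> np.ndarray:
    """FCM memberships u_ik of gray level k in cluster i."""
    d2 = (levels[None, :] - v[:, None]) ** 2
    zero = d2 < 1e-300
    with np.errstate(divide="ignore"):
        p = d2 ** (-1.0 / (m - 1.0))
    p[zero] = 0.0
    denom = p.sum(axis=0, keepdims=True)
    u = np.where(denom > 0, p / np.maximum(denom, 1e-300), 0.0)
    hit_cols = np.where(zero.any(axis=0))[0]
    for k in hit_cols:
        u[:, k] = 0.0
        u[int(np.argmax(zero[:, k])), k] = 1.0
    return u


def enfcm_histogram(levels, counts, c: int, m: float = 2.0, tol: float = 1e-4,
                    max_iter: int = 500) -> FcmResult:
    """Histogram-weighted fuzzy c-means on gray levels.

    Alternating optimization of the FCM objective where each gray level is
    weighted by its histogram count; equivalent to per-pixel FCM on the
    expanded image but linear in the number of occupied levels.  Prototypes
    are initialized at evenly spaced weighted quantiles (deterministic) and
    returned sorted ascending.
    """
    levels = np.asarray(levels, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if c < 2:
        raise ValueError("c must be >= 2")
    occupied = np.unique(levels[counts > 0])
    if occupied.size < c:
        raise ValueError(
            f"histogram has {occupied.size} occupied levels, fewer than c={c}")
    v = _weighted_quantile_init(levels, counts, c)
    for i in range(1, c):  # distinct starting prototypes
        if v[i] <= v[i - 1]:
            v[i] = v[i - 1] + 1e-6
    for _ in range(max_iter):
        u = _memberships(levels, v, m)
        w = (u ** m) * counts[None, :]
        v_new = (w @ levels) / np.maximum(w.sum(axis=1), 1e-300)
        shift = float(np.max(np.abs(v_new - v)))
        v = v_new
        if shift < tol:
            break
    v = np.sort(v)
    for i in range(1, c):  # ordering contract is strict
        if v[i] <= v[i - 1]:
            v[i] = v[i - 1] + 1e-9
    u = _memberships(levels, v, m)
    return FcmResult(c=c, prototypes=v, memberships=u, levels=levels, m=m)


def estimate_global_threshold(stack, sample_fraction: float = 0.02,
                              m: float = 2.0, tol: float = 1e-4) -> float:
    """tau_global from a 2-class EnFCM over a linearly spaced slice sample.

    ``ceil(fraction * n)`` slices are pooled, taken at linearly spaced z
    indices including both endpoints; tau_global is the midpoint of the two
    prototypes.
    """
    slices = [s for s in stack if s is not None]
    if not slices:
        raise ValueError("empty stack")
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    n = len(slices)
    k = int(np.ceil(sample_fraction * n))
    idx = np.unique(np.round(np.linspace(0, n - 1, max(1, k))).astype(int))
    pooled = np.concatenate([np.asarray(slices[i].pixels, dtype=float).ravel()
                             for i in idx])
    levels, counts = gray_histogram(pooled)
    res = enfcm_histogram(levels, counts, c=2, m=m, tol=tol)
    return float(res.prototypes.mean())


def partition_slice(slc: SliceImage, tau_global: float, c: int = 4,
                    m: float = 2.0, tol: float = 1e-4):
    """Double partitioning of one slice.

    Returns ``(SlicePartition, ThresholdFeatures)``.  The local partition
    comes from a 4-class EnFCM of the slice's own histogram; its binary
    form thresholds at the midpoint of the maximal inter-prototype gap.
    The global partition thresholds at tau_global.  A degenerate histogram
    (fewer occupied levels than classes) falls back to the global partition
    only, flagged on the result.
    """
    pix = np.asarray(slc.pixels, dtype=float)
    binary_global = pix < tau_global
    levels, counts = gray_histogram(pix)
    try:
        res = enfcm_histogram(levels, counts, c=c, m=m, tol=tol)
    except ValueError:
        part = SlicePartition(labeled4=None, binary_local=None,
                              binary_global=binary_global, chosen="global",
                              decision_source="heuristic", degenerate=True)
        feats = ThresholdFeatures(tau_global=float(tau_global),
                                  tau_gaps=np.zeros(max(1, c - 1)),
                                  tau_local=float(tau_global), argmax_index=1)
        return part, feats
    v = res.prototypes
    labeled4 = np.argmin(np.abs(pix[..., None] - v[None, None, :]), axis=-1)
    gaps = np.diff(v)
    i = int(np.argmax(gaps))  # 0-based; ties -> first
    tau_local = float((v[i] + v[i + 1]) / 2.0)
    binary_local = pix < tau_local
    feats = ThresholdFeatures(tau_global=float(tau_global), tau_gaps=gaps / 2.0,
                              tau_local=tau_local, argmax_index=i + 1)
    part = SlicePartition(labeled4=labeled4, binary_local=binary_local,
                          binary_global=binary_global)
    return part, feats


# ---------------------------------------------------------------------------
# MCT3 - decision tree
# ---------------------------------------------------------------------------

@dataclass
class _TreeNode:
    feature: int | None = None
    threshold: float = 0.0
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None
    label: str | None = None  # set on leaves only
    gain: float = 0.0


@dataclass
class DecisionTree:
    """Axis-aligned binary decision tree over the 4 threshold features."""

    root: _TreeNode

    def predict(self, features) -> str:
        x = features.as_vector() if isinstance(features, ThresholdFeatures) \
            else np.asarray(features, dtype=float)
        node = self.root
        while node.label is None:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.label

    def depth(self) -> int:
        def d(n):
            return 0 if n.label is not None else 1 + max(d(n.left), d(n.right))
        return d(self.root)

    def n_leaves(self) -> int:
        def c(n):
            return 1 if n.label is not None else c(n.left) + c(n.right)
        return c(self.root)


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def best_split(X: np.ndarray, y: np.ndarray):
    """Best (feature, threshold, information gain) over midpoint candidates.

    Ties broken by lowest feature index, then lowest threshold.
    """
    n, d = X.shape
    h0 = _entropy(y)
    best = (None, 0.0, -1.0)
    for f in range(d):
        vals = X[:, f]
        order = np.argsort(vals, kind="stable")
        sv, sy = vals[order], y[order]
        distinct = np.where(np.diff(sv) > 0)[0]
        for k in distinct:
            thr = (sv[k] + sv[k + 1]) / 2.0
            left, right = sy[: k + 1], sy[k + 1:]
            gain = h0 - (len(left) * _entropy(left) + len(right) * _entropy(right)) / n
            if gain > best[2] + 1e-12:
                best = (f, thr, gain)
    return best


def train_partition_tree(samples) -> DecisionTree:
    """Grow an entropy-minimizing tree until every leaf is homogeneous.

    ``samples`` is a sequence of ``(ThresholdFeatures-or-vector, label)``
    with labels in {"local", "global"}.  Contradictory duplicates (identical
    feature vectors, different labels) are rejected because a homogeneous
    tree cannot exist for them.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 training samples")
    X = np.array([
        f.as_vector() if isinstance(f, ThresholdFeatures) else np.asarray(f, float)
        for f, _ in samples
    ])
    y = np.array([lab for _, lab in samples])
    if set(y) - {"local", "global"}:
        raise ValueError("labels must be 'local' or 'global'")
    if len(set(y)) < 2:
        return DecisionTree(root=_TreeNode(label=str(y[0])))
    seen = {}
    bad = []
    for k, (row, lab) in enumerate(zip(map(tuple, X), y)):
        if row in seen and seen[row][1] != lab:
            bad.append((seen[row][0], k))
        seen.setdefault(row, (k, lab))
    if bad:
        raise ValueError(f"contradictory duplicate feature vectors at sample pairs {bad}")

    def grow(Xs, ys):
        if len(set(ys)) == 1:
            return _TreeNode(label=str(ys[0]))
        f, thr, gain = best_split(Xs, ys)
        if f is None:
            raise RuntimeError("no valid split found for heterogeneous node")
        mask = Xs[:, f] <= thr
        node = _TreeNode(feature=f, threshold=thr, gain=gain)
        node.left = grow(Xs[mask], ys[mask])
        node.right = grow(Xs[~mask], ys[~mask])
        return node

    return DecisionTree(root=grow(X, y))


def _interior_dark_fraction(binary: np.ndarray) -> float:
    """Fraction of dark pixels not connected to the ROI border."""
    if not binary.any():
        return 0.0
    lab, n = ndimage.label(binary, structure=_STRUCT8)
    border = np.unique(np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
    interior = binary & ~np.isin(lab, border[border > 0])
    return float(interior.sum()) / binary.size


def choose_partition(partition: SlicePartition, features: ThresholdFeatures,
                     tree: DecisionTree | None,
                     plausible_band=(0.001, 0.15)) -> SlicePartition:
    """Fill the local-vs-global decision on a slice partition.

    With a trained tree the tree's verdict is used.  Without one, a shipped
    heuristic keeps the partition whose interior dark-pixel fraction (dark
    pixels not connected to the ROI border, i.e. canal candidates) falls in
    a plausible band; local is preferred on ties.
    """
    if partition.degenerate or partition.binary_local is None:
        partition.chosen = "global"
        partition.decision_source = partition.decision_source or "heuristic"
        return partition
    if tree is not None:
        partition.chosen = tree.predict(features)
        partition.decision_source = "tree"
        return partition
    lo, hi = plausible_band
    ok_local = lo <= _interior_dark_fraction(partition.binary_local) <= hi
    ok_global = lo <= _interior_dark_fraction(partition.binary_global) <= hi
    partition.chosen = "local" if (ok_local or not ok_global) else "global"
    partition.decision_source = "heuristic"
    return partition


# ---------------------------------------------------------------------------
# MCT4 - spot detection, centers, selection
# ---------------------------------------------------------------------------

def _min_radius(comp_mask: np.ndarray, center) -> float:
    """Shortest center-to-boundary distance (EDT convention: a rasterized
    disk of radius r yields r; a single pixel yields 0)."""
    edt = ndimage.distance_transform_edt(comp_mask)
    r = int(np.clip(round(center[0]), 0, comp_mask.shape[0] - 1))
    c = int(np.clip(round(center[1]), 0, comp_mask.shape[1] - 1))
    if not comp_mask[r, c]:
        pix = np.argwhere(comp_mask)
        d = np.abs(pix - np.asarray(center)).sum(axis=1)
        r, c = pix[int(np.argmin(d))]
    return float(max(0.0, edt[r, c] - 1.0))


def _component_spot(comp_mask: np.ndarray, center_method: str = "gravity") -> Spot:
    pix = np.argwhere(comp_mask)
    center, outside = spot_center_from_mask(comp_mask, center_method)
    return Spot(pixels=pix, area=int(len(pix)), center=center,
                center_method=center_method,
                min_radius=_min_radius(comp_mask, center),
                center_outside=outside)


def detect_spots(binary: np.ndarray, center_method: str = "gravity") -> list:
    """Connected dark regions, outer space discarded.

    Dark components (8-connectivity) touching the ROI border are classified
    as outer space; the rest are returned as spots sorted by descending
    area (ties by first pixel position, for determinism).
    """
    binary = np.asarray(binary, dtype=bool)
    lab, n = ndimage.label(binary, structure=_STRUCT8)
    if n == 0:
        return []
    border = np.unique(np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
    border = set(border[border > 0].tolist())
    spots = [_component_spot(lab == k, center_method)
             for k in range(1, n + 1) if k not in border]
    spots.sort(key=lambda s: (-s.area, s.pixels[0][0], s.pixels[0][1]))
    return spots


def spot_center_from_mask(comp_mask: np.ndarray, method: str = "gravity"):
    """Center point of one spot mask; returns ``((row, col), outside_flag)``.

    Gravity is the area centroid and may fall outside a concave spot (the
    flag reports this); thinning reduces the spot to a skeletal residue and
    takes the residue point farthest from the boundary, which always lies
    inside.
    """
    pix = np.argwhere(comp_mask)
    if len(pix) == 0:
        raise ValueError("empty spot")
    if method == "gravity":
        center = pix.mean(axis=0)
        r, c = int(round(center[0])), int(round(center[1]))
        outside = not (0 <= r < comp_mask.shape[0] and 0 <= c < comp_mask.shape[1]
                       and comp_mask[r, c])
        return (float(center[0]), float(center[1])), bool(outside)
    if method == "thinning":
        residue = _thin(comp_mask)
        if not residue.any():
            residue = comp_mask
        edt = ndimage.distance_transform_edt(comp_mask)
        cand = np.argwhere(residue)
        vals = edt[cand[:, 0], cand[:, 1]]
        best = cand[np.lexsort((cand[:, 1], cand[:, 0], -vals))][0]
        return (float(best[0]), float(best[1])), False
    raise ValueError(f"unknown center method {method!r}")


def spot_center(spot: Spot, method: str = "gravity", shape=None):
    """Recompute a spot's center with the requested method."""
    if shape is None:
        shape = tuple(spot.pixels.max(axis=0) + 1)
    return spot_center_from_mask(spot.mask(shape), method)


def select_spots(spots, protocol: str = "P3", k: int = 2, min_size: int = 5,
                 min_area: int = 4, min_ratio: float = 0.02) -> list:
    """Spot selection protocols.

    P1 keeps only the largest spot (incisor prior: a single canal).  P2
    keeps the largest plus spots 2..k when larger than ``min_size``.  P3
    keeps every spot passing the size rules (absolute area >= ``min_area``
    and area ratio to the largest >= ``min_ratio``).
    """
    if not spots:
        return []
    if protocol == "P1":
        return [spots[0]]
    if protocol == "P2":
        if k not in (2, 3, 4):
            raise ValueError("P2 requires k in {2, 3, 4}")
        return [spots[0]] + [s for s in spots[1:k] if s.area > min_size]
    if protocol == "P3":
        largest = spots[0].area
        return [s for s in spots
                if s.area >= min_area and s.area / largest >= min_ratio]
    raise ValueError(f"unknown protocol {protocol!r}")


# ---------------------------------------------------------------------------
# MCT5 - automatic shape regularization
# ---------------------------------------------------------------------------

def regularize_spots(spots, roi_shape, smooth_radius: int = 2,
                     merge_distance: float = 2.0,
                     center_method: str = "gravity") -> list:
    """Regularize the dark spots of one slice.

    Light islands inside spots are filled; thin peninsulas are removed by
    morphological opening and the boundary concavities repaired by the
    closing that follows (opening first, so a peninsula narrower than the
    structuring element is removed exactly rather than welded into the
    boundary); spots separated by less than the merge distance are
    unified.  The smoothing loop runs to a fixed point, which makes the
    operation idempotent.
    """
    if not spots:
        return []
    mask = np.zeros(roi_shape, dtype=bool)
    for s in spots:
        mask[s.pixels[:, 0], s.pixels[:, 1]] = True
    se_smooth = _disk_se(smooth_radius).astype(bool) if smooth_radius > 0 else None
    merge_r = int(np.ceil(merge_distance / 2.0))
    se_merge = _disk_se(merge_r).astype(bool) if merge_r > 0 else None
    for _ in range(8):
        prev = mask
        mask = ndimage.binary_fill_holes(mask)
        if se_merge is not None:
            mask = ndimage.binary_closing(mask, structure=se_merge)
        if se_smooth is not None:
            mask = ndimage.binary_opening(mask, structure=se_smooth)
            mask = ndimage.binary_closing(mask, structure=se_smooth)
        mask = ndimage.binary_fill_holes(mask)
        if np.array_equal(mask, prev):
            break
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    out = [_component_spot(lab == k, center_method) for k in range(1, n + 1)]
    out.sort(key=lambda s: (-s.area, s.pixels[0][0], s.pixels[0][1]))
    return out
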