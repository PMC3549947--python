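"""Polyline curve-skeleton graphs shared by the micro-CT and CBCT pipelines.

A curve skeleton is represented as a set of branches (ordered 3D point
sequences, coordinates in voxel units, ``(x, y, z)`` with ``z`` the stacking
axis) plus the nodes where branches start and end.  Nodes of degree 1 are
endpoints (canal orifice or apex), nodes of degree >= 3 are junctions
(canal bifurcations).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SkeletonNode",
    "SkeletonGraph",
    "polyline_length",
    "resample_polyline",
    "assemble_graph",
]


@dataclass
class SkeletonNode:
    point: np.ndarray  # (3,) float, voxel coordinates (x, y, z)
    kind: str  # "endpoint" or "junction"

    def to_dict(self) -> dict:
        return {"point": [float(v) for v in self.point], "kind": self.kind}


@dataclass
class SkeletonGraph:
    """Branches as ordered 3D point sequences plus endpoint/junction nodes."""

    branches: list = field(default_factory=list)  # list of (n_i, 3) arrays
    nodes: list = field(default_factory=list)  # list of SkeletonNode

    # -- basic queries ----------------------------------------------------
    @property
    def n_endpoints(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "endpoint")

    @property
    def n_junctions(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "junction")

    @property
    def is_empty(self) -> bool:
        return not self.branches or all(len(b) == 0 for b in self.branches)

    def branch_lengths(self) -> list:
        return [polyline_length(b) for b in self.branches]

    def total_length(self) -> float:
        return float(sum(self.branch_lengths()))

    def all_points(self) -> np.ndarray:
        if not self.branches:
            return np.empty((0, 3))
        return np.vstack(self.branches)

    def sampled_points(self, spacing: float = 0.25) -> np.ndarray:
        """All branch points after dense arc-length resampling."""
        pts = [resample_polyline(b, spacing) for b in self.branches if len(b)]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    # -- transforms -------------------------------------------------------
    def translated(self, offset) -> "SkeletonGraph":
        off = np.asarray(offset, dtype=float)
        return SkeletonGraph(
            branches=[b + off for b in self.branches],
            nodes=[SkeletonNode(n.point + off, n.kind) for n in self.nodes],
        )

    def scaled(self, factor: float) -> "SkeletonGraph":
        return SkeletonGraph(
            branches=[b * factor for b in self.branches],
            nodes=[SkeletonNode(n.point * factor, n.kind) for n in self.nodes],
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": [n.to_dict() for n in self.nodes],
            "branches": [[[float(v) for v in p] for p in b] for b in self.branches],
        }

    def to_json(self, path=None, indent=None) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "SkeletonGraph":
        nodes = [
            SkeletonNode(np.asarray(n["point"], dtype=float), n["kind"])
            for n in data["nodes"]
        ]
        branches = [np.asarray(b, dtype=float).reshape(-1, 3) for b in data["branches"]]
        return cls(branches=branches, nodes=nodes)

    @classmethod
    def from_json(cls, text_or_path) -> "SkeletonGraph":
        text = text_or_path
        if "\n" not in text and text.strip()[:1] != "{":
            with open(text_or_path) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))


def polyline_length(points) -> float:
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def resample_polyline(points, spacing: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length spacing.

    Endpoints are always preserved exactly.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 2:
        return points.copy()
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return points[[0, -1]].copy()
    n = max(2, int(np.ceil(total / spacing)) + 1)
    t = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(t, s, points[:, k]) for k in range(3)])


def _nearest_vertex(poly: np.ndarray, p: np.ndarray):
    d = np.linalg.norm(poly - p, axis=1)
    i = int(np.argmin(d))
    return i, float(d[i])


def assemble_graph(polylines, join_tol: float = 1.0) -> SkeletonGraph:
    """Assemble raw polylines into a SkeletonGraph.

    Endpoints within ``join_tol`` of each other are merged into a single
    node; a polyline endpoint landing mid-way on another polyline splits it
    there (canal branch attaching to its parent).  Degree-2 nodes are
    dissolved by concatenating their two branches, and branches collapsed
    below the merge tolerance are dropped, so junction/endpoint counts
    reflect the curve topology only.
    """
    polys = [np.asarray(p, dtype=float).reshape(-1, 3) for p in polylines if len(p) > 0]
    polys = [p for p in polys if len(p) >= 1]
    if not polys:
        return SkeletonGraph()
    if len(polys) == 1 and len(polys[0]) == 1:
        p = polys[0]
        return SkeletonGraph(branches=[p], nodes=[SkeletonNode(p[0].copy(), "endpoint")])

    # 1) split polylines where another polyline's endpoint attaches mid-curve
    changed = True
    guard = 0
    while changed and guard < 100:
        changed = False
        guard += 1
        for a_idx, a in enumerate(polys):
            for end in (a[0], a[-1]):
                for b_idx, b in enumerate(polys):
                    if b_idx == a_idx or len(b) < 3:
                        continue
                    i, d = _nearest_vertex(b, end)
                    if d > join_tol:
                        continue
                    # interior attachment only: skip if near either end of b
                    if (
                        np.linalg.norm(b[i] - b[0]) <= join_tol
                        or np.linalg.norm(b[i] - b[-1]) <= join_tol
                    ):
                        continue
                    polys[b_idx] = b[: i + 1]
                    polys.append(b[i:])
                    changed = True
                    break
                if changed:
                    break
            if changed:
                break

    # 2) cluster branch endpoints into nodes (union-find over proximity)
    ends = []  # (poly index, which end, position)
    for i, p in enumerate(polys):
        ends.append((i, 0, p[0]))
        ends.append((i, 1, p[-1]))
    m = len(ends)
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            if np.linalg.norm(ends[i][2] - ends[j][2]) <= join_tol:
                parent[find(i)] = find(j)

    clusters = {}
    for i in range(m):
        clusters.setdefault(find(i), []).append(i)
    node_pos = {root: np.mean([ends[i][2] for i in idx], axis=0) for root, idx in clusters.items()}
    end_node = {}
    for root, idx in clusters.items():
        for i in idx:
            end_node[(ends[i][0], ends[i][1])] = root

    # 3) snap branch ends to node positions, drop collapsed branches
    branches = []  # (node_a, node_b, points)
    for i, p in enumerate(polys):
        na, nb = end_node[(i, 0)], end_node[(i, 1)]
        pts = p.copy()
        pts[0] = node_pos[na]
        pts[-1] = node_pos[nb]
        if na == nb and polyline_length(pts) <= 2.0 * join_tol:
            continue  # collapsed loop at a node
        if len(pts) == 1:
            continue
        branches.append([na, nb, pts])
    if not branches:
        root = min(node_pos)
        return SkeletonGraph(
            branches=[np.asarray([node_pos[root]])],
            nodes=[SkeletonNode(node_pos[root], "endpoint")],
        )

    # 4) dissolve degree-2 nodes by concatenating their two branches
    def degree_map(brs):
        deg = {}
        for na, nb, _ in brs:
            deg[na] = deg.get(na, 0) + 1
            deg[nb] = deg.get(nb, 0) + 1
        return deg

    guard = 0
    while guard < 1000:
        guard += 1
        deg = degree_map(branches)
        node2 = next(
            (n for n, d in deg.items() if d == 2 and _not_self_loop(branches, n)), None
        )
        if node2 is None:
            break
        incident = [k for k, (na, nb, _) in enumerate(branches) if na == node2 or nb == node2]
        if len(incident) != 2:
            break
        k1, k2 = incident
        na1, nb1, p1 = branches[k1]
        na2, nb2, p2 = branches[k2]
        if nb1 != node2:
            p1 = p1[::-1]
            na1, nb1 = nb1, na1
        if na2 != node2:
            p2 = p2[::-1]
            na2, nb2 = nb2, na2
        merged = np.vstack([p1, p2[1:]])
        new = [b for k, b in enumerate(branches) if k not in (k1, k2)]
        new.append([na1, nb2, merged])
        branches = new

    deg = degree_map(branches)
    used_nodes = sorted(deg)
    nodes = [
        SkeletonNode(node_pos[n], "endpoint" if deg[n] == 1 else "junction")
        for n in used_nodes
        if deg[n] != 2
    ]
    return SkeletonGraph(branches=[b[2] for b in branches], nodes=nodes)


def _not_self_loop(branches, node) -> bool:
    for na, nb, _ in branches:
        if na == node and nb == node:
            return False
    return True


def symmetric_distance(a: SkeletonGraph, b: SkeletonGraph, spacing: float = 0.25):
    """Mean and max of symmetric point-to-nearest-curve distances (voxels)."""
    pa = a.sampled_points(spacing)
    pb = b.sampled_points(spacing)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("cannot compare empty skeletons")
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    mean = 0.5 * (float(np.mean(d_ab)) + float(np.mean(d_ba)))
    mx = max(float(np.max(d_ab)), float(np.max(d_ba)))
    return mean, mx
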