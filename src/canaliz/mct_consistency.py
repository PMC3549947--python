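"""Stack-level quality control for the micro-CT pipeline.

Canal anatomy cannot change abruptly between adjacent cross-sections, so
detected dark-spot centers are correlated across neighbor slices.  A large
jump of a spot center, or a change in the number of spots, flags the slice:
a persistent count change whose new spots keep correlating with the next
neighbor is a bifurcation; anything else is advised for intervention.
Flagging is deliberately conservative (more slices advised than truly need
intervention).

Interventions arrive as machine-readable overrides: M1 overrules the
local/global decision, M2 re-thresholds a slice with an explicit value,
M3 discards a detected spot.  (Interactive snake-based unification is not
implemented — it requires user initialization.)
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import mct_slice
from .mct_slice import SliceImage, SlicePartition, Spot, ThresholdFeatures

__all__ = [
    "SpotTrack",
    "EventFlag",
    "Override",
    "SliceRecord",
    "MctStackResult",
    "match_adjacent",
    "default_dist_threshold",
    "classify_events",
    "apply_overrides",
]


@dataclass
class SpotTrack:
    """Per-slice spot centers plus greedy correspondences between neighbors."""

    centers: list  # for each z: list of (row, col)
    links: list  # for each boundary z -> z+1: list of (i, j, distance)
    unmatched: list  # for each boundary: (indices disappearing, indices appearing)

    @property
    def counts(self):
        return [len(c) for c in self.centers]

    def max_link_distance(self, boundary: int) -> float:
        lk = self.links[boundary]
        return max((d for _, _, d in lk), default=0.0)

    def all_link_distances(self):
        return [d for lk in self.links for _, _, d in lk]


@dataclass
class EventFlag:
    z_index: int
    kind: str  # "bifurcation" | "intervention"
    evidence: dict  # spot counts at z-1, z, z+1 and max link distance


@dataclass
class Override:
    """One programmatic manual intervention."""

    z_index: int
    action: str  # "M1_force_partition" | "M2_set_threshold" | "M3_discard_spot"
    value: object = None  # M1: "local"/"global"; M2: threshold; M3: spot index


@dataclass
class SliceRecord:
    """Everything the pipeline knows about one processed slice."""

    image: SliceImage
    partition: SlicePartition
    features: ThresholdFeatures
    spots: list  # list[Spot] after selection/regularization


@dataclass
class MctStackResult:
    """Per-slice results of the micro-CT 2D stages, for one record.

    ``records[z]`` is ``None`` for slices that were skipped (no content).
    ``spot_extractor`` maps a binary dark image to the slice's final spot
    list and is re-run when an override changes a slice's partition.
    """

    records: list
    tau_global: float
    spot_extractor: object = None  # Callable[[np.ndarray], list[Spot]]
    frame_shape: tuple | None = None  # original (rows, cols) of raw slices

    def per_slice_centers(self):
        out = []
        for rec in self.records:
            if rec is None:
                out.append([])
            else:
                r0, c0 = rec.image.roi_offset
                out.append([(s.center[0] + r0, s.center[1] + c0) for s in rec.spots])
        return out

    def per_slice_spots(self):
        return [[] if rec is None else rec.spots for rec in self.records]

    def roi_offsets(self):
        return [(0, 0) if rec is None else rec.image.roi_offset for rec in self.records]


# ---------------------------------------------------------------------------
# MCT6 - correlation checking
# ---------------------------------------------------------------------------

def match_adjacent(per_slice_centers) -> SpotTrack:
    """Greedy nearest-center matching between consecutive slices.

    Repeatedly links the globally closest unmatched pair; each spot links
    to at most one spot in the adjacent slice.  Spots left unmatched are
    recorded as disappearing (slice z) or appearing (slice z+1).
    """
    centers = [[(float(r), float(c)) for r, c in cs] for cs in per_slice_centers]
    if len(centers) < 2:
        raise ValueError("need at least 2 slices to correlate")
    links, unmatched = [], []
    for z in range(len(centers) - 1):
        a, b = centers[z], centers[z + 1]
        pairs = []
        if a and b:
            d = np.linalg.norm(
                np.asarray(a)[:, None, :] - np.asarray(b)[None, :, :], axis=2)
            used_i, used_j = set(), set()
            order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
            for i, j in order:
                if i in used_i or j in used_j:
                    continue
                pairs.append((int(i), int(j), float(d[i, j])))
                used_i.add(int(i))
                used_j.add(int(j))
        gone = [i for i in range(len(a)) if i not in {p[0] for p in pairs}]
        new = [j for j in range(len(b)) if j not in {p[1] for p in pairs}]
        links.append(pairs)
        unmatched.append((gone, new))
    return SpotTrack(centers=centers, links=links, unmatched=unmatched)


def default_dist_threshold(track: SpotTrack, floor: float = 5.0,
                           factor: float = 3.0) -> float:
    """Robust data-driven jump threshold: 3x the median link distance."""
    d = track.all_link_distances()
    if not d:
        return floor
    return float(max(floor, factor * float(np.median(d))))


def classify_events(track: SpotTrack, dist_threshold: float | None = None,
                    persistence: int = 2) -> list:
    """Flag slices where neighbor correlation breaks.

    A boundary between z and z+1 is anomalous when the largest link jump
    exceeds the distance threshold or the spot count changes.  A count
    change is a bifurcation when the new count persists for at least
    ``persistence`` further slices and every spot of slice z+1 correlates
    (link distance below threshold) with slice z+2; otherwise the slice is
    advised for intervention.
    """
    if dist_threshold is None:
        dist_threshold = default_dist_threshold(track)
    counts = track.counts
    nz = len(counts)
    occupied = [z for z, c in enumerate(counts) if c > 0]
    if not occupied:
        return []
    z_lo, z_hi = occupied[0], occupied[-1]
    flags = []
    for z in range(nz - 1):
        if z + 1 < z_lo or z > z_hi:
            continue  # outside the span where the canal is present at all
        max_d = track.max_link_distance(z)
        count_change = counts[z] != counts[z + 1]
        jump = max_d > dist_threshold
        if not (count_change or jump):
            continue
        kind = "intervention"
        if count_change and counts[z] > 0 and counts[z + 1] > 0:
            persist = all(
                counts[z2] == counts[z + 1]
                for z2 in range(z + 1, min(nz, z + 2 + persistence))
            )
            correlates = True
            if z + 1 < nz - 1:
                nxt = track.links[z + 1]
                matched_j = {i for i, _, d in nxt if d <= dist_threshold}
                correlates = matched_j >= set(range(counts[z + 1]))
            if persist and correlates and not jump:
                kind = "bifurcation"
        flags.append(EventFlag(
            z_index=z + 1, kind=kind,
            evidence={
                "counts": (counts[z] if z >= 0 else None,
                           counts[z + 1],
                           counts[z + 2] if z + 2 < nz else None),
                "max_link_dist": max_d,
            },
        ))
    return flags


# ---------------------------------------------------------------------------
# MCT7 - programmatic overrides (M1-M3)
# ---------------------------------------------------------------------------

_ACTION_RANK = {"M1_force_partition": 0, "M2_set_threshold": 0, "M3_discard_spot": 1}


def apply_overrides(result: MctStackResult, overrides) -> MctStackResult:
    """Apply manual-intervention overrides and recompute affected slices.

    M1 re-selects the named partition, M2 re-thresholds the slice with an
    explicit value (the slice then uses that binary image), M3 removes one
    detected spot.  Spot extraction is re-run only for slices whose binary
    partition changed.  Conflicting overrides on one slice — more than one
    partition-level override (M1/M2), an M3 combined with M1/M2, or two
    M3s naming the same spot — are an error, which keeps application
    order-independent.
    """
    if not overrides:
        return result
    for ov in overrides:
        if ov.action not in _ACTION_RANK:
            raise ValueError(f"unknown override action {ov.action!r}")
        if not 0 <= ov.z_index < len(result.records):
            raise ValueError(f"override targets unknown slice z={ov.z_index}")
        if result.records[ov.z_index] is None:
            raise ValueError(f"override targets skipped slice z={ov.z_index}")
    by_slice = {}
    for ov in overrides:
        by_slice.setdefault(ov.z_index, []).append(ov)
    for z, ovs in by_slice.items():
        part_level = [o for o in ovs if _ACTION_RANK[o.action] == 0]
        discards = [o for o in ovs if o.action == "M3_discard_spot"]
        if len(part_level) > 1:
            raise ValueError(f"conflicting partition overrides on slice z={z}")
        if part_level and discards:
            raise ValueError(
                f"M3 spot indices are ambiguous after re-partitioning slice z={z}")
        if len({o.value for o in discards}) != len(discards):
            raise ValueError(f"duplicate M3 overrides on slice z={z}")

    extractor = result.spot_extractor or (lambda b: mct_slice.detect_spots(b))
    records = list(result.records)
    for z in sorted(by_slice):
        rec = records[z]
        part = replace(rec.partition)
        spots = list(rec.spots)
        for ov in sorted(by_slice[z], key=lambda o: (_ACTION_RANK[o.action], str(o.value))):
            if ov.action == "M1_force_partition":
                if ov.value not in ("local", "global"):
                    raise ValueError(f"M1 value must be 'local' or 'global', got {ov.value!r}")
                part.chosen = ov.value
                part.decision_source = "override"
                spots = extractor(part.chosen_binary)
            elif ov.action == "M2_set_threshold":
                thr = float(ov.value)
                part.binary_local = np.asarray(rec.image.pixels, dtype=float) < thr
                part.chosen = "local"
                part.decision_source = "override"
                spots = extractor(part.binary_local)
            else:  # M3_discard_spot
                idx = int(ov.value)
                if not 0 <= idx < len(spots):
                    raise ValueError(
                        f"M3 on slice z={z} names spot {idx}, but only "
                        f"{len(spots)} spots were detected")
                spots = [s for k, s in enumerate(spots) if k != idx]
        records[z] = SliceRecord(image=rec.image, partition=part,
                                 features=rec.features, spots=spots)
    return MctStackResult(records=records, tau_global=result.tau_global,
                          spot_extractor=result.spot_extractor,
                          frame_shape=result.frame_shape)
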