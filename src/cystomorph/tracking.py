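"""Time-lapse structure tracking.

Structures embedded in gel are nearly stationary, so identity across
revisited fields is recovered by greedy nearest-centroid linking under a
distance gate (default 50 μm between consecutive timepoints).  Greedy
ascending-distance matching is fully deterministic (ties broken by smaller
structure id) and adequate for sparse, slow objects; it is documented as a
limitation under crowding.  A track interrupted at a single timepoint
(e.g. a focus exclusion) may bridge one gap when the displacement over the
doubled interval stays within 1.5x the gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .segment import StructureRecord

__all__ = ["Track", "link_timepoints", "build_tracks", "DEFAULT_GATE_UM"]

DEFAULT_GATE_UM = 50.0


@dataclass
class Track:
    """One structure identity followed through time."""

    track_id: int
    arm: str
    induction_time_h: float
    records: list[StructureRecord] = field(default_factory=list)

    @property
    def timepoints_h(self) -> list[float]:
        return [r.timepoint_h for r in self.records]

    @property
    def complete(self) -> bool:
        """Observed at >=1 pre-induction and >=1 post-induction timepoint."""
        ts = self.timepoints_h
        t0 = self.induction_time_h
        return any(t <= t0 for t in ts) and any(t > t0 for t in ts)

    def record_at(self, timepoint_h: float) -> StructureRecord | None:
        for r in self.records:
            if r.timepoint_h == timepoint_h:
                return r
        return None


def _dist(a: StructureRecord, b: StructureRecord) -> float:
    return math.hypot(
        a.centroid_um[0] - b.centroid_um[0], a.centroid_um[1] - b.centroid_um[1]
    )


def link_timepoints(
    records_a: list[StructureRecord],
    records_b: list[StructureRecord],
    gate_um: float = DEFAULT_GATE_UM,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy nearest-centroid matching between two timepoints.

    Candidate pairs within the gate are taken in ascending distance order
    (ties by the smaller structure ids); each record is used at most once.

    Returns
    -------
    matches, deaths, births
        ``matches`` as index pairs ``(i, j)`` into the two lists; ``deaths``
        are unmatched indices of ``records_a``, ``births`` of ``records_b``.
    """
    if gate_um <= 0:
        raise ValueError("gate_um must be positive")
    pairs = []
    for i, ra in enumerate(records_a):
        for j, rb in enumerate(records_b):
            d = _dist(ra, rb)
            if d <= gate_um:
                pairs.append((d, ra.structure_id, rb.structure_id, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _d, _ia, _ib, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    deaths = [i for i in range(len(records_a)) if i not in used_a]
    births = [j for j in range(len(records_b)) if j not in used_b]
    return matches, deaths, births


def build_tracks(
    records_by_time: dict[float, list[StructureRecord]],
    arm: str,
    induction_time_h: float,
    gate_um: float = DEFAULT_GATE_UM,
    bridge_gaps: bool = True,
) -> list[Track]:
    """Link all timepoints of one field into identity-preserving tracks.

    Tracks are the transitive closure of consecutive-timepoint links; a
    track missing one timepoint may be re-joined at the next one within a
    widened gate of ``1.5 * gate_um`` when ``bridge_gaps`` is on.  Track ids
    are assigned in order of first appearance (then by structure id).
    """
    mixed = {
        fid
        for recs in records_by_time.values()
        for fid in {r.field_id for r in recs}
    }
    if len(mixed) > 1:
        raise ValueError(f"records come from multiple fields: {sorted(mixed)}")
    times = sorted(records_by_time)
    if len(times) < 2:
        raise ValueError("tracking needs at least two timepoints")
    tracks: list[Track] = []
    # open tracks eligible for extension: (track, missed_count)
    open_tracks: list[tuple[Track, int]] = []

    def new_track(rec: StructureRecord) -> Track:
        tr = Track(
            track_id=len(tracks) + 1, arm=arm, induction_time_h=induction_time_h
        )
        tr.records.append(rec)
        tracks.append(tr)
        return tr

    first = sorted(records_by_time[times[0]], key=lambda r: r.structure_id)
    for rec in first:
        open_tracks.append((new_track(rec), 0))
    for t in times[1:]:
        current = sorted(records_by_time[t], key=lambda r: r.structure_id)
        tails = [tr.records[-1] for tr, _missed in open_tracks]
        # link within the widened gate, then enforce the per-track gate:
        # ordinary links must stay within gate_um, single-gap bridges within
        # 1.5 * gate_um over the doubled interval
        matches, _deaths, _births = link_timepoints(tails, current, 1.5 * gate_um)
        claimed: set[int] = set()
        next_open: list[tuple[Track, int]] = []
        matched_a = dict(matches)
        for idx, (tr, missed) in enumerate(open_tracks):
            j = matched_a.get(idx)
            limit = 1.5 * gate_um if missed > 0 else gate_um
            if j is not None and _dist(tails[idx], current[j]) <= limit:
                tr.records.append(current[j])
                claimed.add(j)
                next_open.append((tr, 0))
            elif bridge_gaps and missed == 0:
                next_open.append((tr, 1))  # allow one skipped timepoint
        for j, rec in enumerate(current):
            if j not in claimed:
                next_open.append((new_track(rec), 0))
        open_tracks = next_open
    return tracks
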