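"""Contraction-pattern classification from dyssynchrony indices and segments.

A patient is *mildly dyssynchronous* when both global indices sit at or
below the dyssynchrony thresholds (PSD <= 40.3 deg and PBW <= 111.9 deg,
derived in the source population from LBBB controls with normal LV
function); otherwise the pattern is severe and is subtyped by the
spatial arrangement of segment-level onset phases:

* U-shaped      — a line of block between adjacent segments with one
                  contiguous late-contracting territory (propagation
                  wraps around the apex);
* heterogeneous — multiple disjoint territories of significant delay;
* homogeneous   — contraction propagates from the septum to the lateral
                  wall monotonically, with no block line.

The original subtypes were visual reads; the explicit numeric rules
here (block threshold, delay offset, monotonicity tolerance) are this
package's operationalisation and are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .circular import circular_diff, circular_distance, circular_mean, circular_range
from .perfusion import N_SEGMENTS, SegmentProfile
from .phase import DyssynchronyIndices

logger = logging.getLogger(__name__)


class PatternLabel(str, Enum):
    MILD = "MILD"
    U_SHAPED = "U_SHAPED"
    HETEROGENEOUS = "HETEROGENEOUS"
    HOMOGENEOUS = "HOMOGENEOUS"


class GlobalClass(str, Enum):
    MILD = "MILD"
    SEVERE = "SEVERE"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the pattern classifier.

    psd_threshold_deg / pbw_threshold_deg
        Mild-vs-severe cutoffs (both must be satisfied for MILD).
    block_delta_deg
        Minimum circular phase jump between adjacent segments to call a
        line of block.
    delay_offset_deg
        A segment later than the circular mean segment phase by at
        least this much is "delayed".
    monotone_tolerance_deg
        Slack allowed when checking septum-to-lateral monotone
        propagation for the homogeneous subtype.
    """

    psd_threshold_deg: float = 40.3
    pbw_threshold_deg: float = 111.9
    block_delta_deg: float = 90.0
    delay_offset_deg: float = 45.0
    monotone_tolerance_deg: float = 20.0

    def __post_init__(self):
        for name in ("psd_threshold_deg", "pbw_threshold_deg", "block_delta_deg",
                     "delay_offset_deg", "monotone_tolerance_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class PatternResult:
    """Classifier output with the evidence behind the label."""

    label: PatternLabel
    block_lines: list = field(default_factory=list)   # lines, each a list of segment pairs
    delayed_clusters: list = field(default_factory=list)  # clusters, each a list of segment ids
    phase_range_deg: float = float("nan")
    fallback: bool = False  # True when no subtype rule matched cleanly


def classify_global(idx: DyssynchronyIndices, cfg: ClassifierConfig = ClassifierConfig()) -> GlobalClass:
    """MILD iff PSD and PBW are both at or below their thresholds."""
    if idx.psd_deg <= cfg.psd_threshold_deg and idx.pbw_deg <= cfg.pbw_threshold_deg:
        return GlobalClass.MILD
    return GlobalClass.SEVERE


def _require_complete(profile: SegmentProfile) -> np.ndarray:
    phases = np.asarray(profile.mean_phase_deg, dtype=float)
    if phases.size != N_SEGMENTS or np.any(~np.isfinite(phases)):
        raise ValueError("segment profile incomplete: all 13 mean phases required")
    return phases


def segmental_phase_range(profile: SegmentProfile) -> float:
    """Circular spread of the 13 segment mean phases, in degrees.

    360 minus the largest gap between the sorted phases on the circle:
    the deviation between the earliest- and latest-contracting segment,
    independent of the phase origin.
    """
    return circular_range(_require_complete(profile))


def detect_block_lines(profile: SegmentProfile, block_delta_deg: float = 90.0) -> list:
    """Adjacent segment pairs separated by a large phase jump, grouped.

    Returns a list of "lines"; each line is a list of (segment, segment)
    pairs whose circular phase distance is >= ``block_delta_deg``, with
    pairs sharing a segment merged into one line.  Invariant to global
    phase rotation.
    """
    phases = _require_complete(profile)
    pairs = []
    for s, neigh in profile.adjacency.items():
        for t in neigh:
            if s < t and circular_distance(phases[s - 1], phases[t - 1]) >= block_delta_deg:
                pairs.append((s, t))
    # merge pairs sharing a segment into contiguous lines (union-find)
    parent = {p: p for p in pairs}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for i, p in enumerate(pairs):
        for q in pairs[i + 1:]:
            if set(p) & set(q):
                parent[find(p)] = find(q)
    lines = {}
    for p in pairs:
        lines.setdefault(find(p), []).append(p)
    return [sorted(v) for v in lines.values()]


def delayed_clusters(profile: SegmentProfile, delay_offset_deg: float = 45.0) -> list:
    """Connected groups of segments contracting late vs the mean phase.

    A segment is delayed when its signed circular offset from the
    (unweighted) circular mean of all 13 segment phases is at least
    ``delay_offset_deg``.  Delayed segments are grouped into connected
    components over the segment adjacency.
    """
    phases = _require_complete(profile)
    mu = circular_mean(phases)
    delayed = {s for s in range(1, N_SEGMENTS + 1)
               if circular_diff(phases[s - 1], mu) >= delay_offset_deg}
    clusters = []
    todo = set(delayed)
    while todo:
        seed = todo.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            s = stack.pop()
            for t in profile.adjacency[s]:
                if t in todo:
                    todo.discard(t)
                    comp.add(t)
                    stack.append(t)
        clusters.append(sorted(comp))
    return sorted(clusters)


def _septal_to_lateral_monotone(profile: SegmentProfile, tol_deg: float) -> bool:
    """Check monotone septum->lateral propagation in every ring band.

    Within each band the septal segment must be earliest (within tol),
    and the lateral segment latest, with anterior and inferior in
    between — phase offsets taken circularly relative to the septum.
    """
    phases = _require_complete(profile)
    for base in (2, 6, 10):  # apical, mid, basal bands: anterior, septal, inferior, lateral
        ant, sep, inf, lat = (phases[base - 1 + k] for k in range(4))
        r_ant = circular_diff(ant, sep)
        r_inf = circular_diff(inf, sep)
        r_lat = circular_diff(lat, sep)
        if r_ant < -tol_deg or r_inf < -tol_deg or r_lat < -tol_deg:
            return False
        if r_lat < max(r_ant, r_inf) - tol_deg:
            return False
    return True


def classify_pattern(
    idx: DyssynchronyIndices,
    profile: SegmentProfile,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> PatternResult:
    """Assign the four-way contraction-pattern label.

    Precedence: MILD (global rule) -> HETEROGENEOUS (two or more
    disjoint delayed territories) -> U_SHAPED (a block line with exactly
    one delayed territory) -> HOMOGENEOUS (monotone septum-to-lateral
    ramp, no block).  A severe study matching none of the subtype rules
    is labelled by the nearest rule and flagged, with a logged warning.
    All decisions are invariant to a global rotation of the phases.
    """
    phases = _require_complete(profile)
    rng_deg = circular_range(phases)
    blocks = detect_block_lines(profile, cfg.block_delta_deg)
    clusters = delayed_clusters(profile, cfg.delay_offset_deg)
    result = PatternResult(
        label=PatternLabel.MILD,
        block_lines=blocks,
        delayed_clusters=clusters,
        phase_range_deg=rng_deg,
    )
    if classify_global(idx, cfg) is GlobalClass.MILD:
        return result
    if len(clusters) >= 2:
        result.label = PatternLabel.HETEROGENEOUS
    elif blocks and len(clusters) == 1:
        result.label = PatternLabel.U_SHAPED
    elif not blocks and _septal_to_lateral_monotone(profile, cfg.monotone_tolerance_deg):
        result.label = PatternLabel.HOMOGENEOUS
    else:
        # no clean match: fall back to the closest severe subtype
        result.fallback = True
        if blocks:
            result.label = PatternLabel.U_SHAPED
        elif len(clusters) == 1:
            result.label = PatternLabel.HETEROGENEOUS
        else:
            result.label = PatternLabel.HOMOGENEOUS
        logger.warning(
            "severe pattern matched no subtype rule cleanly; labelled %s "
            "(blocks=%d, clusters=%d, range=%.1f deg)",
            result.label.value, len(blocks), len(clusters), rng_deg,
        )
    return result
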