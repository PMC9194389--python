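"""Perfusion quantification, scar burden, and the 13-segment model.

Tracer uptake per sample is summarised over the cardiac cycle and
normalised so the brightest sample reads 100%.  A sample below 50% of
the maximum uptake counts as myocardial scar; scar burden is the
percentage of scarred samples over the whole left ventricle.

The polar map is divided into 13 segments: a single apical bullseye
plus apical, mid and basal ring bands each split into four 90-degree
sectors (anterior, septal, inferior, lateral).  Segment-level circular
mean phases and scar percentages feed the contraction-pattern
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import circular_mean
from .phase import GatedPolarSamples, PhaseMap, PolarGeometry

SECTOR_NAMES = ("anterior", "septal", "inferior", "lateral")
BAND_NAMES = ("apical", "mid", "basal")
N_SEGMENTS = 13

#: scar definition: uptake below this percentage of the myocardial maximum
DEFAULT_SCAR_THRESHOLD_PCT = 50.0


@dataclass
class PerfusionMap:
    """Cycle-summed tracer uptake on the polar grid, raw and % of max."""

    geometry: PolarGeometry
    uptake: np.ndarray      # (n_rings, n_angles), >= 0
    uptake_pct: np.ndarray  # normalised so max = 100 when any uptake > 0


@dataclass
class ScarResult:
    """Scar mask (uptake below threshold) and global scar burden."""

    scar_mask: np.ndarray  # (n_rings, n_angles) bool
    scar_burden_pct: float
    threshold_pct: float = DEFAULT_SCAR_THRESHOLD_PCT


@dataclass
class SegmentMap:
    """Assignment of every polar sample to one of the 13 segments.

    ``labels`` holds segment ids 1..13 per (ring, angle); ``adjacency``
    maps each segment id to the ids of its neighbours (symmetric).
    Segment 1 is the apex; ids 2-5, 6-9, 10-13 are the apical, mid and
    basal bands in sector order anterior, septal, inferior, lateral.
    """

    geometry: PolarGeometry
    labels: np.ndarray  # (n_rings, n_angles) int, values 1..13
    adjacency: dict


@dataclass
class SegmentProfile:
    """Per-segment circular-mean phase, scar percentage and sample count."""

    mean_phase_deg: np.ndarray  # length 13, NaN where no valid phase
    scar_pct: np.ndarray        # length 13
    sample_count: np.ndarray    # length 13, int
    adjacency: dict

    @property
    def segment_ids(self) -> np.ndarray:
        return np.arange(1, N_SEGMENTS + 1)


def perfusion_map(gated: GatedPolarSamples) -> PerfusionMap:
    """Sum counts over frames and normalise to the maximum sample.

    The ungated sum is the standard surrogate for a resting perfusion
    scan when only the gated acquisition is available.
    """
    uptake = gated.counts.sum(axis=-1)
    peak = uptake.max()
    pct = 100.0 * uptake / peak if peak > 0 else np.zeros_like(uptake)
    return PerfusionMap(geometry=gated.geometry, uptake=uptake, uptake_pct=pct)


def scar_mask(perf: PerfusionMap, threshold_pct: float = DEFAULT_SCAR_THRESHOLD_PCT) -> ScarResult:
    """Mark scar as samples strictly below ``threshold_pct`` of max uptake."""
    if perf.uptake.max() <= 0:
        raise ValueError("scar mask undefined for an all-zero perfusion map")
    mask = perf.uptake_pct < threshold_pct
    burden = 100.0 * mask.mean()
    return ScarResult(scar_mask=mask, scar_burden_pct=float(burden), threshold_pct=threshold_pct)


def assign_segments(geometry: PolarGeometry) -> SegmentMap:
    """Partition the polar grid into the 13-segment model.

    The innermost quarter of the rings (at least one) forms the apex
    segment; the remaining rings are split into three near-equal bands
    (apical, mid, basal, apex-to-base), each divided into four equal
    90-degree sectors starting with the anterior wall at angle index 0.
    Fewer than four rings leave the basal band empty: its segments then
    carry zero samples (the full 13-segment model needs n_rings >= 4).
    """
    r, a = geometry.n_rings, geometry.n_angles
    n_apex = max(1, r // 4)
    rest = np.arange(n_apex, r)
    bands = np.array_split(rest, 3)  # apical, mid, basal
    band_of_ring = np.full(r, -1, dtype=int)  # -1 = apex
    for b, rings in enumerate(bands):
        band_of_ring[rings] = b
    sector = (np.arange(a) * 4) // a  # 0 anterior, 1 septal, 2 inferior, 3 lateral
    labels = np.empty((r, a), dtype=int)
    for ring in range(r):
        if band_of_ring[ring] < 0:
            labels[ring, :] = 1
        else:
            labels[ring, :] = 2 + 4 * band_of_ring[ring] + sector
    adjacency = {s: set() for s in range(1, N_SEGMENTS + 1)}

    def link(i, j):
        adjacency[i].add(j)
        adjacency[j].add(i)

    for s in range(2, 6):  # apex touches every apical segment
        link(1, s)
    for b in range(3):  # circumferential neighbours within a band
        base = 2 + 4 * b
        for s in range(4):
            link(base + s, base + (s + 1) % 4)
    for b in range(2):  # radial neighbours, same sector
        for s in range(4):
            link(2 + 4 * b + s, 2 + 4 * (b + 1) + s)
    return SegmentMap(geometry=geometry, labels=labels,
                      adjacency={k: sorted(v) for k, v in adjacency.items()})


def segment_summary(phase: PhaseMap, scar: ScarResult, segmap: SegmentMap) -> SegmentProfile:
    """Per-segment circular mean of valid phases and scar percentage."""
    if phase.phase_deg.shape != segmap.labels.shape:
        raise ValueError("phase map and segment map geometries differ")
    if scar.scar_mask.shape != segmap.labels.shape:
        raise ValueError("scar mask and segment map geometries differ")
    mean_phase = np.full(N_SEGMENTS, np.nan)
    scar_pct = np.zeros(N_SEGMENTS)
    n_samples = np.zeros(N_SEGMENTS, dtype=int)
    for s in range(1, N_SEGMENTS + 1):
        sel = segmap.labels == s
        n_samples[s - 1] = int(sel.sum())
        scar_pct[s - 1] = 100.0 * scar.scar_mask[sel].mean() if sel.any() else np.nan
        valid = sel & phase.valid_mask
        if valid.any():
            mean_phase[s - 1] = circular_mean(phase.phase_deg[valid])
    return SegmentProfile(
        mean_phase_deg=mean_phase,
        scar_pct=scar_pct,
        sample_count=n_samples,
        adjacency=segmap.adjacency,
    )
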