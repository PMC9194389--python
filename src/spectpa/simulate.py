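"""Synthetic gated-SPECT cohort generation.

Builds fully synthetic patients — true contraction-onset phase fields
for the four pattern archetypes, Poisson-noised gated polar-map counts,
scar fields, echo trajectories and outcomes — with the group-level
statistical structure the analysis assumes, so every pipeline stage is
testable without real data.

Archetype phase fields are constructed as ``base + s * g`` where ``g``
is a fixed zero-mean unit-shaped pattern per archetype (wrapped-normal
jitter for the mild pattern; a blocked late territory wrapping via the
apex for the U-shape; two or more disjoint late patches for the
heterogeneous pattern; a monotone septum-to-lateral ramp for the
homogeneous one) and the dispersion scale ``s`` is calibrated by
bisection so the noiseless field hits a target phase standard
deviation.  Default targets are the per-group medians of the source
cohort; group sizes, super-response probabilities, event probabilities
and echo distributions likewise default to the printed group-level
values.

Echo trajectories are generated to satisfy the response definitions
exactly rather than modelled biophysically — downstream analysis only
consumes labels and deltas.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .patterns import ClassifierConfig, PatternLabel, classify_global
from .phase import (
    DyssynchronyIndices,
    GatedPolarSamples,
    PolarGeometry,
    indices_of_phases,
)
from .perfusion import assign_segments
from .stats import PatientRecord

GROUP_ORDER = (
    PatternLabel.MILD,
    PatternLabel.U_SHAPED,
    PatternLabel.HETEROGENEOUS,
    PatternLabel.HOMOGENEOUS,
)

#: per-group study conditions: medians (q1, q3) for skewed variables,
#: mean/sd for symmetric ones, probabilities for flags
DEFAULT_GROUP_STATS = {
    PatternLabel.MILD: dict(
        psd=(23.06, 17.24, 26.6), pbw=(70.5, 58.25, 83.75),
        scar=(24.29, 16.92, 36.95), lvef=(30.2, 25.4, 31.98),
        lvedd=(68.0, 63.3, 72.8), lvedd_6mo=(56.5, 9.38),
        age=(65.22, 11.19), male_p=25 / 32, v5v6_p=7 / 32,
        nyha_p=(11 / 32, 17 / 32, 4 / 32), qrsd=(175.0, 160.5, 187.5),
    ),
    PatternLabel.U_SHAPED: dict(
        psd=(52.98, 47.95, 56.92), pbw=(188.0, 154.5, 225.0),
        scar=(27.26, 23.19, 32.67), lvef=(29.2, 24.3, 31.75),
        lvedd=(72.0, 67.0, 77.5), lvedd_6mo=(57.82, 8.29),
        age=(68.35, 11.06), male_p=12 / 17, v5v6_p=2 / 17,
        nyha_p=(2 / 17, 9 / 17, 6 / 17), qrsd=(172.0, 160.0, 188.5),
    ),
    PatternLabel.HETEROGENEOUS: dict(
        psd=(64.64, 57.97, 74.45), pbw=(241.0, 209.0, 279.0),
        scar=(37.07, 30.09, 43.55), lvef=(23.5, 20.2, 27.6),
        lvedd=(82.0, 71.0, 88.0), lvedd_6mo=(73.84, 16.26),
        age=(66.95, 11.86), male_p=15 / 19, v5v6_p=6 / 19,
        nyha_p=(6 / 19, 11 / 19, 2 / 19), qrsd=(180.0, 170.0, 188.0),
    ),
    PatternLabel.HOMOGENEOUS: dict(
        psd=(46.25, 40.77, 61.93), pbw=(164.0, 131.5, 208.25),
        scar=(38.82, 29.75, 48.66), lvef=(25.2, 22.48, 30.4),
        lvedd=(78.5, 68.25, 83.5), lvedd_6mo=(76.5, 10.0),
        age=(61.83, 8.23), male_p=3 / 6, v5v6_p=4 / 6,
        nyha_p=(2 / 6, 3 / 6, 1 / 6), qrsd=(173.5, 165.0, 193.0),
    ),
}

_Z75 = 0.6744897501960817  # 75th normal percentile, for IQR -> lognormal sigma


@dataclass
class ArchetypeSpec:
    """Recipe for one contraction-pattern phase field."""

    pattern: PatternLabel
    target_psd_deg: float
    target_pbw_deg: float = float("nan")  # informational; PSD drives calibration
    block_sector: int = 0          # 0 anterior, 1 septal, 2 inferior, 3 lateral
    n_delay_patches: int = 2
    gradient_direction: int = 1    # homogeneous ramp: septum -> lateral
    scar_fraction: float = 0.0
    a1_ratio: float = 0.3          # first-harmonic amplitude / mean counts
    jitter: float = 0.12           # within-territory spread, unit-field scale
    base_phase_deg: float = 140.0
    dispersion_scale: Optional[float] = None  # set by calibrate_dispersion

    def __post_init__(self):
        if not 0.0 <= self.target_psd_deg <= 104.0:
            raise ValueError("target_psd_deg must lie in [0, 104]")
        if not 0.0 <= self.scar_fraction < 1.0:
            raise ValueError("scar_fraction must lie in [0, 1)")


def default_archetype(pattern: PatternLabel, **overrides) -> ArchetypeSpec:
    """Archetype with group-median targets of the source cohort."""
    g = DEFAULT_GROUP_STATS[pattern]
    spec = ArchetypeSpec(
        pattern=pattern,
        target_psd_deg=g["psd"][0],
        target_pbw_deg=g["pbw"][0],
        scar_fraction=g["scar"][0] / 100.0,
    )
    return dataclasses.replace(spec, **overrides) if overrides else spec


@dataclass
class CohortConfig:
    """Group sizes and outcome probabilities of the simulated cohort."""

    group_sizes: tuple = (32, 17, 19, 6)
    super_response_p: tuple = (0.656, 0.706, 0.158, 0.333)
    event_p: tuple = (0.156, 0.059, 0.526, 0.50)
    mean_followup_months: float = 37.48

    def __post_init__(self):
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        for probs in (self.super_response_p, self.event_p):
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# phase-field archetypes


def _unit_field(spec: ArchetypeSpec, geometry: PolarGeometry, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-shaped pattern g; the field is base + s * g."""
    r, a = geometry.n_rings, geometry.n_angles
    n_apex = max(1, r // 4)
    sector = (np.arange(a) * 4) // a
    g = spec.jitter * rng.standard_normal((r, a))
    if spec.pattern is PatternLabel.MILD:
        # pure wrapped-normal spread around the base phase
        g = rng.standard_normal((r, a))
    elif spec.pattern is PatternLabel.U_SHAPED:
        # one late territory behind a line of block; the apex sits at an
        # intermediate phase so propagation wraps around it
        late = np.zeros((r, a))
        late[n_apex:, sector == spec.block_sector % 4] = 1.0
        late[:n_apex, :] = 0.35
        g = g + late
    elif spec.pattern is PatternLabel.HETEROGENEOUS:
        # >= 2 disjoint late patches (sector wedges over ring spans)
        segmap = assign_segments(geometry).labels
        patch_segments = ([2, 6], [8, 12], [13], [3])  # pairwise non-adjacent groups
        offsets = (0.85, 0.6, 0.7, 0.65)
        for patch, off in zip(patch_segments[: max(2, spec.n_delay_patches)], offsets):
            g = g + off * np.isin(segmap, patch)
    elif spec.pattern is PatternLabel.HOMOGENEOUS:
        # monotone circular ramp from the septal centre to the lateral wall
        g = 0.4 * spec.jitter * rng.standard_normal((r, a))
        angle_deg = np.arange(a) * 360.0 / a
        septal_center = 360.0 * 1.5 / 4
        dist = np.abs((angle_deg - septal_center + 180.0) % 360.0 - 180.0) / 180.0
        g = g + spec.gradient_direction * np.broadcast_to(dist, (r, a))
    else:  # pragma: no cover
        raise ValueError(f"unknown pattern {spec.pattern}")
    return g - g.mean()


def _field_psd(base_deg: float, scale: float, g: np.ndarray) -> float:
    return indices_of_phases((base_deg + scale * g) % 360.0).psd_deg


def calibrate_dispersion(
    spec: ArchetypeSpec,
    geometry: PolarGeometry,
    seed: int,
    tolerance_deg: float = 2.0,
) -> tuple[ArchetypeSpec, DyssynchronyIndices]:
    """Bisect the dispersion scale until the noiseless field hits the
    target PSD.

    Returns the spec with ``dispersion_scale`` set, together with the
    achieved (PSD, PBW) of the noiseless field.  A non-positive target
    is rejected.
    """
    if spec.target_psd_deg <= 0:
        raise ValueError("target PSD must be positive")
    rng = np.random.default_rng(seed)
    g = _unit_field(spec, geometry, rng)
    # PSD grows linearly in the scale only until phases wrap around the
    # cycle; bracket the FIRST crossing with a gradual scan so the
    # bisection cannot land on a spurious wrapped solution
    lo, hi = 0.0, 2.0
    while _field_psd(spec.base_phase_deg, hi, g) < spec.target_psd_deg and hi < 2048:
        lo = hi
        hi *= 1.2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _field_psd(spec.base_phase_deg, mid, g) < spec.target_psd_deg:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    achieved = indices_of_phases((spec.base_phase_deg + scale * g) % 360.0)
    if abs(achieved.psd_deg - spec.target_psd_deg) > tolerance_deg:
        raise RuntimeError(
            f"dispersion calibration missed target "
            f"({achieved.psd_deg:.2f} vs {spec.target_psd_deg:.2f} deg)"
        )
    return dataclasses.replace(spec, dispersion_scale=scale), achieved


def gen_phase_field(spec: ArchetypeSpec, geometry: PolarGeometry, seed: int) -> np.ndarray:
    """True contraction-onset phases (degrees, (rings, angles)) for an
    archetype.

    Deterministic in (spec, geometry, seed).  If ``dispersion_scale``
    is unset the field is calibrated first (same seed, hence the same
    underlying pattern).
    """
    if spec.dispersion_scale is None:
        spec, _ = calibrate_dispersion(spec, geometry, seed)
    rng = np.random.default_rng(seed)
    g = _unit_field(spec, geometry, rng)
    return (spec.base_phase_deg + spec.dispersion_scale * g) % 360.0


def gen_scar_field(geometry: PolarGeometry, fraction: float, seed: int) -> np.ndarray:
    """Contiguous scar region grown from a random seed sample.

    Breadth-first growth on the polar grid (angles wrap) until
    ``round(fraction * n_samples)`` samples are scarred.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("scar fraction must lie in [0, 1)")
    r, a = geometry.n_rings, geometry.n_angles
    mask = np.zeros((r, a), dtype=bool)
    n_target = int(round(fraction * r * a))
    if n_target == 0:
        return mask
    rng = np.random.default_rng(seed)
    start = (int(rng.integers(r)), int(rng.integers(a)))
    frontier = [start]
    mask[start] = True
    n = 1
    while n < n_target and frontier:
        idx = int(rng.integers(len(frontier)))
        ri, ai = frontier.pop(idx)
        neighbours = [(ri - 1, ai), (ri + 1, ai), (ri, (ai - 1) % a), (ri, (ai + 1) % a)]
        rng.shuffle(neighbours)
        for nr, na in neighbours:
            if 0 <= nr < r and not mask[nr, na]:
                mask[nr, na] = True
                frontier.append((nr, na))
                n += 1
                if n >= n_target:
                    break
    return mask


def gen_gated_counts(
    phase_field: np.ndarray,
    scar_field: Optional[np.ndarray],
    a0: float = 100.0,
    a1_ratio: float = 0.3,
    n_frames: int = 8,
    seed: Optional[int] = None,
    noise: bool = True,
    scar_uptake: float = 0.4,
    scar_a1_factor: float = 0.25,
) -> GatedPolarSamples:
    """Forward model: harmonic count modulation + Poisson noise.

    Per sample the expected frame counts are
    ``a0 * uptake * (1 + a1_ratio_eff * cos(2*pi*k/N - theta))`` with
    ``theta`` placed so the rising mean-crossing of the harmonic sits at
    the sample's true phase.  Scar samples get ``scar_uptake`` of the
    normal uptake and a ``scar_a1_factor``-reduced relative amplitude
    (scar thickens far less than viable myocardium).  ``a0`` is the
    cycle-mean count level of a healthy sample; polar-map samples
    aggregate many reconstructed voxels, so the default elsewhere in
    this package is on the order of 10^3 counts.  With ``noise=False``
    the expected counts are returned, so the phase analysis inverts the
    model exactly.
    """
    phase_field = np.asarray(phase_field, dtype=float)
    r, a = phase_field.shape
    geometry = PolarGeometry(n_rings=r, n_angles=a, n_frames=n_frames)
    if scar_field is None:
        scar_field = np.zeros((r, a), dtype=bool)
    scar_field = np.asarray(scar_field, dtype=bool)
    if scar_field.shape != (r, a):
        raise ValueError("scar field shape inconsistent with phase field")
    uptake = np.where(scar_field, scar_uptake, 1.0)
    rel_amp = a1_ratio * np.where(scar_field, scar_a1_factor, 1.0)
    if np.any(rel_amp >= 1.0):
        raise ValueError("a1_ratio must be < 1 to keep expected counts positive")
    theta = np.deg2rad(phase_field - 270.0)  # onset = theta + 270 deg
    k = np.arange(n_frames)
    w = 2.0 * np.pi * k / n_frames
    mean = (a0 * uptake)[..., None] * (
        1.0 + rel_amp[..., None] * np.cos(w[None, None, :] - theta[..., None])
    )
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(mean).astype(float)
    else:
        counts = mean
    return GatedPolarSamples(geometry=geometry, counts=counts)


# ---------------------------------------------------------------------------
# cohort generation


def _lognormal_from_median_iqr(rng, median, q1, q3, size=None):
    mu = np.log(median)
    sigma = (np.log(q3) - np.log(q1)) / (2.0 * _Z75)
    return np.exp(rng.normal(mu, sigma, size=size))


def _draw_indices(rng, stats, pattern, cfg_cls: ClassifierConfig, max_tries=1000):
    """Draw (psd, pbw) from the group distribution, consistent with the
    group's mild/severe side of the global rule."""
    want_mild = pattern is PatternLabel.MILD
    for _ in range(max_tries):
        psd = float(_lognormal_from_median_iqr(rng, *stats["psd"]))
        pbw = float(_lognormal_from_median_iqr(rng, *stats["pbw"]))
        if psd >= 104.0 or pbw > 360.0:
            continue
        idx = DyssynchronyIndices(psd_deg=psd, pbw_deg=pbw)
        is_mild = classify_global(idx, cfg_cls).value == "MILD"
        if is_mild == want_mild:
            return psd, pbw
    raise RuntimeError("could not draw label-consistent (PSD, PBW)")


def gen_labelled_field(
    pattern: PatternLabel,
    target_psd_deg: float,
    geometry: PolarGeometry,
    seed: int,
    scar_fraction: float = 0.0,
    classifier_cfg: ClassifierConfig = ClassifierConfig(),
    mild_margin: float = 0.85,
    max_attempts: int = 10,
) -> tuple[ArchetypeSpec, np.ndarray]:
    """Archetype field guaranteed to sit on its label's side of the
    mild/severe rule.

    The field is calibrated to ``target_psd_deg``; if its noiseless
    (PSD, PBW) land on the wrong side of the global thresholds the
    target is shrunk (mild) or grown (severe) and recalibrated.  Mild
    fields are required to sit inside both thresholds with a margin
    (default 15%), since the wrapped-normal archetype ties PBW to
    roughly 3.9 * PSD and a borderline field would not be a clean
    exemplar of its label.
    """
    from .patterns import classify_pattern
    from .perfusion import N_SEGMENTS, assign_segments, SegmentProfile
    from .circular import circular_mean

    def _noiseless_label(field, idx):
        # segment profile of the noiseless field (no scar, all valid)
        segmap = assign_segments(geometry)
        means = np.array([circular_mean(field[segmap.labels == s])
                          for s in range(1, N_SEGMENTS + 1)])
        counts = np.array([(segmap.labels == s).sum() for s in range(1, N_SEGMENTS + 1)])
        profile = SegmentProfile(mean_phase_deg=means, scar_pct=np.zeros(N_SEGMENTS),
                                 sample_count=counts, adjacency=segmap.adjacency)
        return classify_pattern(idx, profile, strict_cfg)

    # margin config: exemplars must classify correctly even with the
    # decisive thresholds moved against them, so Poisson noise cannot
    # push them across a decision boundary
    c = classifier_cfg
    if pattern is PatternLabel.U_SHAPED:
        strict_cfg = dataclasses.replace(c, block_delta_deg=1.25 * c.block_delta_deg)
    elif pattern is PatternLabel.HETEROGENEOUS:
        strict_cfg = dataclasses.replace(c, delay_offset_deg=1.2 * c.delay_offset_deg)
    elif pattern is PatternLabel.HOMOGENEOUS:
        strict_cfg = dataclasses.replace(c, block_delta_deg=0.8 * c.block_delta_deg)
    else:
        strict_cfg = c

    # each severe archetype shape supports only a limited dispersion
    # before phases wrap around the cycle and the spatial structure
    # scrambles; targets are clipped to the shape's usable ceiling
    ceiling = {PatternLabel.U_SHAPED: 88.0, PatternLabel.HETEROGENEOUS: 78.0}
    cap = ceiling.get(pattern, 100.0)
    spec = default_archetype(pattern, target_psd_deg=min(target_psd_deg, cap),
                             scar_fraction=scar_fraction)
    for _ in range(max_attempts):
        spec_cal, achieved = calibrate_dispersion(spec, geometry, seed)
        if pattern is PatternLabel.MILD:
            ok = (achieved.psd_deg <= mild_margin * c.psd_threshold_deg
                  and achieved.pbw_deg <= mild_margin * c.pbw_threshold_deg)
            factor = 0.85
        else:
            severe = (achieved.psd_deg > c.psd_threshold_deg
                      or achieved.pbw_deg > c.pbw_threshold_deg)
            if not severe:
                ok, factor = False, 1.15
            else:
                field = gen_phase_field(spec_cal, geometry, seed)
                ok = _noiseless_label(field, achieved).label is pattern
                # too much dispersion turns a homogeneous ramp into a
                # blocked field; too little starves U/heterogeneous contrast
                factor = 0.9 if pattern is PatternLabel.HOMOGENEOUS else 1.15
        if ok:
            return spec_cal, gen_phase_field(spec_cal, geometry, seed)
        spec = dataclasses.replace(spec, target_psd_deg=min(spec.target_psd_deg * factor, cap))
    raise RuntimeError(f"could not generate a label-consistent {pattern.value} field")


def _draw_lvef_6mo(rng, base: float, super_flag: bool) -> float:
    """Follow-up LVEF satisfying (or failing) the super-response rule."""
    if super_flag:
        if rng.random() < 0.5:
            return float(min(50.0 + abs(rng.normal(0.0, 6.0)), 75.0))
        return float(min(base + 15.5 + rng.exponential(5.0), 75.0))
    lvef = base + rng.uniform(-3.0, 15.0)
    return float(min(lvef, 49.5))


def gen_cohort(
    cfg: CohortConfig,
    seed: int,
    with_images: bool = False,
    geometry: PolarGeometry = PolarGeometry(10, 36, 8),
    classifier_cfg: ClassifierConfig = ClassifierConfig(),
    a0: float = 1000.0,
    image_noise: bool = True,
):
    """Generate a synthetic cohort, optionally with gated images.

    Returns ``(records, images)``: a list of PatientRecord whose
    ``pattern`` holds the generating (true) label, and — when
    ``with_images`` — a dict ``id -> {"gated", "true_phase", "scar"}``
    of per-patient Poisson-noised gated polar maps whose noiseless
    phase field was calibrated to the patient's drawn PSD.

    Group-conditional draws follow the study conditions: skewed
    baseline variables (LVEF, LVEDD, QRSd, scar burden, PSD, PBW) are
    log-normal matched to the printed median/IQR; age is normal;
    binary covariates are Bernoulli at the printed group rates;
    super-response and event flags are Bernoulli at the group
    probabilities; follow-up times are exponential at the printed mean.
    Follow-up LVEF is constructed to satisfy the drawn super-response
    label exactly.  Fully deterministic in (cfg, seed).
    """
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    images: dict = {}
    pid = 0
    for gi, pattern in enumerate(GROUP_ORDER):
        stats = DEFAULT_GROUP_STATS[pattern]
        for _ in range(cfg.group_sizes[gi]):
            pid += 1
            patient_id = f"P{pid:03d}"
            psd, pbw = _draw_indices(rng, stats, pattern, classifier_cfg)
            scar = float(np.clip(_lognormal_from_median_iqr(rng, *stats["scar"]), 0.0, 80.0))
            lvef_base = float(np.clip(_lognormal_from_median_iqr(rng, *stats["lvef"]), 10.0, 35.0))
            super_flag = bool(rng.random() < cfg.super_response_p[gi])
            lvef_6mo = _draw_lvef_6mo(rng, lvef_base, super_flag)
            lvedd_base = float(np.clip(_lognormal_from_median_iqr(rng, *stats["lvedd"]), 45.0, 110.0))
            lvedd_6mo = float(np.clip(rng.normal(*stats["lvedd_6mo"]), 40.0, 110.0))
            age = float(np.clip(rng.normal(*stats["age"]), 18.0, 95.0))
            nyha = int(rng.choice([2, 3, 4], p=stats["nyha_p"]))
            qrsd = float(_lognormal_from_median_iqr(rng, *stats["qrsd"]))
            event = bool(rng.random() < cfg.event_p[gi])
            followup = float(rng.exponential(cfg.mean_followup_months))
            records.append(PatientRecord(
                id=patient_id, pattern=pattern, psd_deg=psd, pbw_deg=pbw,
                scar_burden_pct=scar, lvef_baseline_pct=lvef_base,
                lvef_6mo_pct=lvef_6mo, lvedd_baseline_mm=lvedd_base,
                lvedd_6mo_mm=lvedd_6mo, age_yr=age,
                male=bool(rng.random() < stats["male_p"]),
                v5v6_s=bool(rng.random() < stats["v5v6_p"]),
                nyha=nyha, qrsd_ms=qrsd, followup_months=followup, event=event,
            ))
            if with_images:
                img_seed = int(rng.integers(2**30))
                spec, true_phase = gen_labelled_field(
                    pattern, psd, geometry, img_seed,
                    scar_fraction=scar / 100.0, classifier_cfg=classifier_cfg)
                scar_field = gen_scar_field(geometry, spec.scar_fraction, img_seed + 1)
                gated = gen_gated_counts(true_phase, scar_field, a0=a0,
                                         a1_ratio=spec.a1_ratio,
                                         n_frames=geometry.n_frames, seed=img_seed + 2,
                                         noise=image_noise)
                images[patient_id] = {
                    "gated": gated, "true_phase": true_phase, "scar": scar_field,
                    "true_pattern": pattern,
                }
    return records, images
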