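"""First-harmonic phase extraction and global dyssynchrony indices.

Each myocardial sample of a gated polar map carries a count curve over
the cardiac cycle.  Counts rise during systole (partial-volume effect of
wall thickening), so the first Fourier harmonic of the curve encodes the
timing of regional contraction.  The phase assigned to a sample is the
cycle position, in degrees, at which the fitted harmonic crosses its
mean level while rising — the onset of mechanical contraction.

The global dyssynchrony indices derived from the phase distribution are

* PSD — phase standard deviation: the circular standard deviation of
  the phase histogram (histogram rotated so its circular mean sits at
  180 degrees, then the linear weighted SD of bin centres), and
* PBW — phase histogram bandwidth: the width of the smallest contiguous
  circular window of histogram bins holding at least 95% of samples.

Both are invariant to a global rotation of all phases, so the onset
convention above does not affect them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .circular import circular_diff, circular_mean, wrap360

logger = logging.getLogger(__name__)

#: default fraction of the mean below which the harmonic amplitude is
#: considered noise and the sample's phase is masked out
DEFAULT_AMPLITUDE_FLOOR = 0.02


@dataclass(frozen=True)
class PolarGeometry:
    """Sampling grid of a gated polar map.

    Attributes
    ----------
    n_rings : int
        Apex-to-base rings (ring 0 = apex).
    n_angles : int
        Circumferential samples per ring; angle index 0 is the anterior
        wall, increasing anterior -> septal -> inferior -> lateral as
        viewed from the apex.  Must be divisible by 4 (quadrant sectors).
    n_frames : int
        Gates per R-R cycle (8-bin gating by default elsewhere).
    """

    n_rings: int
    n_angles: int
    n_frames: int

    def __post_init__(self):
        if self.n_rings < 3:
            raise ValueError("n_rings must be >= 3")
        if self.n_angles < 8 or self.n_angles % 4 != 0:
            raise ValueError("n_angles must be >= 8 and divisible by 4")
        if self.n_frames < 4:
            raise ValueError("n_frames must be >= 4")

    @property
    def n_samples(self) -> int:
        return self.n_rings * self.n_angles


@dataclass
class GatedPolarSamples:
    """Per-sample count curves over the cardiac cycle on a polar grid."""

    geometry: PolarGeometry
    counts: np.ndarray  # (n_rings, n_angles, n_frames), non-negative

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        g = self.geometry
        if self.counts.shape != (g.n_rings, g.n_angles, g.n_frames):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with geometry "
                f"({g.n_rings}, {g.n_angles}, {g.n_frames})"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class HarmonicFit:
    """Least-squares first-harmonic fit of one count curve.

    ``a0`` is the mean count level, ``a1 >= 0`` the first-harmonic
    amplitude, ``phase_deg`` the contraction onset (rising mean-crossing
    of the fitted harmonic) in [0, 360).  ``valid`` is False when the
    amplitude falls below the floor (flat, non-contracting curve); the
    phase is then meaningless and reported as NaN where undefined.
    """

    a0: float
    a1: float
    phase_deg: float
    valid: bool


@dataclass
class PhaseMap:
    """Contraction-onset phases on the polar grid with a validity mask."""

    geometry: PolarGeometry
    phase_deg: np.ndarray  # (n_rings, n_angles), degrees in [0, 360)
    valid_mask: np.ndarray  # (n_rings, n_angles) bool

    def valid_phases(self) -> np.ndarray:
        """1-D array of phases of valid samples."""
        return self.phase_deg[self.valid_mask]


@dataclass
class PhaseHistogram:
    """Histogram of valid sample phases over the 360-degree cycle."""

    bin_width_deg: float
    counts: np.ndarray  # length 360 / bin_width_deg
    empty: bool = field(default=False)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_deg

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class DyssynchronyIndices:
    """The global dyssynchrony pair (PSD, PBW), both in degrees."""

    psd_deg: float
    pbw_deg: float


@dataclass
class ThickeningSummary:
    """Per-sample wall thickening (%) and its summary over a mask.

    Thickening of a sample is the cyclic fractional count change
    100 * (max_k c_k - min_k c_k) / min_k c_k; the summary is the median
    over masked-in samples with a positive minimum count.
    """

    per_sample_pct: np.ndarray  # (n_rings, n_angles); NaN where excluded
    summary_pct: float


# ---------------------------------------------------------------------------
# first-harmonic fitting


def _harmonic_components(counts: np.ndarray):
    """Vectorized LS fit of a0 + a1*cos(2*pi*k/N - theta) along the last axis.

    With uniform sampling of a full cycle the least-squares solution is
    the discrete Fourier coefficient at frequency 1: a0 is the mean and
    (a1, theta) come from the quadrature sums.
    """
    n = counts.shape[-1]
    k = np.arange(n)
    w = 2.0 * np.pi * k / n
    a0 = counts.mean(axis=-1)
    x = 2.0 * (counts * np.cos(w)).mean(axis=-1)  # a1 cos(theta)
    y = 2.0 * (counts * np.sin(w)).mean(axis=-1)  # a1 sin(theta)
    a1 = np.hypot(x, y)
    theta_deg = np.rad2deg(np.arctan2(y, x))
    # onset = rising crossing of the mean level: cos(t - theta) = 0 with
    # positive slope of the count curve, i.e. t = theta + 270 (mod 360)
    phase_deg = wrap360(theta_deg + 270.0)
    return a0, a1, phase_deg


def fit_first_harmonic(curve, amplitude_floor: float = DEFAULT_AMPLITUDE_FLOOR) -> HarmonicFit:
    """Fit the first Fourier harmonic to one gated count curve.

    Parameters
    ----------
    curve : array-like
        Counts per frame, length >= 4, finite and non-negative.
    amplitude_floor : float
        Fraction of ``a0`` below which the fitted amplitude is treated
        as noise; such samples are flagged invalid.

    Returns
    -------
    HarmonicFit
        ``phase_deg`` is the rising mean-crossing of the fitted harmonic
        (contraction onset), mapped to [0, 360); NaN when the amplitude
        is exactly zero (flat curve).
    """
    c = np.asarray(curve, dtype=float)
    if c.ndim != 1 or c.size < 4:
        raise ValueError("curve must be 1-D with at least 4 frames")
    if not np.all(np.isfinite(c)):
        raise ValueError("curve contains non-finite values")
    if np.any(c < 0):
        raise ValueError("curve contains negative counts")
    a0, a1, phase = _harmonic_components(c)
    a0, a1, phase = float(a0), float(a1), float(phase)
    if a1 <= 1e-12 * max(a0, 1.0):  # numerically flat curve
        a1, phase = 0.0, float("nan")
    valid = a0 > 0 and a1 >= amplitude_floor * a0 and a1 > 0
    return HarmonicFit(a0=a0, a1=a1, phase_deg=phase, valid=valid)


def compute_phase_map(
    gated: GatedPolarSamples, amplitude_floor: float = DEFAULT_AMPLITUDE_FLOOR
) -> PhaseMap:
    """Fit every sample's count curve and assemble the phase polar map.

    Samples whose first-harmonic amplitude falls below
    ``amplitude_floor * a0`` (or with zero mean counts) are masked out.
    A warning is logged when more than half of the samples are invalid;
    the map is still returned.
    """
    a0, a1, phase = _harmonic_components(gated.counts)
    valid = (a0 > 0) & (a1 >= amplitude_floor * a0)
    phase = np.where(a1 > 0, phase, np.nan)
    frac_invalid = 1.0 - valid.mean()
    if frac_invalid > 0.5:
        logger.warning(
            "phase map: %.0f%% of samples invalid (flat or low-amplitude curves)",
            100 * frac_invalid,
        )
    return PhaseMap(geometry=gated.geometry, phase_deg=phase, valid_mask=valid)


# ---------------------------------------------------------------------------
# histogram and indices


def phase_histogram(pmap: PhaseMap, bin_width_deg: float = 1.0) -> PhaseHistogram:
    """Histogram the valid phases into circular bins of ``bin_width_deg``.

    The bin width must divide 360.  The bin total always equals the
    number of valid samples; an all-invalid map yields an all-zero
    histogram with the ``empty`` flag set.
    """
    n_bins = 360.0 / bin_width_deg
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width_deg must divide 360")
    n_bins = int(round(n_bins))
    phases = pmap.valid_phases() % 360.0
    counts = np.histogram(phases, bins=n_bins, range=(0.0, 360.0))[0].astype(float)
    return PhaseHistogram(bin_width_deg=bin_width_deg, counts=counts, empty=phases.size == 0)


def compute_psd(hist: PhaseHistogram) -> float:
    """Phase standard deviation (degrees) of a phase histogram.

    The histogram is rotated so that its circular mean sits at 180
    degrees and the linear weighted standard deviation of the bin
    centres is taken — equivalently, the root weighted mean square of
    circular deviations from the circular mean.  Invariant to any
    global rotation of the phases; at most 360/sqrt(12) ≈ 103.92 for a
    uniform histogram.
    """
    if hist.empty or hist.total <= 0:
        raise ValueError("PSD of an empty phase histogram is undefined")
    w = hist.counts
    centers = hist.bin_centers
    mu = circular_mean(centers, weights=w)
    dev = circular_diff(centers, mu)
    return float(np.sqrt((w * dev**2).sum() / w.sum()))


def compute_pbw(hist: PhaseHistogram, coverage: float = 0.95) -> float:
    """Phase histogram bandwidth (degrees).

    The width of the smallest contiguous circular window of bins that
    contains at least ``coverage`` of the total samples, as (number of
    bins in the window) * bin width.  Rotation invariant.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    if hist.empty or hist.total <= 0:
        raise ValueError("PBW of an empty phase histogram is undefined")
    w = hist.counts
    n = w.size
    total = w.sum()
    target = coverage * total - 1e-9 * total  # tolerate float round-off
    tiled = np.concatenate([w, w])
    csum = np.concatenate([[0.0], np.cumsum(tiled)])
    best = n
    for start in range(n):
        # smallest window [start, start+L) with mass >= target
        idx = np.searchsorted(csum, csum[start] + target, side="left")
        length = idx - start
        if length < best:
            best = length
    return float(max(best, 1) * hist.bin_width_deg)


def dyssynchrony_indices(
    pmap: PhaseMap, bin_width_deg: float = 1.0, coverage: float = 0.95
) -> DyssynchronyIndices:
    """Convenience: histogram a phase map and return (PSD, PBW)."""
    hist = phase_histogram(pmap, bin_width_deg)
    return DyssynchronyIndices(psd_deg=compute_psd(hist), pbw_deg=compute_pbw(hist, coverage))


def indices_of_phases(phases_deg, bin_width_deg: float = 1.0, coverage: float = 0.95) -> DyssynchronyIndices:
    """(PSD, PBW) of a raw phase array, bypassing the polar-map container.

    Used to characterise noiseless generated phase fields with exactly
    the same histogram conventions the analysis applies.
    """
    phases = np.asarray(phases_deg, dtype=float).ravel() % 360.0
    n_bins = int(round(360.0 / bin_width_deg))
    counts = np.histogram(phases, bins=n_bins, range=(0.0, 360.0))[0].astype(float)
    hist = PhaseHistogram(bin_width_deg=bin_width_deg, counts=counts, empty=phases.size == 0)
    return DyssynchronyIndices(psd_deg=compute_psd(hist), pbw_deg=compute_pbw(hist, coverage))


# ---------------------------------------------------------------------------
# wall thickening


def compute_wall_thickening(gated: GatedPolarSamples, mask=None) -> ThickeningSummary:
    """Cyclic fractional count change per sample, summarised by a median.

    Per sample: 100 * (max_k c_k - min_k c_k) / min_k c_k.  Samples with
    a zero minimum count are excluded (NaN).  ``mask`` restricts the
    summary (e.g. to non-scar samples); it defaults to all samples.
    """
    c = gated.counts
    cmin = c.min(axis=-1)
    cmax = c.max(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(cmin > 0, 100.0 * (cmax - cmin) / cmin, np.nan)
    if mask is None:
        mask = np.ones(cmin.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != cmin.shape:
            raise ValueError("mask shape inconsistent with geometry")
    sel = mask & np.isfinite(pct)
    summary = float(np.median(pct[sel])) if sel.any() else float("nan")
    return ThickeningSummary(per_sample_pct=pct, summary_pct=summary)
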