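import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spectpa import (
    GatedPolarSamples,
    PhaseHistogram,
    PolarGeometry,
    compute_pbw,
    compute_phase_map,
    compute_psd,
    compute_wall_thickening,
    fit_first_harmonic,
    phase_histogram,
)
from spectpa.circular import circular_diff
from spectpa.simulate import gen_gated_counts


def harmonic_curve(a0, a1, phase_deg, n_frames):
    """Counts with a rising mean-crossing exactly at phase_deg."""
    k = np.arange(n_frames)
    theta = np.deg2rad(phase_deg - 270.0)
    return a0 + a1 * np.cos(2 * np.pi * k / n_frames - theta)


def grid_search_phase(curve, step_deg=0.1):
    """Independent oracle: dense grid over theta, linear LS in (a0, a1).

    For each candidate theta the model is linear in (a0, a1); the SSE
    is minimised in closed form and the best theta (with a1 >= 0) wins.
    """
    n = curve.size
    k = np.arange(n)
    thetas = np.arange(0.0, 360.0, step_deg)
    basis = np.cos(2 * np.pi * k / n - np.deg2rad(thetas)[:, None])  # (T, n)
    bc = basis - basis.mean(axis=1, keepdims=True)
    yc = curve - curve.mean()
    num = bc @ yc
    den = (bc**2).sum(axis=1)
    a1 = num / den
    sse = (yc**2).sum() - num**2 / den
    sse[a1 < 0] = np.inf
    return float((thetas[np.argmin(sse)] + 270.0) % 360.0)


# ---------------------------------------------------------------------------
# fit_first_harmonic


@pytest.mark.parametrize("n_frames", [4, 8, 16])
@pytest.mark.parametrize("phase", [0.0, 37.0, 90.0, 181.0, 359.0])
def test_noiseless_harmonic_recovered_exactly(n_frames, phase):
    fit = fit_first_harmonic(harmonic_curve(100.0, 20.0, phase, n_frames))
    assert fit.a0 == pytest.approx(100.0, abs=1e-9)
    assert fit.a1 == pytest.approx(20.0, abs=1e-9)
    assert abs(circular_diff(fit.phase_deg, phase)) < 1e-6
    assert fit.valid


def test_noiseless_recovery_over_full_phase_grid():
    for phase in range(0, 360, 1):
        fit = fit_first_harmonic(harmonic_curve(50.0, 5.0, float(phase), 8))
        assert abs(circular_diff(fit.phase_deg, phase)) < 1e-6


def test_constant_curve_invalid_zero_amplitude():
    fit = fit_first_harmonic(np.full(8, 50.0))
    assert fit.a1 == pytest.approx(0.0, abs=1e-9)
    assert not fit.valid
    assert np.isnan(fit.phase_deg)


def test_all_zero_curve_invalid():
    fit = fit_first_harmonic(np.zeros(8))
    assert not fit.valid


def test_input_validation():
    with pytest.raises(ValueError):
        fit_first_harmonic([1.0, np.nan, 2.0, 3.0])
    with pytest.raises(ValueError):
        fit_first_harmonic([1.0, -1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        fit_first_harmonic([1.0, 2.0, 3.0])  # too few frames


def test_poisson_phase_error_within_grid_oracle_bound(rng):
    """Analytic LS phase matches the brute-force grid oracle on noisy draws."""
    n_curves = 400
    true_phases = rng.uniform(0, 360, n_curves)
    errs_fit, errs_oracle = [], []
    for phase in true_phases:
        curve = rng.poisson(harmonic_curve(100.0, 30.0, phase, 8)).astype(float)
        fit = fit_first_harmonic(curve)
        oracle_phase = grid_search_phase(curve, step_deg=0.1)
        errs_fit.append(abs(circular_diff(fit.phase_deg, phase)))
        errs_oracle.append(abs(circular_diff(oracle_phase, phase)))
    # the closed-form fit is the LS optimum the oracle approximates
    assert np.mean(errs_fit) <= np.mean(errs_oracle) + 0.1
    assert np.mean(errs_fit) < 15.0  # sanity: noise level implies ~6 deg


# ---------------------------------------------------------------------------
# compute_phase_map


def test_phase_map_inverts_known_field(geometry):
    rng = np.random.default_rng(1)
    field = rng.uniform(0, 360, (geometry.n_rings, geometry.n_angles))
    gated = gen_gated_counts(field, None, a0=200.0, noise=False)
    pmap = compute_phase_map(gated)
    assert pmap.valid_mask.all()
    assert np.max(np.abs(circular_diff(pmap.phase_deg, field))) < 1e-6


def test_flat_sample_masked_others_unchanged(geometry):
    field = np.full((geometry.n_rings, geometry.n_angles), 120.0)
    gated = gen_gated_counts(field, None, a0=200.0, noise=False)
    gated.counts[3, 5, :] = 80.0  # one frame-constant sample
    pmap = compute_phase_map(gated)
    assert not pmap.valid_mask[3, 5]
    assert pmap.valid_mask.sum() == geometry.n_samples - 1
    good = pmap.phase_deg[pmap.valid_mask]
    assert np.max(np.abs(circular_diff(good, 120.0))) < 1e-6


def test_mostly_invalid_map_warns_but_returns(geometry, caplog):
    counts = np.full((geometry.n_rings, geometry.n_angles, geometry.n_frames), 30.0)
    gated = GatedPolarSamples(geometry=geometry, counts=counts)
    with caplog.at_level(logging.WARNING):
        pmap = compute_phase_map(gated)
    assert pmap.valid_mask.sum() == 0
    assert any("invalid" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# phase_histogram


def test_histogram_point_mass(geometry):
    field = np.full((geometry.n_rings, geometry.n_angles), 37.2)
    gated = gen_gated_counts(field, None, a0=100.0, noise=False)
    pmap = compute_phase_map(gated)
    hist = phase_histogram(pmap, 1.0)
    assert hist.counts[37] == geometry.n_samples
    assert hist.total == geometry.n_samples


def test_histogram_empty_map_flagged(geometry):
    gated = GatedPolarSamples(
        geometry=geometry,
        counts=np.full((geometry.n_rings, geometry.n_angles, geometry.n_frames), 10.0),
    )
    hist = phase_histogram(compute_phase_map(gated))
    assert hist.empty
    assert hist.total == 0


def test_histogram_bin_width_must_divide_360(geometry):
    field = np.zeros((geometry.n_rings, geometry.n_angles))
    gated = gen_gated_counts(field, None, noise=False)
    with pytest.raises(ValueError):
        phase_histogram(compute_phase_map(gated), bin_width_deg=7.0)


def test_uniform_phases_pass_chi_square_gof():
    rng = np.random.default_rng(99)
    phases = rng.uniform(0, 360, 10_000)
    counts = np.histogram(phases, bins=36, range=(0, 360))[0]
    from scipy.stats import chisquare

    _, p = chisquare(counts)
    assert p > 0.01


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(min_value=0, max_value=359.99), min_size=0, max_size=200))
def test_histogram_conserves_sample_count(phases):
    counts = np.histogram(np.asarray(phases) % 360, bins=360, range=(0, 360))[0]
    assert counts.sum() == len(phases)


# ---------------------------------------------------------------------------
# PSD


def hist_of(phases, bin_width=1.0):
    n_bins = int(360 / bin_width)
    counts = np.histogram(np.asarray(phases, float) % 360, bins=n_bins, range=(0, 360))[0]
    return PhaseHistogram(bin_width_deg=bin_width, counts=counts.astype(float),
                          empty=len(phases) == 0)


def test_psd_point_mass_is_zero():
    assert compute_psd(hist_of([200.5] * 10)) == pytest.approx(0.0, abs=1e-9)


def test_psd_two_point_hand_value():
    # half at 0, half at 90: circular mean 45, deviations +-45
    assert compute_psd(hist_of([0.0] * 5 + [90.0] * 5)) == pytest.approx(45.0, abs=1e-9)


def test_psd_shift_invariance():
    rng = np.random.default_rng(5)
    phases = rng.uniform(0, 300, 500)
    h1, h2 = hist_of(phases), hist_of((phases + 123.0) % 360)
    assert compute_psd(h1) == pytest.approx(compute_psd(h2), abs=1e-9)


def test_psd_empty_errors():
    with pytest.raises(ValueError):
        compute_psd(hist_of([]))


def test_psd_bounded_by_uniform_limit():
    rng = np.random.default_rng(6)
    for _ in range(20):
        phases = rng.uniform(0, 360, 300)
        assert compute_psd(hist_of(phases)) <= 103.93


# ---------------------------------------------------------------------------
# PBW


def brute_force_pbw(counts, coverage, bin_width=1.0):
    """Exhaustive scan over every circular window start and width."""
    n = counts.size
    total = counts.sum()
    target = coverage * total - 1e-9 * total
    best = n
    for start in range(n):
        acc = 0.0
        for width in range(1, n + 1):
            acc += counts[(start + width - 1) % n]
            if acc >= target:
                best = min(best, width)
                break
    return best * bin_width


def test_pbw_single_bin():
    assert compute_pbw(hist_of([45.4] * 20)) == pytest.approx(1.0)


def test_pbw_uniform_block():
    counts = np.zeros(360)
    counts[10:110] = 1.0  # uniform mass over 100 bins
    h = PhaseHistogram(bin_width_deg=1.0, counts=counts)
    assert compute_pbw(h, coverage=0.95) == pytest.approx(95.0)


def test_pbw_rotation_invariance():
    rng = np.random.default_rng(7)
    counts = rng.poisson(2.0, 360).astype(float)
    h = PhaseHistogram(bin_width_deg=1.0, counts=counts)
    base = compute_pbw(h)
    for k in (1, 45, 123, 359):
        hr = PhaseHistogram(bin_width_deg=1.0, counts=np.roll(counts, k))
        assert compute_pbw(hr) == pytest.approx(base)


def test_pbw_equals_brute_force_on_random_histograms():
    rng = np.random.default_rng(8)
    for _ in range(200):
        counts = rng.poisson(rng.uniform(0.1, 3.0), 72).astype(float)
        if counts.sum() == 0:
            continue
        h = PhaseHistogram(bin_width_deg=5.0, counts=counts)
        cov = rng.uniform(0.5, 1.0)
        assert compute_pbw(h, cov) == pytest.approx(brute_force_pbw(counts, cov, 5.0))


def test_psd_pbw_monotone_in_dispersion():
    """Wider wrapped-normal fields never decrease PSD; PBW follows."""
    rng_draws = np.random.default_rng(9).standard_normal(2000)
    psds, pbws = [], []
    for sigma in (5, 10, 20, 35, 50):
        phases = (180.0 + sigma * rng_draws) % 360.0
        h = hist_of(phases)
        psds.append(compute_psd(h))
        pbws.append(compute_pbw(h))
    assert all(a <= b + 1e-9 for a, b in zip(psds, psds[1:]))
    assert all(a <= b + 1e-9 for a, b in zip(pbws, pbws[1:]))


# ---------------------------------------------------------------------------
# wall thickening


def test_thickening_zero_for_constant_frames(geometry):
    counts = np.full((geometry.n_rings, geometry.n_angles, geometry.n_frames), 70.0)
    thick = compute_wall_thickening(GatedPolarSamples(geometry=geometry, counts=counts))
    assert np.allclose(thick.per_sample_pct, 0.0)
    assert thick.summary_pct == pytest.approx(0.0)


def test_thickening_dense_sampling_approaches_closed_form():
    # a0=100, a1=20: extremes 120/80 -> 100*(120-80)/80 = 50%
    field = np.full((3, 8), 90.0)
    gated = gen_gated_counts(field, None, a0=100.0, a1_ratio=0.2,
                             n_frames=720, noise=False)
    thick = compute_wall_thickening(gated)
    assert thick.summary_pct == pytest.approx(50.0, abs=0.05)


def test_thickening_8_frames_matches_direct_enumeration():
    curve = harmonic_curve(100.0, 20.0, 45.0, 8)
    expected = 100.0 * (curve.max() - curve.min()) / curve.min()
    field = np.full((3, 8), 45.0)
    gated = gen_gated_counts(field, None, a0=100.0, a1_ratio=0.2, n_frames=8, noise=False)
    thick = compute_wall_thickening(gated)
    assert thick.summary_pct == pytest.approx(expected, abs=1e-9)


def test_thickening_zero_minimum_excluded():
    counts = np.zeros((3, 8, 8))
    counts[0, 0, :] = [0, 1, 2, 3, 3, 2, 1, 0]  # min 0 -> excluded
    counts[1:, :, :] = 10.0
    geometry = PolarGeometry(3, 8, 8)
    thick = compute_wall_thickening(GatedPolarSamples(geometry=geometry, counts=counts))
    assert np.isnan(thick.per_sample_pct[0, 0])
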