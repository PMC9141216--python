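"""Max projection, transects, sub-pixel crossing, and oracle equivalence."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from rilate import (EventModel, TransectProfile, ValidationError,
                    critical_extent, extract_transects, max_projection,
                    mean_profile, measure_sample, simulate_event,
                    temperature_at)
from rilate.io import ThermalFrameStack


def _profile(temps, spacing=100.0, side="above"):
    temps = np.asarray(temps, dtype=float)
    return TransectProfile(side=side, distances_um=np.arange(temps.size) * spacing,
                           temperatures_C=temps, column=0)


# ---------------------------------------------------------------------------
# max projection
# ---------------------------------------------------------------------------

def test_max_projection_single_frame_is_identity(small_stack):
    one = ThermalFrameStack(frames=small_stack.frames[:1],
                            timestamps_s=small_stack.timestamps_s[:1],
                            calibration_um=100.0, branch_band=(2, 3), column_roi=(0, 4))
    np.testing.assert_array_equal(max_projection(one), one.frames[0])


def test_max_projection_equals_brute_force(small_stack):
    expected = np.maximum.reduce([small_stack.frames[i] for i in range(3)])
    np.testing.assert_array_equal(max_projection(small_stack), expected)


def test_appending_colder_frames_leaves_extent_unchanged(noiseless_model):
    stack, _ = simulate_event(noiseless_model)
    above, below = measure_sample(stack)
    colder = np.concatenate([stack.frames, stack.frames[-1:] - 10.0])
    stack2 = ThermalFrameStack(frames=colder,
                               timestamps_s=np.append(stack.timestamps_s,
                                                      stack.timestamps_s[-1] + 1),
                               calibration_um=stack.calibration_um,
                               branch_band=stack.branch_band,
                               column_roi=stack.column_roi)
    above2, below2 = measure_sample(stack2)
    assert above2.extent_um == above.extent_um
    assert below2.extent_um == below.extent_um


# ---------------------------------------------------------------------------
# transects
# ---------------------------------------------------------------------------

def test_single_transect_sits_at_roi_centre():
    proj = np.tile(np.array([80.0, 60.0, 90.0, 90.0, 40.0, 30.0])[:, None], (1, 10))
    profiles = extract_transects(proj, 100.0, (2, 3), (0, 9), n_transects=1)
    assert {p.column for p in profiles} == {4}  # centre of 0..9 rounds to 4


def test_transect_orientation_and_distances():
    proj = np.tile(np.arange(6.0)[:, None] * 10 + 20, (1, 4))  # rows 20..70
    profiles = extract_transects(proj, 50.0, (2, 3), (0, 3), n_transects=2)
    above = [p for p in profiles if p.side == "above"][0]
    below = [p for p in profiles if p.side == "below"][0]
    # above reads rows r_top-1 .. 0 (away from the band)
    np.testing.assert_array_equal(above.temperatures_C, [30.0, 20.0])
    np.testing.assert_array_equal(above.distances_um, [0.0, 50.0])
    np.testing.assert_array_equal(below.temperatures_C, [60.0, 70.0])


def test_band_at_image_edge_gives_no_above_profiles():
    proj = np.full((5, 4), 60.0)
    profiles = extract_transects(proj, 50.0, (0, 1), (0, 3), n_transects=2)
    assert all(p.side == "below" for p in profiles)


def test_too_many_transects_rejected():
    proj = np.full((5, 4), 60.0)
    with pytest.raises(ValidationError, match="exceeds"):
        extract_transects(proj, 50.0, (2, 2), (0, 3), n_transects=10)


def test_noiseless_profiles_monotone_non_increasing(noiseless_model):
    stack, _ = simulate_event(noiseless_model)
    profiles = extract_transects(max_projection(stack), stack.calibration_um,
                                 stack.branch_band, stack.column_roi)
    for p in profiles:
        assert np.all(np.diff(p.temperatures_C) <= 1e-12)


# ---------------------------------------------------------------------------
# critical extent
# ---------------------------------------------------------------------------

def test_interpolated_crossing_hand_example():
    # [80, 70, 60, 40] at 100 µm spacing: 2 full steps + half step = 250 µm
    assert critical_extent(_profile([80, 70, 60, 40])) == pytest.approx(250.0)


def test_all_below_threshold_gives_zero():
    assert critical_extent(_profile([50.0, 40, 30])) == 0.0
    assert critical_extent(_profile([20.0, 10])) == 0.0


def test_threshold_is_boundary_exclusive():
    # first pixel exactly at threshold terminates the zone immediately
    assert critical_extent(_profile([50.0, 60.0, 40.0])) == 0.0


def test_distal_hot_speckle_does_not_reopen_zone():
    assert critical_extent(_profile([80, 60, 40, 90, 30])) == pytest.approx(150.0)


def test_raising_threshold_never_increases_extent():
    rng = np.random.default_rng(99)
    for _ in range(25):
        temps = rng.uniform(20, 110, size=12)
        prof = _profile(temps)
        extents = [critical_extent(prof, thr) for thr in np.linspace(30, 100, 15)]
        assert all(a >= b - 1e-12 for a, b in zip(extents, extents[1:]))


def test_frontier_inversion_nested_inside_critical_zone(noiseless_model):
    """Inverting any frontier temperature above 50 °C lands inside the zone."""
    stack, _ = simulate_event(noiseless_model)
    prof = mean_profile(stack, "above")
    crit = critical_extent(prof, 50.0)
    for tf in (52.0, 60.0, 75.0, 100.0):
        assert critical_extent(prof, tf) < crit


def test_noiseless_extent_matches_closed_form(noiseless_model):
    stack, truth = simulate_event(noiseless_model)
    above, below = measure_sample(stack)
    half_px = noiseless_model.calibration_um / 2
    assert abs(above.extent_um - truth.critical_above_um) <= half_px
    assert abs(below.extent_um - truth.critical_below_um) <= half_px
    # translation-invariant noiseless field: all transects identical
    assert np.ptp(above.per_transect_um) == 0.0


def test_asymmetric_lambdas_order_extents():
    m = EventModel(lambda_above=2000.0, lambda_below=1200.0, noise_sd=0.0)
    stack, _ = simulate_event(m)
    above, below = measure_sample(stack)
    assert above.extent_um > below.extent_um


def test_degenerate_side_flagged_absent_not_zero():
    m = EventModel(grid_shape=(90, 48), branch_band=(0, 5))
    stack, _ = simulate_event(m)
    above, below = measure_sample(stack)
    assert above is None
    assert below is not None and below.extent_um > 0


def test_noisy_extent_unbiased_up_to_peak_detection_bias():
    """Mean extent over replicate noisy events exceeds the closed form by at
    most the max-projection bias bound (E[max of k plateau noises] divided by
    the temperature gradient at the 50 °C crossing), and is never biased low.
    """
    noise_sd = 2.0
    m = EventModel(noise_sd=noise_sd, frontier_sd=0.0)
    extents = []
    for seed in range(50):
        stack, truth = simulate_event(
            EventModel(noise_sd=noise_sd, frontier_sd=0.0, seed=seed))
        above, _ = measure_sample(stack)
        extents.append(above.extent_um)
    extents = np.array(extents)
    # plateau frames: s(t) == 1
    duration = m.ramp_time + m.plateau_time
    ts = np.linspace(0, duration, m.n_frames)
    k = int(np.sum(ts >= m.ramp_time))
    # E[max of k standard normals] by numeric integration of the order statistic
    x = np.linspace(-8, 8, 4001)
    emax = np.trapezoid(x * k * norm.cdf(x) ** (k - 1) * norm.pdf(x), x)
    gradient = (50.0 - m.t_ambient) / m.lambda_above  # °C per µm at the crossing
    bias_bound = emax * noise_sd / gradient
    se = extents.std(ddof=1) / math.sqrt(len(extents))
    analytic = m.critical_extent("above")
    assert extents.mean() > analytic - 2 * se
    assert extents.mean() < analytic + bias_bound + 2 * se


# ---------------------------------------------------------------------------
# temperature lookup
# ---------------------------------------------------------------------------

def test_temperature_at_endpoints_and_grid_points():
    prof = _profile([80, 70, 60, 40])
    assert temperature_at(prof, 0.0) == 80.0
    assert temperature_at(prof, 200.0) == 60.0       # exact grid point
    assert temperature_at(prof, 150.0) == pytest.approx(65.0)
    with pytest.raises(ValidationError, match="outside"):
        temperature_at(prof, 400.0)


def test_frontier_temperature_recovered_by_inversion(noiseless_model):
    stack, truth = simulate_event(noiseless_model)
    prof = mean_profile(stack, "above")
    recovered = temperature_at(prof, truth.necrosis_above_um)
    assert recovered == pytest.approx(truth.frontier_above_C, abs=0.5)
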