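"""Hilbert-phase and continuous-relative-phase behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitsynergy.crp import (
    CRPSeries,
    DegenerateSignalError,
    analytic_phase,
    crp,
    crp_compare,
    mean_crp_curve,
    subject_crp_profile,
    wrap_degrees,
)
from gaitsynergy.pipeline import representative_cycles
from gaitsynergy.preprocessing import NormalizedCycle, PCT_GRID
from gaitsynergy.profiles import make_profile
from gaitsynergy.synthetic import generate_trial

T = PCT_GRID / 100.0


def _cycle(values):
    return NormalizedCycle(np.asarray(values, dtype=float), 50.0)


def test_phase_of_cosine_advances_90_degrees_per_quarter_period():
    phi = analytic_phase(_cycle(np.cos(2 * np.pi * T))).phi
    assert wrap_degrees(phi[25] - phi[0]) == pytest.approx(90.0, abs=2.0)


def test_phase_is_amplitude_and_offset_invariant():
    x = np.sin(2 * np.pi * T)
    p1 = analytic_phase(_cycle(x)).phi
    p2 = analytic_phase(_cycle(3.0 * x + 20.0)).phi
    assert np.allclose(p1, p2, atol=1e-9)


def test_constant_signal_raises_degenerate_error():
    with pytest.raises(DegenerateSignalError):
        analytic_phase(_cycle(np.full(101, 7.0)))


def test_crp_of_signal_with_itself_is_zero():
    p = analytic_phase(_cycle(np.sin(2 * np.pi * T)))
    assert np.allclose(crp(p, p).crp, 0.0)


def test_crp_antisymmetry_under_pair_swap():
    p1 = analytic_phase(_cycle(np.sin(2 * np.pi * T)))
    p2 = analytic_phase(_cycle(np.cos(4 * np.pi * T) + 0.3 * np.sin(2 * np.pi * T)))
    forward = crp(p1, p2).crp
    backward = crp(p2, p1).crp
    assert np.allclose(wrap_degrees(forward + backward), 0.0, atol=1e-9)


def test_quarter_period_lag_recovers_90_degrees():
    x1 = _cycle(np.sin(2 * np.pi * T))
    x2 = _cycle(np.sin(2 * np.pi * T - np.pi / 2))  # lags by a quarter period
    series = crp(analytic_phase(x1), analytic_phase(x2)).crp
    interior = series[5:-5]
    assert np.all(np.abs(interior - 90.0) < 2.0)


@pytest.mark.parametrize("lag_frac", [0.1, 0.25, 0.4])
def test_single_harmonic_lag_maps_to_crp(lag_frac):
    x1 = _cycle(np.sin(2 * np.pi * T))
    x2 = _cycle(np.sin(2 * np.pi * (T - lag_frac)))
    series = crp(analytic_phase(x1), analytic_phase(x2)).crp
    interior = series[5:-5]
    assert np.mean(np.abs(wrap_degrees(interior - 360.0 * lag_frac))) < 2.0


def test_compare_identical_and_shifted_curves():
    base = CRPSeries(30.0 * np.sin(2 * np.pi * T), stance_end_pct=47.0)
    same = crp_compare(base, base)
    assert same.rmse == pytest.approx(0.0) and same.pcc == pytest.approx(1.0)
    shifted = CRPSeries(base.crp + 10.0, stance_end_pct=47.0)
    res = crp_compare(base, shifted)
    assert res.rmse == pytest.approx(10.0)
    assert res.pcc == pytest.approx(1.0)


def test_compare_matches_hand_computed_toy_vectors():
    c1 = CRPSeries(np.array([0.0, 10.0, 20.0, 10.0, 0.0]), stance_end_pct=50.0)
    c2 = CRPSeries(np.array([0.0, 20.0, 40.0, 20.0, 0.0]), stance_end_pct=50.0)
    res = crp_compare(c1, c2)
    assert res.rmse == pytest.approx(np.sqrt(600.0 / 5.0), abs=1e-9)
    assert res.pcc == pytest.approx(1.0)


def test_compare_rmse_pcc_match_brute_force_oracle():
    rng = np.random.default_rng(7)
    for _ in range(200):
        a = rng.uniform(-180.0, 180.0, 101)
        b = rng.uniform(-180.0, 180.0, 101)
        res = crp_compare(CRPSeries(a), CRPSeries(b))
        diff = np.array([((x - y + 180.0) % 360.0) - 180.0 for x, y in zip(a, b)])
        diff[diff == -180.0] = 180.0
        rmse = np.sqrt(sum(d * d for d in diff) / len(diff))
        pcc = float(np.corrcoef(a, b)[0, 1])
        assert res.rmse == pytest.approx(rmse, abs=1e-10)
        assert res.pcc == pytest.approx(pcc, abs=1e-10)


def test_windowed_comparison_uses_stance_boundary():
    vals = np.concatenate([np.zeros(51), np.full(50, 40.0)])
    c1 = CRPSeries(vals, stance_end_pct=50.0)
    c2 = CRPSeries(np.zeros(101), stance_end_pct=50.0)
    assert crp_compare(c1, c2, "stance").rmse == pytest.approx(0.0)
    assert crp_compare(c1, c2, "swing").rmse == pytest.approx(40.0)


def test_intralimb_profile_has_one_series_per_side(quiet_healthy_trial):
    cycles = representative_cycles(quiet_healthy_trial, 6, frame="own")
    series = subject_crp_profile(cycles, "intralimb")
    assert len(series) == 2


def test_identical_limbs_give_zero_interlimb_crp():
    base = NormalizedCycle(np.sin(2 * np.pi * T) * 20.0, 47.0)
    cycles = {(s, j): base for s in ("left", "right") for j in ("hip", "knee")}
    series = subject_crp_profile(cycles, "interlimb")
    for s in series:
        assert np.allclose(s.crp, 0.0, atol=1e-9)


def test_half_cycle_shift_gives_antiphase_interlimb_crp():
    p = make_profile("healthy", overrides={"noise_sd": 0.0, "harmonic_count": 1})
    trial = generate_trial(p, 6, seed=4)
    cycles = representative_cycles(trial, smooth_order=1, frame="reference")
    series = subject_crp_profile(cycles, "interlimb")
    hip_pair = series[0]
    interior = np.abs(hip_pair.crp[5:-5])
    assert np.all(np.abs(interior - 180.0) < 2.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=20))
def test_wrap_degrees_range_and_congruence(values):
    arr = np.asarray(values)
    wrapped = wrap_degrees(arr)
    assert np.all(wrapped > -180.0) and np.all(wrapped <= 180.0)
    assert np.allclose(np.cos(np.radians(wrapped)), np.cos(np.radians(arr)), atol=1e-6)
    assert np.allclose(np.sin(np.radians(wrapped)), np.sin(np.radians(arr)), atol=1e-6)


def test_mean_crp_curve_handles_wraparound():
    near_wrap = [CRPSeries(np.full(101, 179.0)), CRPSeries(np.full(101, -179.0))]
    mean = mean_crp_curve(near_wrap)
    assert np.allclose(np.abs(mean.crp), 180.0, atol=1e-9)
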