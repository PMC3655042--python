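"""Time-activity curves, residence times, remainder rule, SD envelopes."""

import math

import numpy as np
import pytest

from petdosim import (
    F18,
    build_tac,
    remainder_residence,
    residence_time,
    uncertainty_window,
)
from petdosim import reference as ref


def test_single_point_constant_back_extrapolation_and_decay_tail():
    tac = build_tac([(1.0, 0.1)], "organ", F18)
    assert tac(0.5) == pytest.approx(0.1)
    assert tac(1.0 + F18.half_life_h) == pytest.approx(0.05, rel=1e-12)


def test_linear_interpolation_midpoint():
    tac = build_tac([(1.0, 0.1), (2.0, 0.2)], "organ", F18)
    assert tac(1.5) == pytest.approx(0.15)


def test_truncation_beyond_horizon():
    tac = build_tac([(1.0, 0.1)], "organ", F18, horizon_h=10.0)
    assert tac(10.0) > 0.0
    assert tac(10.5) == 0.0


def test_linear_from_zero_back_extrapolation():
    tac = build_tac([(1.0, 0.1)], "organ", F18, back_extrapolation="linear_from_zero")
    assert tac(0.0) == pytest.approx(0.0)
    assert tac(0.5) == pytest.approx(0.05)


def test_unsorted_or_duplicate_times_rejected():
    with pytest.raises(ValueError):
        build_tac([(1.0, 0.1), (1.0, 0.2)], "organ", F18)


def test_rectangle_integral():
    tac = build_tac([(0.0, 0.1), (2.0, 0.1)], "organ", F18, horizon_h=2.0)
    assert residence_time(tac) == pytest.approx(0.2, rel=1e-12)


def test_trapped_unit_activity_matches_inverse_decay_constant():
    # (0, 1.0) with analytic tail integrates to 1/lambda_p = 2.6396 h
    tac = build_tac([(0.0, 1.0)], "organ", F18, tail_policy="analytic_tail")
    tau = residence_time(tac)
    assert tau == pytest.approx(F18.total_disintegrations, rel=1e-3)
    assert tau == pytest.approx(2.6396, abs=2e-3)


def test_zero_curve_integrates_to_zero():
    tac = build_tac([(0.0, 0.0), (2.0, 0.0)], "organ", F18)
    assert residence_time(tac) == 0.0


def test_trapezoid_matches_mono_exponential_closed_form():
    # spec tolerance for the integrator: < 0.5 % at 0.01 h steps
    lam = F18.decay_constant
    t = np.linspace(0.0, 2.0, 41)
    tac = build_tac(list(zip(t, np.exp(-lam * t))), "organ", F18, horizon_h=10.0)
    closed = (1.0 - math.exp(-lam * 10.0)) / lam
    assert residence_time(tac, step_h=0.01) == pytest.approx(closed, rel=5e-3)


def test_residence_scales_linearly_with_activity():
    pts = [(0.1, 0.2), (0.5, 0.15), (2.0, 0.05)]
    tau1 = residence_time(build_tac(pts, "o", F18))
    tau3 = residence_time(build_tac([(t, 3 * v) for t, v in pts], "o", F18))
    assert tau3 == pytest.approx(3 * tau1, rel=1e-12)


@pytest.mark.parametrize(
    "organ_taus, printed_remainder",
    [
        (ref.RESIDENCE_TD, ref.RESIDENCE_REMAINDER_TD),
        (ref.RESIDENCE_DYNAMIC_SINGLE, ref.RESIDENCE_REMAINDER_DYNAMIC_SINGLE),
    ],
    ids=["tissue-distribution", "dynamic-single"],
)
def test_remainder_rule_reproduces_published_values(organ_taus, printed_remainder):
    rem = remainder_residence(organ_taus, ref.RESIDENCE_BLADDER, F18)
    assert rem == pytest.approx(printed_remainder, abs=0.01)


def test_everything_is_remainder_without_organs():
    assert remainder_residence({}, 0.0, F18) == pytest.approx(
        F18.total_disintegrations, rel=1e-15
    )


def test_remainder_conservation_is_exact():
    taus = {"a": 0.3, "b": 0.7}
    rem = remainder_residence(taus, 0.2, F18)
    assert sum(taus.values()) + 0.2 + rem == pytest.approx(
        F18.total_disintegrations, abs=1e-9
    )


def test_inconsistent_inputs_rejected():
    with pytest.raises(ValueError):
        remainder_residence({"a": 2.0}, 1.0, F18)


def _integrate(points):
    return residence_time(build_tac(points, "o", F18))


def test_uncertainty_window_zero_sd_collapses():
    pts = [(0.1, 0.2), (1.0, 0.1)]
    tau, lo, hi, cv = uncertainty_window(pts, [(t, 0.0) for t, _ in pts], _integrate)
    assert lo == hi == tau
    assert cv == 0.0


def test_uncertainty_window_proportional_sd_gives_matching_cv():
    # sd = 10 % of mean at every point -> cv = 10 % by linearity of the integral
    pts = [(0.1, 0.2), (0.5, 0.15), (2.0, 0.05)]
    sd = [(t, 0.1 * v) for t, v in pts]
    tau, lo, hi, cv = uncertainty_window(pts, sd, _integrate)
    assert cv == pytest.approx(10.0, rel=1e-9)
    assert hi - tau == pytest.approx(tau - lo, rel=1e-9)


def test_uncertainty_window_floors_negative_lower_curve():
    pts = [(0.5, 0.1)]
    sd = [(0.5, 0.3)]  # sd > mean
    tau, lo, hi, cv = uncertainty_window(pts, sd, _integrate)
    assert lo == 0.0
    assert hi > tau
    # asymmetric window: cv from the mean of the two half-widths
    assert cv == pytest.approx(100.0 * 0.5 * ((hi - tau) + tau) / tau, rel=1e-12)


def test_uncertainty_window_zero_mean_reports_absent_cv():
    pts = [(0.5, 0.0)]
    tau, lo, hi, cv = uncertainty_window(pts, [(0.5, 0.0)], _integrate)
    assert tau == 0.0
    assert cv is None
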