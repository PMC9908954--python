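"""Adaptive CS discharge model: closed forms, oracles, dynamic properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cssim.cs_model import (
    PRESETS,
    CSParameters,
    CSState,
    CSTrace,
    discharge_step,
    group_bank,
    simulate_discharge,
    steady_state_discharge,
    tonic_threshold,
)

P3 = PRESETS["3"]
FS = 60.0


def trapezoid(fs=FS, ramp=0.5, hold=2.0, release=0.5, amp=5.0, pad=0.5):
    t = np.arange(0.0, pad + ramp + hold + release + pad, 1.0 / fs)
    knots = [0, pad, pad + ramp, pad + ramp + hold, pad + ramp + hold + release, t[-1]]
    vals = [0, 0, amp, amp, 0, 0]
    return t, np.interp(t, knots, vals)


class TestParameters:
    def test_published_presets(self):
        shared = dict(a=338.9952, b=2.2707, c=7.1531, tau=0.0250)
        for g in ("6B", "3", "4"):
            p = PRESETS[g]
            assert (p.a, p.b, p.c, p.tau) == tuple(shared.values())
            assert p.d == -27.9311
        p6a = PRESETS["6A"]
        assert (p6a.a, p6a.b, p6a.c, p6a.tau) == tuple(shared.values())
        assert p6a.d == -17.9311

    def test_validation(self):
        with pytest.raises(ValueError):
            CSParameters(a=1, b=2, c=1, d=0, tau=0.0)
        with pytest.raises(ValueError):
            CSParameters(a=1, b=-1, c=1, d=0, tau=0.1)


class TestClosedForms:
    def test_zero_input_is_silent(self):
        state = discharge_step(CSState(u=0, x=0, y=0), 0.0, 1 / FS, P3)
        assert state.y == 0.0  # d < 0 is rectified away

    def test_adapted_steady_state_value(self):
        # long-held u0 = 5: y -> c*u0 + d = 7.8344
        assert steady_state_discharge(5.0, P3) == pytest.approx(7.8344, abs=1e-10)
        # the power-law adaptation tail decays slowly; after 40 s the
        # residual transient is under 0.1% of the initial burst
        t = np.arange(0, 40.0, 1 / FS)
        tr = simulate_discharge(np.full_like(t, 5.0), t, P3, x0=0.0)
        assert abs(tr.y[-1] - 7.8344) < 1e-3 * tr.y.max()

    def test_step_peak_before_threshold_moves(self):
        u0 = 5.0
        state = discharge_step(CSState(u=0.0, x=0.0, y=0.0), u0, 1 / FS, P3)
        assert state.y == pytest.approx((P3.a + P3.c) * u0 + P3.d)

    def test_tonic_thresholds(self):
        assert tonic_threshold(PRESETS["6B"]) == pytest.approx(3.9048, abs=1e-4)
        assert tonic_threshold(PRESETS["6A"]) == pytest.approx(2.5067, abs=1e-4)
        # 6A fires tonically at loads where 6B stays silent
        u = 3.0
        assert steady_state_discharge(u, PRESETS["6A"]) > 0
        assert steady_state_discharge(u, PRESETS["6B"]) == 0.0
        assert steady_state_discharge(0.0, P3) == 0.0


class TestThresholdDynamics:
    def test_matches_independent_ode_integration(self):
        # exact per-sample update vs scipy's adaptive integrator
        p = P3
        t = np.arange(0, 1.0, 1 / FS)
        tr = simulate_discharge(np.full_like(t, 5.0), t, p, x0=0.0)
        sol = solve_ivp(
            lambda _, x: [np.sign(5.0 - x[0]) * abs(5.0 - x[0]) ** p.b / p.tau],
            [0, t[-1]],
            [0.0],
            t_eval=t,
            rtol=1e-11,
            atol=1e-13,
        )
        np.testing.assert_allclose(tr.x, sol.y[0], atol=1e-8)

    def test_threshold_approaches_monotonically_without_crossing(self):
        t = np.arange(0, 2.0, 1 / FS)
        for u0, x0 in ((5.0, 0.0), (1.0, 4.0), (-3.0, 0.0)):
            tr = simulate_discharge(np.full_like(t, u0), t, P3, x0=x0)
            gap = np.abs(u0 - tr.x)
            assert np.all(np.diff(gap) <= 1e-12)
            assert np.all(np.sign(u0 - tr.x[:-1]) * np.sign(u0 - tr.x[1:]) >= 0)

    def test_adaptation_nonincreasing_after_peak_and_converges(self):
        t = np.arange(0, 30.0, 1 / FS)
        tr = simulate_discharge(np.full_like(t, 5.0), t, P3, x0=0.0)
        k = int(np.argmax(tr.y))
        assert np.all(np.diff(tr.y[k:]) <= 1e-9)
        # power-law adaptation: the remaining transient at 500*tau is under
        # 1% of the initial burst
        ss = steady_state_discharge(5.0, P3)
        i = int(500 * P3.tau * FS)
        assert abs(tr.y[i] - ss) < 0.01 * (tr.y[k] - ss)

    def test_substep_semigroup_exactness(self):
        # the update is the exact ODE flow, so subdividing each hold
        # interval (10 substeps) leaves the trace unchanged
        t, u = trapezoid()
        a = simulate_discharge(u, t, P3, x0=0.0)
        b = simulate_discharge(u, t, P3, x0=0.0, substeps=10)
        assert abs(a.y.max() - b.y.max()) <= 0.01 * a.y.max()
        np.testing.assert_allclose(a.x, b.x, atol=1e-9)


class TestDynamicSignatures:
    def test_trapezoid_phasic_burst_adapt_silent_release(self):
        t, u = trapezoid()
        tr = simulate_discharge(u, t, P3, x0=0.0)
        ramp = (t > 0.5) & (t <= 1.0)
        hold_end = (t > 2.6) & (t <= 3.0)
        release = t > 3.0
        assert tr.y[ramp].max() > 5 * max(tr.y[hold_end].max(), 1.0)  # phasic burst
        assert tr.y[hold_end].max() < 0.25 * tr.y[ramp].max()  # adapted
        assert np.all(tr.y[release][5:] == 0.0)  # silent during/after release

    def test_peak_discharge_nondecreasing_in_ramp_rate(self):
        peaks = []
        for ramp in (2.0, 1.0, 0.5, 0.25, 0.1):
            t = np.arange(0, ramp + 1.0, 1 / FS)
            u = np.clip(t / ramp, 0, 1) * 5.0
            peaks.append(simulate_discharge(u, t, P3, x0=0.0).y.max())
        assert np.all(np.diff(peaks) >= 0)

    def test_hysteresis_under_triangular_cycling(self):
        t = np.arange(0, 6.0, 1 / FS)
        u = 5.0 * (1.0 - np.abs((t % 2.0) - 1.0))
        tr = simulate_discharge(u, t, P3, x0=0.0)
        rising = np.gradient(u) > 0
        probe = np.abs(u - 2.5) < 0.2
        late = t > 2.0
        y_up = tr.y[late & rising & probe].mean()
        y_down = tr.y[late & ~rising & probe].mean()
        assert abs(y_up - y_down) > 10.0  # strongly direction-dependent


@settings(derandomize=True, max_examples=40)
@given(
    u=st.lists(st.floats(-10, 10), min_size=2, max_size=60),
    x0=st.floats(-10, 10),
)
def test_output_rectified_and_trace_invariant(u, x0):
    u = np.asarray(u)
    t = np.arange(len(u)) / FS
    tr = simulate_discharge(u, t, P3, x0=x0)
    assert np.all(tr.y >= 0.0)
    np.testing.assert_allclose(
        tr.y, np.maximum(0.0, P3.a * (tr.u - tr.x) + P3.c * tr.u + P3.d), atol=1e-12
    )


class TestErrors:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            simulate_discharge(np.zeros(5), np.zeros(4), P3)

    def test_nonfinite_input(self):
        with pytest.raises(ValueError):
            simulate_discharge(np.array([0.0, np.nan]), np.array([0.0, 1 / FS]), P3)
        with pytest.raises(ValueError):
            discharge_step(CSState(0, 0, 0), np.inf, 1 / FS, P3)

    def test_nonpositive_dt(self):
        with pytest.raises(ValueError):
            discharge_step(CSState(0, 0, 0), 1.0, 0.0, P3)

    def test_trace_requires_uniform_time(self):
        with pytest.raises(ValueError):
            CSTrace(t=np.array([0.0, 0.1, 0.3]), u=np.zeros(3), x=np.zeros(3), y=np.zeros(3))


class _FakeRecord:
    def __init__(self, t, channels):
        self.t = t
        self._ch = channels

    def channel(self, name):
        return self._ch[name]


class TestGroupBank:
    def test_zero_strain_gives_zero_everywhere(self):
        t = np.arange(0, 2, 1 / FS)
        rec = _FakeRecord(t, {ch: np.zeros_like(t) for ch in (
            "tf_axial", "tf_transverse", "tib_axial", "tib_transverse")})
        bank = group_bank(rec)
        assert set(bank) == {"3", "4", "6B", "6A"}
        for tr in bank.values():
            assert np.all(tr.y == 0.0)

    def test_missing_channel_is_configuration_error(self):
        t = np.arange(0, 1, 1 / FS)
        rec = _FakeRecord(t, {"tf_axial": np.zeros_like(t)})
        with pytest.raises(KeyError, match="tf_transverse|tib"):
            group_bank(rec)
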