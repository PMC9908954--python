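"""Strain synthesis, directional tuning, and the acquisition chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cssim.experiments import _stance_posture
from cssim.synthetic_leg import (
    CHANNELS,
    LoadSchedule,
    LoadState,
    SegmentSection,
    SensorChain,
    _rosette_frames,
    gauge_response_matrix,
    sensor_chain,
    simulate_stepping,
    strain_at_gauges,
)


class TestSection:
    def test_hollow_square_closed_form(self):
        sec = SegmentSection(outer=10.0, wall=1.0)
        # (10^4 - 8^4)/12 mm^4
        assert sec.area_moment == pytest.approx((1e-2**4 - 8e-3**4) / 12.0)
        assert sec.area_moment > 0
        assert sec.half_depth == pytest.approx(5e-3)

    def test_validation(self):
        with pytest.raises(ValueError):
            SegmentSection(outer=10.0, wall=5.0)


class TestStrainAtGauges:
    def test_free_leg_is_strain_free(self, leg, section):
        out = strain_at_gauges(
            (0.1, 0.2, -1.0),
            LoadState(contact=False, contact_force=np.array([1.0, 2.0, 3.0]),
                      carriage_mass=2.0),
            leg, section,
        )
        np.testing.assert_array_equal(out, np.zeros(4))

    def test_doubling_force_doubles_strain(self, leg, section):
        load = LoadState(contact_force=np.array([-3.0, 1.0, 8.0]))
        double = LoadState(contact_force=np.array([-6.0, 2.0, 16.0]))
        e1 = strain_at_gauges((0.0, 0.3, -1.2), load, leg, section)
        e2 = strain_at_gauges((0.0, 0.3, -1.2), double, leg, section)
        np.testing.assert_allclose(e2, 2 * e1, rtol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(
        f1=st.tuples(*[st.floats(-10, 10)] * 3),
        f2=st.tuples(*[st.floats(-10, 10)] * 3),
    )
    def test_superposition(self, leg, section, f1, f2):
        W = gauge_response_matrix((0.1, 0.4, -1.3), leg, section)
        np.testing.assert_allclose(
            W @ (np.add(f1, f2)), W @ np.asarray(f1) + W @ np.asarray(f2), atol=1e-15
        )

    def test_carriage_weight_enters_vertical_reaction(self, leg, section):
        e_mass = strain_at_gauges((0.0, 0.3, -1.2), LoadState(carriage_mass=1.0), leg, section)
        e_force = strain_at_gauges(
            (0.0, 0.3, -1.2), LoadState(contact_force=np.array([0.0, 0.0, 9.81])), leg, section
        )
        np.testing.assert_allclose(e_mass, e_force, rtol=1e-12)


class TestDirectionalTuning:
    def test_cosine_tuning_with_antagonistic_maxima(self, leg, section):
        posture = _stance_posture(leg)
        sites, _ = _rosette_frames(posture, leg)
        W = gauge_response_matrix(posture, leg, section)
        phis = np.radians(np.arange(12) * 30.0)
        axial, transverse = [], []
        for phi in phis:
            F = 6.0 * (np.cos(phi) * sites["tf"]["d_hat"] + np.sin(phi) * sites["tf"]["a_hat"])
            e = W @ F
            axial.append(e[0])
            transverse.append(e[1])
        axial = np.array(axial)
        transverse = np.array(transverse)
        assert np.argmax(axial) == 0  # dorsal
        assert np.argmax(transverse) == 6  # ventral, 180 degrees away
        # single maximum, approximately cosine falloff
        for resp in (axial, transverse):
            c = np.cos(phis - phis[np.argmax(resp)])
            fit = np.polyfit(c, resp, 1)
            pred = np.polyval(fit, c)
            ss = 1 - np.sum((resp - pred) ** 2) / np.sum((resp - resp.mean()) ** 2)
            assert ss > 0.98


class TestSensorChain:
    def test_zero_signal_is_midrange_code(self):
        codes = sensor_chain(np.zeros(64))
        assert np.all(codes == 2048)

    def test_quantization_step_is_vref_over_levels(self):
        ch = SensorChain()
        assert ch.lsb == pytest.approx(3.3 / 4096)
        # one LSB of strain resolves as one code step
        eps = ch.lsb / ch.volts_per_strain
        codes = sensor_chain(np.full(32, 10.5 * eps))
        assert np.all(codes == 2048 + 10)

    def test_single_sample_spike_removed_by_median(self):
        ch = SensorChain()
        smooth = np.full(120, 2e-3)
        spiked = smooth.copy()
        spiked[60] += 100 * ch.lsb / ch.volts_per_strain
        t = np.arange(120) / ch.fs
        c_smooth, _, _ = ch.apply(smooth, t)
        c_spiked, _, _ = ch.apply(spiked, t)
        np.testing.assert_array_equal(c_spiked, c_smooth)

    def test_median_idempotent_on_constants_and_preserves_ramps(self):
        ch = SensorChain()
        t = np.arange(200) / ch.fs
        const = np.full(200, 2e-3)
        c1, _, _ = ch.apply(const, t)
        assert np.ptp(c1) == 0
        ramp = np.linspace(0, 4e-3, 200)
        codes, _, _ = ch.apply(ramp, t)
        raw = np.rint((ch.vref / 2 + ch.volts_per_strain * ramp) / ch.lsb)
        # interior of a monotone ramp passes the median filter unchanged
        np.testing.assert_array_equal(codes[7:-7], raw[7:-7])

    def test_saturation_clips_and_flags(self):
        ch = SensorChain()
        big = np.full(40, 1.0)  # 1 strain -> far beyond ADC range
        t = np.arange(40) / ch.fs
        codes, _, sat = ch.apply(big, t)
        assert np.all(codes == ch.levels - 1)
        assert np.all(sat)

    def test_seeded_noise_is_reproducible(self):
        raw = np.zeros(100)
        a = sensor_chain(raw, seed=3)
        b = sensor_chain(raw, seed=3)
        np.testing.assert_array_equal(a, b)
        assert np.any(sensor_chain(raw, seed=4) != a)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sensor_chain(np.zeros(4), gain=0.0)
        with pytest.raises(ValueError):
            sensor_chain(np.zeros(4), adc_bits=0)


class TestSimulateStepping:
    def test_swing_strains_exactly_zero_before_noise(self, footpath, footpath_angles):
        rec = simulate_stepping(footpath, LoadSchedule(), seed=None, angles=footpath_angles)
        assert np.all(rec.clean[~rec.phase] == 0.0)

    def test_steps_repeat_identically_without_noise(self, footpath, footpath_angles):
        rec = simulate_stepping(
            footpath, LoadSchedule(), seed=None, n_steps=3, angles=footpath_angles
        )
        n = len(footpath.t)
        for name in CHANNELS:
            ch = rec.channel(name)
            np.testing.assert_array_equal(ch[:n], ch[n : 2 * n])
            np.testing.assert_array_equal(ch[:n], ch[2 * n :])

    def test_zero_carriage_zero_friction_is_quiet(self, footpath, footpath_angles):
        sched = LoadSchedule(carriage_mass=0.0, mu=0.0)
        rec = simulate_stepping(footpath, sched, seed=None, angles=footpath_angles)
        assert np.max(np.abs(rec.clean)) == 0.0

    def test_added_mass_scales_amplitude_preserving_shape(self, footpath, footpath_angles):
        recs = {
            m: simulate_stepping(
                footpath, LoadSchedule(added_mass=m), seed=None, angles=footpath_angles
            )
            for m in (0.0, 0.5, 1.0)
        }
        peaks = [np.abs(recs[m].clean[:, 0]).max() for m in (0.0, 0.5, 1.0)]
        assert peaks[0] < peaks[1] < peaks[2]
        # shape preserved: waveforms stay strongly correlated as mass grows
        base = recs[0.0].clean[:, 0]
        heavy = recs[1.0].clean[:, 0]
        assert np.corrcoef(base, heavy)[0, 1] > 0.98

    def test_tf_axial_is_largest_channel(self, footpath, footpath_angles):
        rec = simulate_stepping(footpath, LoadSchedule(), seed=None, angles=footpath_angles)
        amps = np.abs(rec.clean).max(axis=0)
        assert np.argmax(amps) == CHANNELS.index("tf_axial")
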