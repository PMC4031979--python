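"""Controller decision logic: profiles, safety rules, closed-loop behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oxyloop.controller import (
    DEFAULT_MH,
    DEFAULT_SH,
    ControllerConfig,
    ControllerState,
    FiO2Controller,
    Profile,
    Reason,
    propose,
    select_profile,
    spo2_error,
    table_step,
    update_effective_fio2,
    validate_profile_pair,
)
from oxyloop.physiology import VirtualPatient
from oxyloop.sensor import Oximeter
from conftest import make_sample


def fresh_state(fio2=0.40, t=0.0, lockout=30.0) -> ControllerState:
    return ControllerState(
        fio2_current=fio2, fio2_effective_est=fio2, last_change_t=t - lockout
    )


class TestConfig:
    def test_default_setpoint_is_band_midpoint(self, config):
        assert config.setpoint == 94.0
        assert config.spo2_low == 92.0 and config.spo2_high == 96.0

    def test_printed_safety_constants(self, config):
        assert config.rescue_spo2 == 85.0
        assert config.rescue_fio2 == 1.0
        assert config.lockout_s == 30.0
        assert config.siq_min == 0.30

    def test_invalid_band_rejected(self):
        with pytest.raises(Exception):
            ControllerConfig(spo2_low=96.0, spo2_high=92.0)
        with pytest.raises(Exception):
            ControllerConfig(rescue_spo2=93.0)


class TestError:
    @pytest.mark.parametrize("spo2, expected", [(94, 0.0), (90, -4.0), (98, 4.0)])
    def test_deviation_from_setpoint(self, config, spo2, expected):
        assert spo2_error(make_sample(spo2=spo2), config) == expected

    def test_invalid_sample_rejected(self, config):
        with pytest.raises(ValueError):
            spo2_error(make_sample(siq=0.1), config)
        with pytest.raises(ValueError):
            spo2_error(make_sample(spo2=None, signal_present=False), config)


class TestProfiles:
    @pytest.mark.parametrize(
        "profile, delta, expected",
        [
            (DEFAULT_SH, 0, 0.0),
            (DEFAULT_SH, -4, 0.10),
            (DEFAULT_MH, -4, 0.05),
            (DEFAULT_SH, -3, 0.05),
            (DEFAULT_SH, -8, 0.20),
            (DEFAULT_SH, -12, 0.30),
            (DEFAULT_SH, 2, 0.0),
            (DEFAULT_SH, -2, 0.0),
            (DEFAULT_SH, 3, -0.03),
            (DEFAULT_MH, 5, -0.04),
        ],
    )
    def test_table_lookup(self, profile, delta, expected):
        assert table_step(profile, delta) == pytest.approx(expected)

    def test_severe_profile_dominates_every_bin(self):
        validate_profile_pair(DEFAULT_SH, DEFAULT_MH)
        for d in range(-20, 21):
            assert abs(DEFAULT_SH.step(d)) >= abs(DEFAULT_MH.step(d))

    @given(st.integers(min_value=-30, max_value=30))
    def test_sign_convention(self, delta):
        """Below target steps up, above target steps down, dead band holds."""
        for prof in (DEFAULT_SH, DEFAULT_MH):
            s = prof.step(delta)
            if -2 <= delta <= 2:
                assert s == 0.0
            elif delta < -2:
                assert s > 0.0
            else:
                assert s < 0.0

    def test_malformed_tables_rejected(self):
        with pytest.raises(ValueError):
            Profile("X", (-4.0, 2.0), (0.1, 0.05, 0.0))  # no zero bin at 0
        with pytest.raises(ValueError):
            Profile("X", (-4.0, 2.0, 3.0), (0.05, 0.0, -0.02, -0.01, 0.0))
        with pytest.raises(ValueError):
            validate_profile_pair(DEFAULT_MH, DEFAULT_SH)  # dominance reversed


class TestPropose:
    def test_rescue_bypasses_lockout(self, config, sh):
        state = fresh_state(0.40, t=100.0, lockout=1.0)  # changed 1 s ago
        proposal, new, reason = propose(state, make_sample(t=100.0, spo2=84), 100.0, config, sh)
        assert proposal == 1.0
        assert reason is Reason.RESCUE
        assert new.fio2_current == 1.0

    def test_low_siq_keeps_last_fio2(self, config, sh):
        state = fresh_state(0.40)
        proposal, new, reason = propose(state, make_sample(spo2=80, siq=0.20), 0.0, config, sh)
        assert proposal == 0.40
        assert reason is Reason.HOLD_SIQ
        assert new.fio2_current == 0.40

    def test_lockout_holds(self, config, sh):
        state = ControllerState(fio2_current=0.40, fio2_effective_est=0.40, last_change_t=80.0)
        proposal, _, reason = propose(state, make_sample(t=100.0, spo2=90), 100.0, config, sh)
        assert proposal == 0.40
        assert reason is Reason.HOLD_LOCKOUT

    def test_in_target_holds_and_bleeds_integrator(self, config, sh):
        state = ControllerState(
            fio2_current=0.40, fio2_effective_est=0.40, last_change_t=-30.0, integrator=0.03
        )
        proposal, new, reason = propose(state, make_sample(spo2=94), 0.0, config, sh)
        assert proposal == 0.40
        assert reason is Reason.HOLD_IN_TARGET
        assert new.integrator == 0.0

    def test_step_applies_table_with_dampening(self, config, sh):
        state = fresh_state(0.40)
        proposal, new, reason = propose(state, make_sample(spo2=90), 0.0, config, sh)
        # error -4 -> SH +0.10, estimator converged -> no dampening, small I term
        assert reason is Reason.STEP
        assert proposal == pytest.approx(0.51, abs=1e-9)
        assert new.last_change_t == 0.0

    def test_lagging_estimate_shrinks_correction(self, config, sh):
        lagged = ControllerState(fio2_current=0.50, fio2_effective_est=0.35, last_change_t=-30.0)
        settled = ControllerState(fio2_current=0.50, fio2_effective_est=0.50, last_change_t=-30.0)
        p_lag, _, _ = propose(lagged, make_sample(spo2=90), 0.0, config, sh)
        p_set, _, _ = propose(settled, make_sample(spo2=90), 0.0, config, sh)
        assert p_lag - 0.50 < p_set - 0.50

    @given(
        st.integers(min_value=0, max_value=100),
        st.floats(min_value=0.21, max_value=1.0),
        st.floats(min_value=0.21, max_value=1.0),
        st.floats(min_value=-0.05, max_value=0.05),
    )
    def test_proposal_always_clamped(self, spo2, fio2, est, integ):
        """Every proposal lies in [0.21, 1.00] whatever the state."""
        config, sh = ControllerConfig(), DEFAULT_SH
        state = ControllerState(
            fio2_current=fio2, fio2_effective_est=est, last_change_t=-30.0, integrator=integ
        )
        proposal, _, _ = propose(state, make_sample(spo2=spo2), 0.0, config, sh)
        assert 0.21 <= proposal <= 1.0

    @given(st.floats(min_value=0.21, max_value=1.0), st.integers(min_value=0, max_value=84))
    def test_rescue_dominance(self, fio2, spo2):
        """A valid sample below 85% always yields a 100% proposal."""
        config, mh = ControllerConfig(), DEFAULT_MH
        state = ControllerState(fio2_current=fio2, fio2_effective_est=fio2, last_change_t=-1.0)
        proposal, _, reason = propose(state, make_sample(spo2=spo2), 0.0, config, mh)
        assert proposal == 1.0
        assert reason is Reason.RESCUE


class TestEffectiveFiO2Estimator:
    def test_fixed_point(self):
        s = ControllerState(fio2_current=0.5, fio2_effective_est=0.5, last_change_t=0.0)
        assert update_effective_fio2(s, 10.0).fio2_effective_est == pytest.approx(0.5)

    def test_step_response_one_time_constant(self):
        s = ControllerState(fio2_current=1.0, fio2_effective_est=0.21, last_change_t=0.0)
        est = update_effective_fio2(s, 60.0, tau=60.0).fio2_effective_est
        assert est == pytest.approx(0.21 + (1 - math.exp(-1)) * 0.79, abs=1e-9)

    def test_asymptote(self):
        s = ControllerState(fio2_current=1.0, fio2_effective_est=0.21, last_change_t=0.0)
        assert update_effective_fio2(s, 1e5).fio2_effective_est == pytest.approx(1.0, abs=1e-6)


class TestProfileSelection:
    @pytest.mark.parametrize(
        "pf, name", [(160.0, "SH"), (239.0, "MH"), (199.9, "SH"), (200.0, "MH")]
    )
    def test_threshold_200(self, pf, name):
        assert select_profile(pf).name == name

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            select_profile(0.0)


class TestControllerLoop:
    def run_stream(self, spo2_value, seconds, siq=0.98, fio2_init=0.40, config=None):
        ctl = FiO2Controller(config or ControllerConfig(), DEFAULT_SH, fio2_init=fio2_init)
        changes = []
        for t in range(1, seconds + 1):
            d = ctl.observe(make_sample(t=float(t), spo2=spo2_value, siq=siq))
            if d is not None and d.proposal != d.fio2_before:
                changes.append((t, d.proposal, d.reason))
        return ctl, changes

    def test_persistent_error_changes_every_lockout(self):
        _, changes = self.run_stream(89, 600)
        times = [t for t, _, _ in changes]
        assert len(times) >= 5
        assert min(np.diff(times)) == 30

    def test_all_low_siq_freezes_fio2(self):
        ctl, changes = self.run_stream(80, 600, siq=0.10)
        assert changes == []
        assert ctl.fio2_current == 0.40

    def test_rescue_is_immediate_not_on_tick(self):
        ctl = FiO2Controller(ControllerConfig(), DEFAULT_SH, fio2_init=0.40)
        d30 = ctl.observe(make_sample(t=30.0, spo2=94))
        assert d30.reason is Reason.HOLD_IN_TARGET
        d31 = ctl.observe(make_sample(t=31.0, spo2=84))
        assert d31 is not None and d31.proposal == 1.0 and d31.reason is Reason.RESCUE

    def test_nontick_valid_samples_do_not_decide(self):
        ctl = FiO2Controller(ControllerConfig(), DEFAULT_SH, fio2_init=0.40)
        assert ctl.observe(make_sample(t=7.0, spo2=90)) is None

    @pytest.mark.parametrize("start", [1.0, 0.21, 0.60])
    def test_closed_loop_settles_without_oscillation(self, start, moderate_params, quiet_sensor):
        """Noiseless static loop: reach 92-96% inside 15 min, then stay.

        After first entering the band the FiO2 trace shows no direction
        reversals (anti-windup / dampening sanity check).
        """
        vp = VirtualPatient(moderate_params, fio2_init=start)
        ctl = FiO2Controller(ControllerConfig(), DEFAULT_MH, fio2_init=start)
        ox = Oximeter(quiet_sensor)
        entered = None
        deltas = []
        for t in range(1800):
            vp.step(ctl.fio2_current, 1.0)
            s = ox.sample(float(t), vp.probe_sao2)
            d = ctl.observe(s)
            if d is not None and d.proposal != d.fio2_before:
                deltas.append(d.proposal - d.fio2_before)
            in_band = 92 <= s.spo2 <= 96
            if in_band and entered is None:
                entered = t
            if entered is not None:
                assert in_band, f"left the band at t={t}s after entering at {entered}s"
        assert entered is not None and entered <= 900
        signs = np.sign(deltas)
        assert np.all(signs == signs[0]) if len(signs) else True
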