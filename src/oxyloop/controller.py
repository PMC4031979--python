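"""SpO2-targeted FiO2 controller.

The controller compares the displayed SpO2 with the midpoint of the target
band (92–96% -> setpoint 94%) and proposes FiO2 step changes taken from one
of two deviation-to-step tables ("profiles"):

* **SH** — for severely hypoxemic patients (PaO2/FiO2 < 200 mm Hg), with
  larger up-steps because intrapulmonary shunt blunts their response to
  FiO2 changes;
* **MH** — for moderately hypoxemic patients (PaO2/FiO2 >= 200 mm Hg),
  with gentler steps.

Safety rules, in decision priority order:

1. *Rescue*: a valid sample with SpO2 < 85% immediately yields a 100% FiO2
   proposal, bypassing the lockout.
2. *Signal-quality fall-back*: while the signal is absent or SIQ < 0.30,
   the last FiO2 is kept.
3. *Lockout*: after any FiO2 change, 30 s must expire before the next
   non-rescue change.
4. Otherwise a dampened PID correction is applied: the proportional term is
   the table step, a small clamped integral term accumulates sustained
   error, and the whole correction is scaled down while the estimated
   effective (alveolar) FiO2 still lags the set FiO2 — this realizes the
   dampening against physiological and technical delays that permits safe
   30-s decision ticks.

Proposals are emitted on 30-s decision ticks; rescue is evaluated on every
1-Hz sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .sensor import OximeterSample

__all__ = [
    "Reason",
    "Profile",
    "DEFAULT_SH",
    "DEFAULT_MH",
    "validate_profile_pair",
    "ControllerConfig",
    "ControllerState",
    "Decision",
    "spo2_error",
    "table_step",
    "update_effective_fio2",
    "propose",
    "select_profile",
    "FiO2Controller",
]


class Reason(str, Enum):
    """Why the controller proposed (or held) a given FiO2."""

    RESCUE = "RESCUE"
    STEP = "STEP"
    HOLD_LOCKOUT = "HOLD_LOCKOUT"
    HOLD_SIQ = "HOLD_SIQ"
    HOLD_IN_TARGET = "HOLD_IN_TARGET"


@dataclass(frozen=True)
class Profile:
    """A deviation-to-step table.

    Bins are half-open ``(lo, hi]`` over the signed SpO2 deviation
    (SpO2 - setpoint, in %): ``edges`` are the inclusive upper bounds of
    the first ``len(edges)`` bins and ``steps`` has one more entry for the
    open top bin.  Negative deviations (below target) map to positive FiO2
    steps.  The bin containing deviation 0 must have step 0 (the in-target
    dead band).
    """

    name: str
    edges: tuple[float, ...]
    steps: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.edges) + 1:
            raise ValueError(f"profile {self.name}: need len(edges)+1 steps")
        if list(self.edges) != sorted(self.edges):
            raise ValueError(f"profile {self.name}: edges must be ascending")
        if self.step(0.0) != 0.0:
            raise ValueError(f"profile {self.name}: bin containing 0 must have step 0")
        steps = list(self.steps)
        if any(b > a for a, b in zip(steps, steps[1:])):
            raise ValueError(f"profile {self.name}: steps must be non-increasing with deviation")
        for e, s in zip(self.edges, self.steps):
            if e < 0 and s < 0:
                raise ValueError(f"profile {self.name}: below-target bin (<= {e}) must not step down")
        if self.steps[-1] > 0:
            raise ValueError(f"profile {self.name}: top bin must not step up")

    def step(self, delta_spo2: float) -> float:
        """FiO2 step (signed fraction) for a signed SpO2 deviation."""
        idx = int(np.searchsorted(self.edges, delta_spo2, side="left"))
        return self.steps[idx]


#: Default tables. Bin edges (upper, inclusive) over integer deviations:
#:   <= -9 | -8,-7 | -6,-5,-4 | -3 | -2..+2 (dead band) | +3 | >= +4
_DEFAULT_EDGES = (-9.0, -7.0, -4.0, -3.0, 2.0, 3.0)
DEFAULT_SH = Profile("SH", _DEFAULT_EDGES, (0.30, 0.20, 0.10, 0.05, 0.00, -0.03, -0.05))
DEFAULT_MH = Profile("MH", _DEFAULT_EDGES, (0.15, 0.10, 0.05, 0.02, 0.00, -0.02, -0.04))


def validate_profile_pair(sh: Profile, mh: Profile) -> None:
    """Check the severe profile dominates the moderate one in every bin.

    Raises ``ValueError`` naming the offending bin if |SH step| < |MH step|
    anywhere.  Tables with different edges are compared on integer
    deviations -20..20.
    """
    if sh.edges == mh.edges:
        for i, (a, b) in enumerate(zip(sh.steps, mh.steps)):
            if abs(a) < abs(b):
                raise ValueError(f"profile dominance violated in bin {i}: |SH {a}| < |MH {b}|")
    else:
        for d in range(-20, 21):
            if abs(sh.step(d)) < abs(mh.step(d)):
                raise ValueError(
                    f"profile dominance violated at deviation {d}: "
                    f"|SH {sh.step(d)}| < |MH {mh.step(d)}|"
                )


class ControllerConfig(BaseModel):
    """Controller constants.  Defaults are the device's printed settings:
    target band 92–96% (setpoint 94%), rescue 100% FiO2 at SpO2 < 85%,
    30-s lockout and decision tick, SIQ cutoff 0.30."""

    model_config = {"frozen": True}

    spo2_low: float = 92.0
    spo2_high: float = 96.0
    setpoint: float | None = None  # derived midpoint unless given explicitly
    rescue_spo2: float = 85.0
    rescue_fio2: float = 1.0
    lockout_s: float = Field(30.0, gt=0.0)
    decision_interval_s: float = Field(30.0, gt=0.0)
    siq_min: float = Field(0.30, ge=0.0, le=1.0)
    fio2_min: float = 0.21
    fio2_max: float = 1.0
    profile_id: str = Field("MH", pattern="^(SH|MH)$")
    # PID / dampening internals (the device's unpublished constants; all tunable)
    ki: float = Field(0.002, ge=0.0, description="integral gain, FiO2 fraction per %*tick")
    kd: float = Field(0.0, ge=0.0, description="derivative gain (off by default)")
    integrator_clamp: float = Field(0.05, ge=0.0, description="anti-windup clamp on the I term")
    damp_scale: float = Field(0.2, gt=0.0, description="FiO2 lag at which corrections vanish")
    effective_tau_s: float = Field(60.0, gt=0.0, description="effective-FiO2 estimator time constant")
    fio2_resolution: float = Field(0.01, gt=0.0, description="ventilator FiO2 setting granularity")

    @model_validator(mode="after")
    def _check(self) -> "ControllerConfig":
        if self.setpoint is None:
            object.__setattr__(self, "setpoint", (self.spo2_low + self.spo2_high) / 2.0)
        if not self.spo2_low < self.setpoint < self.spo2_high:
            raise ValueError("require spo2_low < setpoint < spo2_high")
        if not self.rescue_spo2 < self.spo2_low:
            raise ValueError("require rescue_spo2 < spo2_low")
        if not self.fio2_min < self.fio2_max:
            raise ValueError("require fio2_min < fio2_max")
        return self


@dataclass(frozen=True)
class ControllerState:
    """Controller memory between decisions."""

    fio2_current: float
    fio2_effective_est: float
    last_change_t: float
    integrator: float = 0.0
    last_valid_fio2: float | None = None

    def __post_init__(self) -> None:
        if self.last_valid_fio2 is None:
            object.__setattr__(self, "last_valid_fio2", self.fio2_current)


@dataclass(frozen=True)
class Decision:
    """One emitted proposal."""

    t: float
    proposal: float
    reason: Reason
    fio2_before: float


def _is_valid(sample: OximeterSample, config: ControllerConfig) -> bool:
    return sample.valid and sample.siq >= config.siq_min


def spo2_error(sample: OximeterSample, config: ControllerConfig) -> float:
    """Signed deviation SpO2 - setpoint (%).  Requires a valid sample."""
    if not _is_valid(sample, config):
        raise ValueError("spo2_error requires a valid sample; route invalid samples to the hold path")
    return float(sample.spo2) - config.setpoint


def table_step(profile: Profile, delta_spo2: float) -> float:
    """Step (signed FiO2 fraction) of the bin containing ``delta_spo2``."""
    return profile.step(delta_spo2)


def update_effective_fio2(state: ControllerState, dt: float, tau: float = 60.0) -> ControllerState:
    """Relax the effective-FiO2 estimate toward the set FiO2 (first order)."""
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    alpha = 1.0 - math.exp(-dt / tau)
    est = state.fio2_effective_est + (state.fio2_current - state.fio2_effective_est) * alpha
    return replace(state, fio2_effective_est=est)


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(hi, max(lo, x))


def propose(
    state: ControllerState,
    sample: OximeterSample,
    t: float,
    config: ControllerConfig,
    profile: Profile,
) -> tuple[float, ControllerState, Reason]:
    """One controller decision.  Total: every input resolves to a proposal.

    Priority: rescue > signal-quality hold > lockout > table/PID step (or
    in-target hold).  The caller is responsible for invoking this on
    decision ticks (and immediately on rescue conditions).
    """
    if t < state.last_change_t:
        raise ValueError("time must not run backwards past the last change")
    valid = _is_valid(sample, config)

    if valid and sample.spo2 < config.rescue_spo2:
        proposal = config.rescue_fio2
        new = replace(
            state,
            fio2_current=proposal,
            integrator=0.0,
            last_valid_fio2=proposal,
            last_change_t=t if proposal != state.fio2_current else state.last_change_t,
        )
        return proposal, new, Reason.RESCUE

    if not valid:
        return state.last_valid_fio2, state, Reason.HOLD_SIQ

    if t - state.last_change_t < config.lockout_s:
        return state.fio2_current, replace(state, last_valid_fio2=state.fio2_current), Reason.HOLD_LOCKOUT

    error = float(sample.spo2) - config.setpoint
    p_term = table_step(profile, error)
    if p_term == 0.0:
        # inside the dead band: hold, bleed off the integrator
        new = replace(state, integrator=0.0, last_valid_fio2=state.fio2_current)
        return state.fio2_current, new, Reason.HOLD_IN_TARGET

    integ = _clamp(state.integrator - config.ki * error, -config.integrator_clamp, config.integrator_clamp)
    damp = max(0.0, 1.0 - abs(state.fio2_current - state.fio2_effective_est) / config.damp_scale)
    correction = (p_term + integ) * damp
    res = config.fio2_resolution
    proposal = _clamp(
        round((state.fio2_current + correction) / res) * res,
        config.fio2_min,
        config.fio2_max,
    )
    proposal = round(proposal, 6)
    new = replace(
        state,
        fio2_current=proposal,
        integrator=integ,
        last_valid_fio2=proposal,
        last_change_t=t if proposal != state.fio2_current else state.last_change_t,
    )
    return proposal, new, Reason.STEP


def select_profile(pf_ratio: float) -> Profile:
    """Pick the profile from the baseline PaO2/FiO2 ratio.

    The classic 200 mm Hg threshold separates severe (SH) from moderate
    (MH) hypoxemia; exactly 200 takes the gentler MH profile.
    """
    if pf_ratio <= 0.0:
        raise ValueError("PaO2/FiO2 ratio must be positive")
    return DEFAULT_SH if pf_ratio < 200.0 else DEFAULT_MH


class FiO2Controller:
    """Stateful wrapper running the decision logic on a 1-Hz sample stream.

    ``observe`` must be called once per second; it returns a
    :class:`Decision` on decision ticks (every ``decision_interval_s``) and
    immediately when the rescue rule fires, ``None`` otherwise.  In
    open-loop use a nurse may deviate from proposals and external forcing
    (suction preoxygenation) may change the set FiO2: report the actually
    applied value through :meth:`sync_applied`.
    """

    def __init__(
        self,
        config: ControllerConfig | None = None,
        profile: Profile | None = None,
        fio2_init: float = 0.30,
        t0: float = 0.0,
    ):
        self.config = config if config is not None else ControllerConfig()
        if profile is None:
            profile = DEFAULT_SH if self.config.profile_id == "SH" else DEFAULT_MH
        self.profile = profile
        # start outside lockout so the first tick may act
        self.state = ControllerState(
            fio2_current=fio2_init,
            fio2_effective_est=fio2_init,
            last_change_t=t0 - self.config.lockout_s,
        )
        self._t_prev = t0
        self._t0 = t0

    @property
    def fio2_current(self) -> float:
        return self.state.fio2_current

    def sync_applied(self, fio2_applied: float) -> None:
        """Adopt an externally applied FiO2 (nurse override, preoxygenation)."""
        if fio2_applied != self.state.fio2_current:
            self.state = replace(
                self.state, fio2_current=fio2_applied, last_valid_fio2=fio2_applied
            )

    def observe(self, sample: OximeterSample) -> Decision | None:
        t = sample.t
        dt = t - self._t_prev
        if dt > 0.0:
            self.state = update_effective_fio2(self.state, dt, self.config.effective_tau_s)
        self._t_prev = t

        rescue_now = _is_valid(sample, self.config) and sample.spo2 < self.config.rescue_spo2
        on_tick = (t - self._t0) % self.config.decision_interval_s == 0.0 and t > self._t0
        if not on_tick and not (rescue_now and self.state.fio2_current != self.config.rescue_fio2):
            return None
        before = self.state.fio2_current
        proposal, self.state, reason = propose(self.state, sample, t, self.config, self.profile)
        return Decision(t=t, proposal=proposal, reason=reason, fio2_before=before)
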