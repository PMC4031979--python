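"""Closed-loop experiment orchestration.

Builds virtual-patient cohorts in two severity strata, runs 1-Hz
closed-loop episodes (sensor sample -> policy decision on 30-s ticks ->
FiO2 applied -> patient stepped), injects disturbances (transient-shunt
desaturation events, endotracheal suctioning with preoxygenation to 100%
FiO2), and drives the two-profile crossover comparison plus a usual-care
baseline.

Everything is seeded: the same seed regenerates an episode bit for bit.
The usual-care policy is an explicit caricature of manual FiO2 management
(periodic checks, alarm-driven increases, reluctant decreases), not a fit
to any recorded nurse behavior; outputs label it as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .controller import (
    DEFAULT_MH,
    DEFAULT_SH,
    ControllerConfig,
    FiO2Controller,
    Profile,
    select_profile,
)
from .evaluation import RangeSummary, suction_mask, time_in_ranges
from .io import EpisodeRecord, config_hash
from .physiology import PatientParams, VirtualPatient, pf_ratio
from .sensor import Oximeter, OximeterSample, SensorParams

__all__ = [
    "Stratum",
    "SEVERE",
    "MODERATE",
    "TrialPlan",
    "CohortPatient",
    "draw_patient",
    "draw_cohort",
    "ControllerPolicy",
    "UsualCarePolicy",
    "run_episode",
    "run_crossover",
    "run_comparison",
    "matched_mean_in_target",
]


@dataclass(frozen=True)
class Stratum:
    """A severity stratum: shunt range and the clinical baseline FiO2 at
    which the admission PaO2/FiO2 ratio is taken."""

    name: str
    shunt_range: tuple[float, float]
    baseline_fio2: float


#: Severe stratum: shunt ~ U(0.20, 0.30), baseline FiO2 0.40 (PF < 200).
SEVERE = Stratum("severe", (0.20, 0.30), 0.40)
#: Moderate stratum: shunt ~ U(0.05, 0.15), baseline FiO2 0.30 (PF >= 200).
MODERATE = Stratum("moderate", (0.05, 0.15), 0.30)
_STRATA = {s.name: s for s in (SEVERE, MODERATE)}


class TrialPlan(BaseModel):
    """Conditions of one simulated crossover trial."""

    model_config = {"frozen": True}

    n_severe: int = Field(10, ge=0)
    n_moderate: int = Field(10, ge=0)
    period_h: float = Field(3.0, gt=0.0, description="duration of each profile period")
    suction_per_period: int = Field(2, ge=0)
    suction_force_s: float = Field(180.0, gt=0.0, description="preoxygenation + suction at FiO2 1.0")
    suction_window_min: float = Field(15.0, gt=0.0, description="exclusion window per episode")
    desat_rate_per_h: float = Field(1.0, ge=0.0, description="Poisson arrival rate")
    desat_magnitude: tuple[float, float] = (0.10, 0.25)
    desat_duration_s: tuple[float, float] = (120.0, 600.0)
    sensor: SensorParams = Field(default_factory=SensorParams)
    controller: ControllerConfig = Field(default_factory=ControllerConfig)


@dataclass(frozen=True)
class CohortPatient:
    """One virtual trial participant."""

    patient_id: int
    stratum: str
    params: PatientParams
    baseline_fio2: float
    pf_baseline: float


def draw_patient(patient_id: int, stratum: Stratum, rng: np.random.Generator) -> CohortPatient:
    lo, hi = stratum.shunt_range
    params = PatientParams(shunt_fraction=float(rng.uniform(lo, hi)))
    return CohortPatient(
        patient_id=patient_id,
        stratum=stratum.name,
        params=params,
        baseline_fio2=stratum.baseline_fio2,
        pf_baseline=pf_ratio(params, stratum.baseline_fio2),
    )


def draw_cohort(plan: TrialPlan, rng: np.random.Generator) -> list[CohortPatient]:
    """Severe patients first, then moderate; ids are 0-based."""
    cohort = [draw_patient(i, SEVERE, rng) for i in range(plan.n_severe)]
    cohort += [
        draw_patient(plan.n_severe + i, MODERATE, rng) for i in range(plan.n_moderate)
    ]
    return cohort


class Policy(Protocol):
    fio2_set: float

    def observe(self, sample: OximeterSample) -> None: ...
    def sync_applied(self, fio2: float) -> None: ...
    @property
    def proposed(self) -> float | None: ...
    @property
    def last_reason(self) -> str: ...


class ControllerPolicy:
    """The automated controller followed faithfully (open-loop adherence 1)."""

    name = "controller"

    def __init__(self, config: ControllerConfig, profile: Profile, fio2_init: float):
        self.controller = FiO2Controller(config, profile, fio2_init=fio2_init)
        self.fio2_set = fio2_init
        self._proposed = fio2_init
        self._reason = ""

    def observe(self, sample: OximeterSample) -> None:
        decision = self.controller.observe(sample)
        self._reason = ""
        if decision is not None:
            self._proposed = decision.proposal
            self.fio2_set = decision.proposal
            self._reason = decision.reason.value

    def sync_applied(self, fio2: float) -> None:
        self.fio2_set = fio2
        self.controller.sync_applied(fio2)

    @property
    def proposed(self) -> float | None:
        return self._proposed

    @property
    def last_reason(self) -> str:
        return self._reason


class UsualCarePolicy:
    """Caricature of manual FiO2 management for the historical baseline.

    Raises FiO2 by ``raise_step`` when a low-SpO2 alarm (below
    ``alarm_spo2``) has been sounding for ``alarm_sustain_s`` seconds (with
    a refractory period, the nurse having other duties), and lowers it by
    ``lower_step`` only at periodic checks when SpO2 is at or above
    ``lower_spo2``.  No proposals column is produced: ``proposed`` is None.
    """

    name = "usual_care"

    def __init__(
        self,
        fio2_init: float,
        check_interval_min: float = 30.0,
        raise_step: float = 0.10,
        lower_step: float = 0.05,
        alarm_spo2: float = 92.0,
        lower_spo2: float = 98.0,
        alarm_sustain_s: float = 30.0,
        alarm_refractory_s: float = 300.0,
    ):
        self.fio2_set = fio2_init
        self.check_interval_s = check_interval_min * 60.0
        self.raise_step = raise_step
        self.lower_step = lower_step
        self.alarm_spo2 = alarm_spo2
        self.lower_spo2 = lower_spo2
        self.alarm_sustain_s = alarm_sustain_s
        self.alarm_refractory_s = alarm_refractory_s
        self._below_since: float | None = None
        self._last_raise = -np.inf
        self._reason = ""

    def observe(self, sample: OximeterSample) -> None:
        t = sample.t
        self._reason = ""
        if sample.valid and sample.spo2 < self.alarm_spo2:
            if self._below_since is None:
                self._below_since = t
            sustained = t - self._below_since >= self.alarm_sustain_s
            if sustained and t - self._last_raise >= self.alarm_refractory_s:
                self.fio2_set = min(1.0, self.fio2_set + self.raise_step)
                self._last_raise = t
                self._reason = "UC_RAISE"
        else:
            self._below_since = None
        if t > 0 and t % self.check_interval_s == 0.0:
            if sample.valid and sample.spo2 >= self.lower_spo2:
                self.fio2_set = max(0.21, self.fio2_set - self.lower_step)
                self._reason = "UC_LOWER"

    def sync_applied(self, fio2: float) -> None:
        self.fio2_set = fio2

    @property
    def proposed(self) -> float | None:
        return None

    @property
    def last_reason(self) -> str:
        return self._reason


def _schedule_suction(plan: TrialPlan, duration: float, rng: np.random.Generator) -> list[float]:
    """Suction onset times: away from the period edges, well separated."""
    times: list[float] = []
    k = plan.suction_per_period
    lo, hi = 600.0, duration - 1500.0
    if hi <= lo or k == 0:
        return times
    sep = min(1200.0, (hi - lo) / k)
    for _ in range(500):
        if len(times) == k:
            break
        cand = float(rng.uniform(lo, hi))
        if all(abs(cand - t) >= sep for t in times):
            times.append(cand)
    return sorted(round(t) for t in times)


def _schedule_desat(
    plan: TrialPlan, duration: float, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Desaturation events as (start, end, shunt_increase)."""
    events = []
    t = 0.0
    if plan.desat_rate_per_h <= 0:
        return events
    while True:
        t += float(rng.exponential(3600.0 / plan.desat_rate_per_h))
        if t >= duration:
            return events
        dur = float(rng.uniform(*plan.desat_duration_s))
        mag = float(rng.uniform(*plan.desat_magnitude))
        events.append((round(t), min(duration, round(t + dur)), round(mag, 3)))


def run_episode(
    patient: CohortPatient,
    plan: TrialPlan,
    seed: int,
    profile: Profile | None = None,
    policy_factory: "Callable[[float], Policy] | None" = None,
) -> EpisodeRecord:
    """Simulate one episode at 1 Hz and return the full logged record.

    By default the policy is the automated controller with ``profile``
    (matched to the patient's baseline PF ratio when omitted); pass
    ``policy_factory`` (fio2_init -> policy) to run usual care instead.
    Suction events force FiO2 = 1.0 (preoxygenation + suctioning) for
    ``plan.suction_force_s`` and then hand control back to the policy.
    """
    duration = int(round(plan.period_h * 3600.0))
    ss = np.random.SeedSequence([int(seed) % (2**31), patient.patient_id])
    ev_rng, sensor_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    suctions = _schedule_suction(plan, duration, ev_rng)
    desats = _schedule_desat(plan, duration, ev_rng)

    if profile is None:
        profile = select_profile(patient.pf_baseline)
    if policy_factory is None:
        policy: Policy = ControllerPolicy(plan.controller, profile, patient.baseline_fio2)
    else:
        policy = policy_factory(patient.baseline_fio2)

    vp = VirtualPatient(patient.params, fio2_init=patient.baseline_fio2)
    ox = Oximeter(plan.sensor, rng=sensor_rng)

    suction_iv = [(s, s + plan.suction_force_s) for s in suctions]
    rows = []
    for t in range(duration):
        shunt_off = 0.0
        for a, b, m in desats:
            if a <= t < b:
                shunt_off += m
        in_suction = any(a <= t < b for a, b in suction_iv)
        applied = 1.0 if in_suction else policy.fio2_set
        vp.step(applied, 1.0, shunt_off)
        sample = ox.sample(float(t), vp.probe_sao2)
        if in_suction:
            policy.sync_applied(1.0)
            reason = "SUCTION"
        else:
            policy.observe(sample)
            reason = policy.last_reason
        rows.append(
            (
                t,
                sample.spo2,
                sample.hr,
                sample.pi,
                sample.siq,
                sample.signal_present,
                round(applied, 3),
                None if policy.proposed is None else round(policy.proposed, 3),
                reason,
            )
        )

    samples = pd.DataFrame(
        rows,
        columns=[
            "t_s",
            "spo2",
            "hr",
            "pi",
            "siq",
            "signal_present",
            "fio2_set",
            "fio2_proposed",
            "decision_reason",
        ],
    )
    for col in ("t_s", "spo2", "hr", "pi", "siq", "fio2_set", "fio2_proposed"):
        samples[col] = pd.to_numeric(samples[col])
    samples["signal_present"] = samples["signal_present"].astype(bool)
    events = pd.DataFrame(
        [("suction", a, b, None) for a, b in suction_iv]
        + [("desaturation", a, b, m) for a, b, m in desats],
        columns=["kind", "start_s", "end_s", "magnitude"],
    ).sort_values("start_s", ignore_index=True)

    metadata = {
        "seed": int(seed),
        "patient_id": patient.patient_id,
        "stratum": patient.stratum,
        "patient_params": patient.params.model_dump(),
        "baseline_fio2": patient.baseline_fio2,
        "pf_baseline": round(patient.pf_baseline, 1),
        "policy": getattr(policy, "name", "custom"),
        "policy_note": "usual-care arm is a caricature of manual titration, not fitted behavior"
        if getattr(policy, "name", "") == "usual_care"
        else "",
        "profile": profile.name if policy_factory is None else None,
        "plan": plan.model_dump(),
        "config_hash": config_hash(plan),
        "duration_s": duration,
    }
    return EpisodeRecord(metadata=metadata, samples=samples, events=events)


def episode_summary(record: EpisodeRecord, mask_suction: bool = True) -> RangeSummary:
    """Range summary of an episode, with its suction windows masked."""
    mask = None
    if mask_suction:
        ev = record.events
        onsets = [float(s) for s in ev.loc[ev["kind"] == "suction", "start_s"]]
        window = record.metadata.get("plan", {}).get("suction_window_min", 15.0)
        mask = suction_mask(onsets, window)
    return time_in_ranges(record.samples, mask)


def run_crossover(
    plan: TrialPlan,
    seed: int,
    record_sink: "Callable[[EpisodeRecord, str], None] | None" = None,
) -> pd.DataFrame:
    """Run the two-profile crossover on a fresh cohort.

    Every patient runs both profiles in randomized order (seeded stand-in
    for the sealed envelope) with independent disturbance realizations;
    suction windows are masked per the 15-min rule before summarizing.
    Returns one row per patient x profile with the range percentages,
    profile order and matched-profile flag.
    """
    root = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 777]))
    cohort = draw_cohort(plan, root)
    rows = []
    for patient in cohort:
        order = list(root.permutation(["SH", "MH"]))
        matched = select_profile(patient.pf_baseline).name
        for period_idx, prof_name in enumerate(order):
            profile = DEFAULT_SH if prof_name == "SH" else DEFAULT_MH
            ep_seed = int(seed) % (2**31 - 1) * 2 + period_idx
            record = run_episode(patient, plan, seed=ep_seed, profile=profile)
            if record_sink is not None:
                record_sink(record, f"p{patient.patient_id:02d}_{prof_name}")
            summary = episode_summary(record)
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "stratum": patient.stratum,
                    "shunt_fraction": round(patient.params.shunt_fraction, 4),
                    "pf_baseline": round(patient.pf_baseline, 1),
                    "profile": prof_name,
                    "period": period_idx,
                    "matched": prof_name == matched,
                    **summary.as_dict(),
                    "seed": int(seed),
                }
            )
    return pd.DataFrame(rows)


def matched_mean_in_target(crossover: pd.DataFrame) -> float:
    """Cohort mean % time in target, each patient under its matched profile."""
    matched = crossover[crossover["matched"]]
    return float(matched["pct_normoxemia"].mean())


def run_comparison(plan: TrialPlan, seed: int) -> pd.DataFrame:
    """Paired controller-vs-usual-care comparison on identical disturbances.

    Each patient is simulated twice from the same episode seed (identical
    suction/desaturation schedules and sensor noise): once under the
    matched-profile controller, once under the usual-care caricature.
    """
    root = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 778]))
    cohort = draw_cohort(plan, root)
    rows = []
    for patient in cohort:
        ep_seed = int(seed) % (2**31 - 1) * 2 + 1
        for arm, factory in (
            ("controller", None),
            ("usual_care", lambda f: UsualCarePolicy(f)),
        ):
            record = run_episode(patient, plan, seed=ep_seed, policy_factory=factory)
            summary = episode_summary(record)
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "stratum": patient.stratum,
                    "arm": arm,
                    **summary.as_dict(),
                    "seed": int(seed),
                }
            )
    return pd.DataFrame(rows)
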