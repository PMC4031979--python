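"""Virtual-patient oxygen-transport model.

Maps a delivered FiO2 history to an arterial oxygen-saturation trajectory
through three classical pieces:

* the (simplified) alveolar gas equation,
  ``PAO2 = FiO2 * (Pb - 47) - PaCO2 / R``;
* the Severinghaus closed-form oxyhemoglobin dissociation curve,
  ``S = 1 / (1 + 23400 / (P^3 + 150 P))``;
* a single-compartment venous-admixture (shunt) mass balance on oxygen
  content, ``CaO2 = Cc'O2 - s * avDO2 / (1 - s)``.

The model is deliberately minimal — one shunt compartment, a first-order
alveolar wash-in and a pure lung-to-probe transport delay — but it captures
the property that matters for FiO2 titration: the higher the intrapulmonary
shunt, the smaller the SaO2 response to a given FiO2 step, so severely
hypoxemic patients need larger FiO2 changes than moderately hypoxemic ones.

FiO2 is a fraction in [0.21, 1.0] everywhere in this package; percent
appears only at user interfaces.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field
from scipy.optimize import brentq

__all__ = [
    "ModelError",
    "PatientParams",
    "PatientState",
    "severinghaus_sao2",
    "pao2_from_sao2",
    "alveolar_po2",
    "o2_content",
    "shunt_arterial_content",
    "arterial_po2",
    "equilibrium_state",
    "step_patient",
    "fio2_for_sao2",
    "pf_ratio",
    "VirtualPatient",
]

#: Severinghaus (1979) constant: P^3 + 150 P at 50% saturation equals 23400.
_SEV_K = 23400.0

FIO2_MIN = 0.21
FIO2_MAX = 1.0


class ModelError(RuntimeError):
    """Gas-exchange model failure (non-physical state or failed inversion)."""


class PatientParams(BaseModel):
    """Static gas-exchange parameters of one virtual patient.

    Defaults describe a mechanically ventilated adult ICU patient with
    mild anemia and normocapnia; severity is set almost entirely by
    ``shunt_fraction``.
    """

    model_config = {"frozen": True}

    shunt_fraction: float = Field(0.15, ge=0.0, le=0.95, description="venous admixture fraction")
    hb: float = Field(11.0, gt=0.0, description="hemoglobin, g/dl")
    paco2: float = Field(40.0, gt=0.0, description="arterial CO2 tension, mm Hg")
    barometric_pressure: float = Field(760.0, gt=0.0, description="mm Hg")
    resp_quotient: float = Field(0.8, gt=0.0, description="respiratory quotient (dimensionless)")
    av_o2_diff: float = Field(5.0, gt=0.0, description="arteriovenous O2 content difference, ml O2/dl")
    tau_alveolar: float = Field(45.0, gt=0.0, description="alveolar FiO2 wash-in time constant, s")
    circ_delay: float = Field(15.0, ge=0.0, description="lung-to-probe circulatory delay, s")


@dataclass(frozen=True)
class PatientState:
    """Instantaneous gas-exchange state (saturation as a fraction)."""

    t: float
    fio2_effective: float
    pao2: float
    sao2: float


def _sev(p: float) -> float:
    # scalar hot path, keep free of numpy dispatch
    return 1.0 / (1.0 + _SEV_K / (p * p * p + 150.0 * p))


def _sev_deriv(p: float) -> float:
    q = p * p * p + 150.0 * p + _SEV_K
    return _SEV_K * (3.0 * p * p + 150.0) / (q * q)


def severinghaus_sao2(pao2):
    """Oxyhemoglobin saturation (fraction) from PaO2 (mm Hg).

    Severinghaus closed form ``S = 1/(1 + 23400/(P^3 + 150 P))``; accurate to
    about ±0.3% saturation over the clinical range and analytically
    invertible.  Accepts scalars or arrays; strictly increasing in ``pao2``.
    """
    p = np.asarray(pao2, dtype=float)
    if np.any(p <= 0.0):
        raise ValueError("pao2 must be positive (mm Hg)")
    s = 1.0 / (1.0 + _SEV_K / (p ** 3 + 150.0 * p))
    return float(s) if np.ndim(pao2) == 0 else s


def pao2_from_sao2(sao2):
    """Exact inverse of :func:`severinghaus_sao2` (Cardano's formula).

    Solves ``P^3 + 150 P = 23400 * S / (1 - S)`` for the single real root.
    """
    s = np.asarray(sao2, dtype=float)
    if np.any((s <= 0.0) | (s >= 1.0)):
        raise ValueError("sao2 must lie strictly in (0, 1)")
    half = 0.5 * _SEV_K * s / (1.0 - s)
    disc = np.sqrt(half ** 2 + 125000.0)  # (150/3)^3 = 125000
    p = np.cbrt(half + disc) + np.cbrt(half - disc)
    return float(p) if np.ndim(sao2) == 0 else p


def alveolar_po2(fio2: float, params: PatientParams) -> float:
    """Alveolar O2 tension (mm Hg) from the simplified alveolar gas equation."""
    if not 0.0 < fio2 <= 1.0:
        raise ValueError(f"fio2 must lie in (0, 1], got {fio2}")
    pao2 = fio2 * (params.barometric_pressure - 47.0) - params.paco2 / params.resp_quotient
    if pao2 <= 0.0:
        raise ModelError(
            f"alveolar PO2 non-positive ({pao2:.1f} mm Hg) for fio2={fio2}, "
            f"paco2={params.paco2}, Pb={params.barometric_pressure}"
        )
    return pao2


def o2_content(pao2: float, sao2: float, hb: float) -> float:
    """Oxygen content, ml O2/dl: ``1.34 * Hb * SaO2 + 0.003 * PaO2``."""
    if pao2 < 0.0 or sao2 < 0.0 or hb <= 0.0:
        raise ValueError("o2_content arguments must be non-negative (hb positive)")
    return 1.34 * hb * sao2 + 0.003 * pao2


def shunt_arterial_content(end_capillary_content: float, params: PatientParams) -> float:
    """Arterial O2 content after venous admixture (Berggren mass balance).

    ``CaO2 = Cc'O2 - s * avDO2 / (1 - s)`` with ``s`` the shunt fraction.
    """
    s = params.shunt_fraction
    if s >= 1.0:
        raise ValueError("shunt_fraction must be < 1")
    ca = end_capillary_content - s * params.av_o2_diff / (1.0 - s)
    if ca <= 0.0:
        raise ModelError(
            f"arterial O2 content non-positive ({ca:.2f} ml/dl): shunt {s:.2f} too "
            f"large for end-capillary content {end_capillary_content:.2f} ml/dl"
        )
    return ca


def _invert_content(ca: float, hb: float, p_hi: float, p_guess: float | None = None) -> float:
    """Solve ``1.34*hb*S(P) + 0.003*P = ca`` for P (monotone in P).

    Newton from a warm start with a bracketed-bisection (brentq) fallback.
    The root lies in (0, p_hi] because admixture can only lower content.
    """
    k = 1.34 * hb

    def f(p: float) -> float:
        return k * _sev(p) + 0.003 * p - ca

    hi = p_hi * (1.0 + 1e-12)
    p = p_guess if p_guess is not None and 0.0 < p_guess <= hi else 0.5 * p_hi
    for _ in range(12):
        fp = f(p)
        if abs(fp) < 1e-12:
            return p
        step = fp / (k * _sev_deriv(p) + 0.003)
        p_new = p - step
        if not (1e-6 <= p_new <= hi):
            break
        if abs(p_new - p) < 1e-9:
            return p_new
        p = p_new
    else:
        return p
    try:
        return brentq(f, 1e-6, hi, xtol=1e-9)
    except ValueError as exc:  # pragma: no cover - defensive
        raise ModelError(f"PaO2 inversion failed for content {ca:.3f} ml/dl") from exc


#: Dynamic-stepping floor: below this PaO2 (profound hypoxemia, SaO2 ~32%)
#: the fixed-avDO2 admixture balance is no longer meaningful and the state
#: saturates instead of becoming non-physical.
PAO2_FLOOR = 20.0


def _arterial_pao2_scalar(
    fio2: float,
    shunt: float,
    hb: float,
    paco2: float,
    pb: float,
    rq: float,
    dav: float,
    p_guess: float | None = None,
    floor: float | None = None,
) -> float:
    pa = fio2 * (pb - 47.0) - paco2 / rq
    if pa <= 0.0:
        raise ModelError(f"alveolar PO2 non-positive for fio2={fio2:.2f}")
    cc = 1.34 * hb * _sev(pa) + 0.003 * pa
    ca = cc - shunt * dav / (1.0 - shunt)
    if floor is not None and ca <= 1.34 * hb * _sev(floor) + 0.003 * floor:
        return floor
    if ca <= 0.0:
        raise ModelError(
            f"arterial O2 content non-positive: shunt {shunt:.2f} too large at fio2 {fio2:.2f}"
        )
    return _invert_content(ca, hb, pa, p_guess)


def arterial_po2(fio2: float, params: PatientParams, shunt_offset: float = 0.0) -> float:
    """Steady-state arterial PO2 (mm Hg) at a given effective FiO2.

    Composes alveolar gas equation -> end-capillary saturation/content ->
    shunt admixture -> joint inversion of content/dissociation for PaO2.
    ``shunt_offset`` transiently adds to the baseline shunt fraction
    (used for desaturation events).
    """
    shunt = min(0.95, max(0.0, params.shunt_fraction + shunt_offset))
    return _arterial_pao2_scalar(
        fio2,
        shunt,
        params.hb,
        params.paco2,
        params.barometric_pressure,
        params.resp_quotient,
        params.av_o2_diff,
    )


def equilibrium_state(fio2: float, params: PatientParams, t: float = 0.0) -> PatientState:
    """Patient state fully equilibrated at a constant delivered FiO2."""
    p = arterial_po2(fio2, params)
    return PatientState(t=t, fio2_effective=fio2, pao2=p, sao2=_sev(p))


def step_patient(
    state: PatientState,
    fio2_set: float,
    dt: float,
    params: PatientParams,
    shunt_offset: float = 0.0,
) -> PatientState:
    """Advance the alveolar/arterial state by ``dt`` seconds.

    The effective alveolar FiO2 relaxes toward ``fio2_set`` with first-order
    time constant ``tau_alveolar``; PaO2/SaO2 are recomputed through the full
    shunt chain.  This function is pure and carries no transport delay — the
    lung-to-probe circulatory delay is applied by :class:`VirtualPatient`,
    which buffers past saturations.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    if not FIO2_MIN <= fio2_set <= FIO2_MAX:
        raise ValueError(f"fio2_set must lie in [{FIO2_MIN}, {FIO2_MAX}]")
    alpha = 1.0 - math.exp(-dt / params.tau_alveolar)
    fe = state.fio2_effective + (fio2_set - state.fio2_effective) * alpha
    shunt = min(0.95, max(0.0, params.shunt_fraction + shunt_offset))
    p = _arterial_pao2_scalar(
        fe,
        shunt,
        params.hb,
        params.paco2,
        params.barometric_pressure,
        params.resp_quotient,
        params.av_o2_diff,
        p_guess=state.pao2,
        floor=PAO2_FLOOR,
    )
    return PatientState(t=state.t + dt, fio2_effective=fe, pao2=p, sao2=_sev(p))


def fio2_for_sao2(params: PatientParams, target_sao2: float) -> float:
    """Delivered FiO2 whose steady state yields ``target_sao2`` (fraction).

    Raises :class:`ModelError` if the target is unreachable within
    [0.21, 1.0] (e.g. refractory hypoxemia from a very large shunt).
    """
    lo = equilibrium_state(FIO2_MIN, params).sao2
    hi = equilibrium_state(FIO2_MAX, params).sao2
    if not lo <= target_sao2 <= hi:
        raise ModelError(
            f"target SaO2 {target_sao2:.3f} unreachable: range [{lo:.3f}, {hi:.3f}]"
        )
    return brentq(
        lambda f: equilibrium_state(f, params).sao2 - target_sao2,
        FIO2_MIN,
        FIO2_MAX,
        xtol=1e-6,
    )


def pf_ratio(params: PatientParams, fio2: float) -> float:
    """Steady-state PaO2/FiO2 ratio (mm Hg) at a given delivered FiO2."""
    return equilibrium_state(fio2, params).pao2 / fio2


class VirtualPatient:
    """Stateful virtual patient: alveolar lag plus circulatory transport delay.

    ``step`` advances the gas-exchange state by ``dt`` (1 s in all the
    scenario code); ``probe_sao2`` is the saturation seen at the oximeter
    probe, i.e. the arterial saturation from ``circ_delay`` seconds ago
    (pure transport delay implemented as a ring buffer).
    """

    def __init__(self, params: PatientParams, fio2_init: float = FIO2_MIN):
        self.params = params
        self.state = equilibrium_state(fio2_init, params)
        n = int(round(params.circ_delay)) + 1
        self._probe: deque[float] = deque([self.state.sao2] * n, maxlen=n)

    def step(self, fio2_set: float, dt: float = 1.0, shunt_offset: float = 0.0) -> PatientState:
        self.state = step_patient(self.state, fio2_set, dt, self.params, shunt_offset)
        self._probe.append(self.state.sao2)
        return self.state

    @property
    def probe_sao2(self) -> float:
        """True saturation currently visible at the probe site."""
        return self._probe[0]
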