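"""Pulse-oximeter model.

Turns the true arterial saturation at the probe site into the sampled,
averaged, quantized and quality-annotated SpO2 stream a bedside monitor
produces: 1-Hz samples, a 2-s trailing averaging window, Gaussian reading
noise, whole-percent quantization, and two kinds of signal problems —
complete dropouts (probe off / no signal) and low signal-quality (SIQ)
episodes during which the displayed SpO2 is unreliable.

Event arrivals are Poisson with configurable rates; with a fixed seed the
whole stream is bit-reproducible.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

__all__ = ["SensorParams", "OximeterSample", "Oximeter", "sample_series"]


class SensorParams(BaseModel):
    """Oximeter noise/quality configuration.

    Defaults produce no-signal and low-SIQ fractions well under 0.5% of
    recorded time, of the order seen on well-monitored ICU patients.
    """

    model_config = {"frozen": True}

    noise_sd: float = Field(0.5, ge=0.0, description="reading noise SD, % SpO2")
    averaging_window: float = Field(2.0, gt=0.0, description="trailing average window, s")
    dropout_rate: float = Field(0.5, ge=0.0, description="no-signal events per hour")
    dropout_duration: float = Field(30.0, gt=0.0, description="no-signal event length, s")
    low_siq_rate: float = Field(0.5, ge=0.0, description="low-SIQ events per hour")
    low_siq_duration: float = Field(30.0, gt=0.0, description="low-SIQ event length, s")
    seed: int = 0


@dataclass(frozen=True)
class OximeterSample:
    """One timestamped oximeter reading with quality metadata.

    ``spo2`` is the integer displayed percent (None while no signal);
    ``siq`` is the signal index quality in [0, 1].
    """

    t: float
    spo2: int | None
    hr: float | None
    pi: float | None
    siq: float
    signal_present: bool

    @property
    def valid(self) -> bool:
        """Usable for control decisions (signal present, SpO2 displayed)."""
        return self.signal_present and self.spo2 is not None


def _quantize(x: float) -> int:
    # clinical displays round half up and clamp to [0, 100]
    return int(min(100, max(0, math.floor(x + 0.5))))


class Oximeter:
    """Stateful 1-Hz pulse-oximeter simulator.

    Call :meth:`sample` once per second with the true saturation at the
    probe; the instrument keeps its own trailing window and event clocks.
    """

    def __init__(self, params: SensorParams, rng: np.random.Generator | None = None):
        self.params = params
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        n = int(round(params.averaging_window)) + 1
        self._window: deque[float] = deque(maxlen=n)
        self._dropout_until = -1.0
        self._next_dropout = self._draw_arrival(params.dropout_rate)
        self._low_siq_until = -1.0
        self._next_low_siq = self._draw_arrival(params.low_siq_rate)
        self._hr = 82.0
        self._pi = 2.0

    def _draw_arrival(self, rate_per_h: float) -> float:
        if rate_per_h <= 0.0:
            return math.inf
        return float(self.rng.exponential(3600.0 / rate_per_h))

    def sample(self, t: float, true_sao2: float | None) -> OximeterSample:
        """Produce the oximeter reading at time ``t`` (seconds).

        ``true_sao2`` is the saturation fraction at the probe; ``None``
        signals a gap in the underlying history, which yields a no-signal
        sample rather than an error.
        """
        p = self.params
        if true_sao2 is not None:
            self._window.append(true_sao2)

        # slow vital-sign wander, purely cosmetic for logs/plots
        self._hr += float(self.rng.normal(0.0, 0.3)) - 0.01 * (self._hr - 82.0)
        self._pi += float(self.rng.normal(0.0, 0.03)) - 0.02 * (self._pi - 2.0)
        self._pi = max(0.2, self._pi)

        if t >= self._next_dropout:
            self._dropout_until = t + p.dropout_duration
            self._next_dropout = t + p.dropout_duration + self._draw_arrival(p.dropout_rate)
        if t >= self._next_low_siq:
            self._low_siq_until = t + p.low_siq_duration
            self._next_low_siq = t + p.low_siq_duration + self._draw_arrival(p.low_siq_rate)

        if t < self._dropout_until or true_sao2 is None or not self._window:
            return OximeterSample(t=t, spo2=None, hr=None, pi=None, siq=0.0, signal_present=False)

        mean_pct = 100.0 * sum(self._window) / len(self._window)
        hr = round(self._hr, 1)
        pi = round(self._pi, 2)
        if t < self._low_siq_until:
            # low-perfusion/motion conditions: reading may be arbitrary
            spo2 = _quantize(mean_pct + float(self.rng.normal(0.0, 4.0 * p.noise_sd + 2.0)))
            siq = round(float(self.rng.uniform(0.02, 0.29)), 3)
        else:
            spo2 = _quantize(mean_pct + float(self.rng.normal(0.0, p.noise_sd)))
            siq = round(float(self.rng.uniform(0.85, 1.0)), 3)
        return OximeterSample(t=t, spo2=spo2, hr=hr, pi=pi, siq=siq, signal_present=True)


def sample_series(true_sao2: "np.ndarray | list[float]", params: SensorParams) -> list[OximeterSample]:
    """Sample a full 1-Hz true-saturation series through a fresh oximeter."""
    ox = Oximeter(params)
    return [ox.sample(float(t), float(s)) for t, s in enumerate(true_sao2)]
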