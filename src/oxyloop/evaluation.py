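"""Outcome metrics for episode logs.

Computes the time-weighted percentages of recorded time spent in the
clinical SpO2 ranges — hypoxemia (<=91%), normoxemia (92–96%), hyperoxemia
(>=97%) — plus no-signal and low-SIQ time, with interval-based exclusion
masks (suction windows, aberrant readings), 6-h audit-window extraction,
nurse-adherence measurement, and thin wrappers around standard group tests.

Weighting is percentage-of-*time*, not of samples: each sample holds until
the next one (the final sample holds for one median inter-sample gap), so
logs recorded every 1–2 min and 1-Hz controller traces are treated
consistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MaskReason",
    "ExclusionMask",
    "RangeSummary",
    "time_in_ranges",
    "suction_mask",
    "filter_aberrant",
    "extract_windows",
    "adherence",
    "GroupComparison",
    "compare_groups",
    "format_summary_table",
]

#: SpO2 band edges (integer percent, inclusive): <=91 hypoxemia,
#: 92..96 normoxemia, >=97 hyperoxemia.
HYPOXEMIA_MAX = 91
NORMOXEMIA_MAX = 96
#: SIQ at or below this is reported as low-quality time.
LOW_SIQ_MAX = 0.30


class MaskReason(str, Enum):
    SUCTION = "SUCTION"
    ABERRANT = "ABERRANT"
    CUSTOM = "CUSTOM"


@dataclass(frozen=True)
class ExclusionMask:
    """Non-overlapping half-open [start, end) intervals of excluded time."""

    intervals: tuple[tuple[float, float, MaskReason], ...] = ()

    @staticmethod
    def from_intervals(
        intervals: "list[tuple[float, float]] | list[tuple[float, float, MaskReason]]",
        reason: MaskReason = MaskReason.CUSTOM,
    ) -> "ExclusionMask":
        """Build a normalized mask: sorted, overlaps of equal reason merged."""
        items = []
        for iv in intervals:
            if len(iv) == 3:
                a, b, r = iv
            else:
                a, b = iv
                r = reason
            if b > a:
                items.append((float(a), float(b), MaskReason(r)))
        items.sort()
        merged: list[tuple[float, float, MaskReason]] = []
        for a, b, r in items:
            if merged and a <= merged[-1][1] and r == merged[-1][2]:
                pa, pb, pr = merged[-1]
                merged[-1] = (pa, max(pb, b), pr)
            else:
                merged.append((a, b, r))
        return ExclusionMask(tuple(merged))

    def union(self, other: "ExclusionMask") -> "ExclusionMask":
        return ExclusionMask.from_intervals(list(self.intervals) + list(other.intervals))

    def total(self) -> float:
        """Total excluded duration, counting overlaps once."""
        spans = sorted((a, b) for a, b, _ in self.intervals)
        out, last_end = 0.0, -math.inf
        for a, b in spans:
            a = max(a, last_end)
            if b > a:
                out += b - a
                last_end = b
        return out

    def overlap(self, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Excluded duration within each [start, end) interval (vectorized)."""
        out = np.zeros_like(start, dtype=float)
        spans = sorted((a, b) for a, b, _ in self.intervals)
        # flatten possibly-overlapping spans of different reasons
        flat: list[tuple[float, float]] = []
        for a, b in spans:
            if flat and a <= flat[-1][1]:
                flat[-1] = (flat[-1][0], max(flat[-1][1], b))
            else:
                flat.append((a, b))
        for a, b in flat:
            out += np.clip(np.minimum(end, b) - np.maximum(start, a), 0.0, None)
        return out


@dataclass(frozen=True)
class RangeSummary:
    """Time-weighted range percentages for one episode (or window).

    Percentages refer to *recorded* (non-excluded) time; the five
    categories are mutually exclusive (signal state takes priority over
    the oxygenation bands) and sum to 100.
    """

    pct_hypoxemia: float
    pct_normoxemia: float
    pct_hyperoxemia: float
    pct_no_signal: float
    pct_low_siq: float
    total_time: float
    excluded_time: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "pct_hypoxemia": self.pct_hypoxemia,
            "pct_normoxemia": self.pct_normoxemia,
            "pct_hyperoxemia": self.pct_hyperoxemia,
            "pct_no_signal": self.pct_no_signal,
            "pct_low_siq": self.pct_low_siq,
            "total_time": self.total_time,
            "excluded_time": self.excluded_time,
        }


EMPTY_SUMMARY = RangeSummary(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _durations(t: np.ndarray) -> np.ndarray:
    """Per-sample hold durations: to the next sample; last holds one median gap."""
    if len(t) == 1:
        return np.array([1.0])
    gaps = np.diff(t)
    return np.append(gaps, np.median(gaps))


def time_in_ranges(log: pd.DataFrame, mask: ExclusionMask | None = None) -> RangeSummary:
    """Time-weighted SpO2 range percentages of recorded time.

    ``log`` needs columns ``t_s`` (strictly increasing) and ``spo2``;
    ``signal_present`` and ``siq`` are honored when present.  Samples
    falling inside ``mask`` are excluded from numerator and denominator
    alike (partially covered samples contribute their unmasked share).
    Returns an all-zero summary if nothing is left after masking.
    """
    if log.empty:
        raise ValueError("log must be non-empty")
    t = np.asarray(log["t_s"], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dur = _durations(t)
    end = t + dur
    if mask is not None and mask.intervals:
        excluded = mask.overlap(t, end)
        w = dur - excluded
    else:
        w = dur.copy()

    spo2 = pd.to_numeric(log["spo2"], errors="coerce").to_numpy(dtype=float)
    if "signal_present" in log.columns:
        present = log["signal_present"].fillna(False).to_numpy(dtype=bool)
    else:
        present = np.ones(len(t), dtype=bool)
    present = present & ~np.isnan(spo2)
    if "siq" in log.columns:
        siq = pd.to_numeric(log["siq"], errors="coerce").fillna(0.0).to_numpy(dtype=float)
    else:
        siq = np.ones(len(t), dtype=float)

    no_signal = ~present
    low_siq = present & (siq <= LOW_SIQ_MAX)
    ok = present & ~low_siq
    rounded = np.full(len(t), np.nan)
    rounded[ok] = np.floor(spo2[ok] + 0.5)  # integer band edges; round half up
    hypo = ok & (rounded <= HYPOXEMIA_MAX)
    hyper = ok & (rounded > NORMOXEMIA_MAX)
    normo = ok & ~hypo & ~hyper

    recorded = float(w.sum())
    excluded_time = float(dur.sum() - recorded)
    if recorded <= 0.0:
        return RangeSummary(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, excluded_time)

    def pct(m: np.ndarray) -> float:
        return 100.0 * float(w[m].sum()) / recorded

    return RangeSummary(
        pct_hypoxemia=pct(hypo),
        pct_normoxemia=pct(normo),
        pct_hyperoxemia=pct(hyper),
        pct_no_signal=pct(no_signal),
        pct_low_siq=pct(low_siq),
        total_time=recorded,
        excluded_time=excluded_time,
    )


def suction_mask(events: "list[float]", window_min: float = 15.0) -> ExclusionMask:
    """One ``window_min``-minute exclusion window per suctioning episode.

    ``events`` are the preoxygenation onset times (s); overlapping windows
    are merged.
    """
    return ExclusionMask.from_intervals(
        [(t, t + 60.0 * window_min) for t in events], MaskReason.SUCTION
    )


def filter_aberrant(log: pd.DataFrame, floor: float = 80.0) -> tuple[pd.DataFrame, ExclusionMask]:
    """Drop aberrant readings (SpO2 strictly below ``floor``) from an audit log.

    Intended for usual-care logs whose monitors record artifactual lows;
    never applied to controller traces, where genuine desaturations must
    count.  Returns the filtered log and a mask covering the removed
    samples' hold intervals (reason ABERRANT), so that masking the original
    log gives the same range percentages as summarizing the filtered log
    under the same mask.
    """
    if not 0.0 < floor < 100.0:
        raise ValueError("floor must lie in (0, 100)")
    t = np.asarray(log["t_s"], dtype=float)
    dur = _durations(t)
    spo2 = pd.to_numeric(log["spo2"], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isnan(spo2) & (np.floor(spo2 + 0.5) < floor)
    mask = ExclusionMask.from_intervals(
        [(t[i], t[i] + dur[i]) for i in np.flatnonzero(bad)], MaskReason.ABERRANT
    )
    return log.loc[~bad].reset_index(drop=True), mask


_DEFAULT_ANCHORS = {"admission": 0.0, "h24": 24.0 * 3600.0, "day7": 7.0 * 24.0 * 3600.0}


def extract_windows(
    log: pd.DataFrame,
    anchors: dict[str, float] | None = None,
    width_h: float = 6.0,
) -> tuple[list[tuple[str, pd.DataFrame]], list[str]]:
    """Slice audit windows (default 6 h at admission, +24 h and day 7).

    Returns ``(windows, warnings)``; anchors entirely outside the log are
    omitted with a warning record, partial coverage is kept.
    """
    if anchors is None:
        anchors = _DEFAULT_ANCHORS
    t = np.asarray(log["t_s"], dtype=float)
    t_end = float(t[-1]) + float(_durations(t)[-1])
    width = width_h * 3600.0
    windows, warns = [], []
    for name, a in anchors.items():
        sel = log[(log["t_s"] >= a) & (log["t_s"] < a + width)]
        if sel.empty:
            warns.append(f"window '{name}' [{a:.0f}, {a + width:.0f}) s outside log (ends {t_end:.0f} s)")
            continue
        windows.append((name, sel.reset_index(drop=True)))
    return windows, warns


def adherence(log: pd.DataFrame, tol: float = 0.005) -> float | None:
    """Time-weighted fraction of time the set FiO2 equals the proposed FiO2.

    Returns ``None`` (unavailable) if either column is missing or they
    never overlap.
    """
    if "fio2_set" not in log.columns or "fio2_proposed" not in log.columns:
        return None
    t = np.asarray(log["t_s"], dtype=float)
    dur = _durations(t)
    a = pd.to_numeric(log["fio2_set"], errors="coerce").to_numpy(dtype=float)
    b = pd.to_numeric(log["fio2_proposed"], errors="coerce").to_numpy(dtype=float)
    both = ~np.isnan(a) & ~np.isnan(b)
    if not both.any():
        return None
    agree = both & (np.abs(a - b) <= tol)
    return float(dur[agree].sum() / dur[both].sum())


@dataclass(frozen=True)
class GroupComparison:
    """Result of a standard two-group test (plumbing around scipy.stats)."""

    test: str
    statistic: float | None
    pvalue: float | None
    effect: float | None  # mean(b) - mean(a); positive means group b higher
    n: tuple[int, int]
    computable: bool = True
    note: str = ""


def compare_groups(
    values_a,
    values_b,
    paired: bool = False,
    test: str = "auto",
) -> GroupComparison:
    """Compare two groups of summary percentages.

    ``test``: ``"wilcoxon"`` (paired signed-rank), ``"mannwhitney"``
    (unpaired), ``"ttest"`` (two-sample, for study-vs-historical), or
    ``"auto"`` (wilcoxon if paired else mannwhitney).  Groups with fewer
    than two values per arm (or unequal paired lengths) are reported as
    not computable rather than raising.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "auto":
        test = "wilcoxon" if paired else "mannwhitney"
    n = (len(a), len(b))
    if min(n) < 2:
        return GroupComparison(test, None, None, None, n, False, "need >= 2 values per group")
    if test == "wilcoxon":
        if len(a) != len(b):
            return GroupComparison(test, None, None, None, n, False, "paired groups must have equal length")
        d = b - a
        if np.all(d == 0.0):
            return GroupComparison(test, 0.0, 1.0, 0.0, n, True, "identical paired groups")
        res = stats.wilcoxon(a, b)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ttest":
        res = stats.ttest_ind(a, b)
    else:
        raise ValueError(f"unknown test '{test}'")
    return GroupComparison(
        test=test,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        effect=float(b.mean() - a.mean()),
        n=n,
    )


_ROW_LABELS = [
    ("pct_no_signal", "Time with no signal (%)"),
    ("pct_low_siq", "Time with SIQ <= 0.3 (%)"),
    ("pct_hypoxemia", "Time with hypoxemia (SpO2 <= 91%) (%)"),
    ("pct_normoxemia", "Time with normoxemia (SpO2 92% to 96%) (%)"),
    ("pct_hyperoxemia", "Time with hyperoxemia (SpO2 >= 97%) (%)"),
]


def format_summary_table(summaries: dict[str, RangeSummary]) -> str:
    """Human-readable table of range percentages, one column per episode."""
    cols = list(summaries)
    width = max(18, *(len(c) + 2 for c in cols)) if cols else 18
    head = "".ljust(42) + "".join(c.rjust(width) for c in cols)
    lines = [head]
    for key, label in _ROW_LABELS:
        row = label.ljust(42)
        for c in cols:
            row += f"{getattr(summaries[c], key):.1f}".rjust(width)
        lines.append(row)
    lines.append(
        "Recorded time (s)".ljust(42)
        + "".join(f"{summaries[c].total_time:.0f}".rjust(width) for c in cols)
    )
    return "\n".join(lines)
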