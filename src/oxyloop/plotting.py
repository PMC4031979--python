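"""Episode visualization: the classic five-signal strip chart.

Top to bottom: SpO2 over time with the target band, FiO2 set and FiO2
proposed as step traces, then heart rate and perfusion index.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io import EpisodeRecord

__all__ = ["plot_episode"]


def plot_episode(record: EpisodeRecord, path: str | None = None):
    """Render an episode log; saves to ``path`` if given, returns the figure."""
    df = record.samples
    t = df["t_s"] / 60.0
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(10, 7), height_ratios=[2, 1.4, 1])

    ax = axes[0]
    ax.axhspan(92, 96, color="tab:green", alpha=0.15, label="target 92-96%")
    ax.plot(t, df["spo2"], lw=0.8, color="tab:blue")
    ax.set_ylabel("SpO2 (%)")
    ax.set_ylim(75, 101)
    ax.legend(loc="lower right", fontsize=8)

    ax = axes[1]
    ax.step(t, 100 * df["fio2_set"], where="post", color="purple", lw=1.0, label="FiO2 set")
    if df["fio2_proposed"].notna().any():
        ax.step(
            t, 100 * df["fio2_proposed"], where="post", color="red", lw=0.8,
            alpha=0.7, label="FiO2 proposed",
        )
    ax.set_ylabel("FiO2 (%)")
    ax.set_ylim(15, 105)
    ax.legend(loc="upper right", fontsize=8)

    ax = axes[2]
    ax.plot(t, df["hr"], color="gray", lw=0.8, label="HR (bpm)")
    ax2 = ax.twinx()
    ax2.plot(t, df["pi"], color="purple", lw=0.8, alpha=0.6, label="PI (%)")
    ax.set_ylabel("HR (bpm)")
    ax2.set_ylabel("PI (%)")
    ax.set_xlabel("time (min)")

    for a, b, kind in zip(
        record.events["start_s"] / 60.0,
        record.events["end_s"] / 60.0,
        record.events["kind"],
    ):
        color = "orange" if kind == "suction" else "red"
        axes[0].axvspan(a, b, color=color, alpha=0.12)

    fig.suptitle(
        f"{record.metadata.get('policy', '?')} | {record.metadata.get('stratum', '?')} "
        f"patient, seed {record.metadata.get('seed', '?')}"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
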