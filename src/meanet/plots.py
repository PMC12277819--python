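"""Optional figure rendering: rasters with firing-rate traces and
coupling-strength histograms.

Rasters show a display window (default the first 5 minutes) of the full
recording, one row per electrode, with the population firing rate underneath.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .types import SessionRecord


def raster_plot(session: SessionRecord, window_s: float = 300.0,
                rate_bin_s: float = 1.0, path: str | Path | None = None):
    """Raster of a display window plus the binned population firing rate."""
    t1 = min(window_s, session.duration_s)
    fig, (ax_r, ax_f) = plt.subplots(
        2, 1, figsize=(8, 5), sharex=True, height_ratios=[4, 1]
    )
    for row, tr in enumerate(session.trains):
        t = tr.times_s[tr.times_s <= t1]
        ax_r.vlines(t, row + 0.6, row + 1.4, lw=0.4, color="k")
    ax_r.set_ylim(0.5, len(session.trains) + 0.5)
    ax_r.set_ylabel("electrode")
    ax_r.set_title(f"{session.assembloid_id} {session.condition}")
    edges = np.arange(0, t1 + rate_bin_s, rate_bin_s)
    all_t = np.concatenate([tr.times_s[tr.times_s <= t1] for tr in session.trains])
    rate, _ = np.histogram(all_t, bins=edges)
    ax_f.stairs(rate / (rate_bin_s * max(1, len(session.trains))), edges, color="tab:blue")
    ax_f.set_xlabel("time (s)")
    ax_f.set_ylabel("Hz/electrode")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def coupling_histogram(strengths: np.ndarray, bins: int = 20,
                       path: str | Path | None = None):
    """Histogram of the coupling strengths of significantly coupled pairs."""
    fig, ax = plt.subplots(figsize=(5, 4))
    if strengths.size:
        ax.hist(strengths, bins=bins, color="tab:orange", edgecolor="k")
    ax.set_xlabel("coupling strength")
    ax.set_ylabel("pairs")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
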