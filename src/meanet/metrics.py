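"""Per-session activity metrics: active electrodes, mean firing rate, and
drug-response ratios (drug-condition MFR over baseline MFR per assembloid)."""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np

from .types import ElectrodeMetrics, SessionRecord

DEFAULT_MIN_RATE_HZ = 0.1  # common MEA activity criterion; logged in outputs


def electrode_metrics(
    session: SessionRecord, min_rate_hz: float = DEFAULT_MIN_RATE_HZ
) -> list[ElectrodeMetrics]:
    """Spike count, mean firing rate, and activity flag per electrode.

    An electrode is active iff its rate over the full recording is at least
    ``min_rate_hz``.
    """
    if session.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    out = []
    for tr in session.trains:
        rate = tr.n_spikes / session.duration_s
        out.append(
            ElectrodeMetrics(
                electrode_id=tr.electrode_id,
                spike_count=tr.n_spikes,
                mfr_hz=rate,
                active=rate >= min_rate_hz,
            )
        )
    return out


def session_mfr(
    session: SessionRecord,
    scope: str = "all",
    min_rate_hz: float = DEFAULT_MIN_RATE_HZ,
) -> float:
    """Session mean firing rate: average of per-electrode rates.

    ``scope='all'`` averages over every electrode; ``scope='active'`` over
    electrodes meeting the activity criterion (NaN with a warning if none do).
    """
    if scope not in ("all", "active"):
        raise ValueError("scope must be 'all' or 'active'")
    ms = electrode_metrics(session, min_rate_hz)
    if not ms:
        raise ValueError("session has no electrodes")
    rates = [m.mfr_hz for m in ms if scope == "all" or m.active]
    if not rates:
        warnings.warn(
            f"session {session.assembloid_id}/{session.condition}: no active "
            "electrodes; active-scope MFR undefined",
            stacklevel=2,
        )
        return math.nan
    return float(np.mean(rates))


def log_transform(values: Sequence[float], offset: float = 0.0) -> np.ndarray:
    """Base-10 logarithm of (value + offset).

    With ``offset=0`` zero values are out of domain and raise; summaries that
    exclude zeros must do so explicitly and report the exclusion count.
    """
    v = np.asarray(values, dtype=float) + offset
    if np.any(v <= 0):
        raise ValueError("log_transform domain error: value + offset <= 0")
    return np.log10(v)


def drug_response_ratio(
    session_drug: SessionRecord,
    session_bl: SessionRecord,
    scope: str = "all",
    min_rate_hz: float = DEFAULT_MIN_RATE_HZ,
) -> float:
    """Drug response of one assembloid: MFR(drug) / MFR(baseline).

    Values below 1 indicate net inhibition.  NaN when the baseline MFR is 0.
    """
    if session_bl.condition != "BL":
        raise ValueError("session_bl must be the baseline condition")
    if session_drug.assembloid_id != session_bl.assembloid_id:
        raise ValueError("drug and baseline sessions must share an assembloid")
    if set(session_drug.electrode_ids) != set(session_bl.electrode_ids):
        raise ValueError("electrode sets differ between conditions")
    bl = session_mfr(session_bl, scope, min_rate_hz)
    drug = session_mfr(session_drug, scope, min_rate_hz)
    if not bl or math.isnan(bl):
        warnings.warn(
            f"assembloid {session_bl.assembloid_id}: baseline MFR is 0, "
            "drug-response ratio undefined",
            stacklevel=2,
        )
        return math.nan
    return drug / bl
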