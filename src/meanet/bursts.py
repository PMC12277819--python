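"""Single-electrode burst detection (Max-Interval-style ISI scan) and
network-burst detection (coincident burst onsets across electrodes).

A burst opens at a qualifying short inter-spike interval, extends while ISIs
stay below the in-burst maximum, and is kept only if it has enough spikes and
duration.  A network burst (NB) is declared wherever bursts from a sufficient
fraction of active electrodes start within a short sliding window; overlapping
candidate windows merge into one NB whose extent is the union of the
participating bursts' spans.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np

from .metrics import DEFAULT_MIN_RATE_HZ, electrode_metrics
from .types import Burst, BurstParams, NetworkBurst, SessionRecord, SpikeTrain


def detect_bursts(train: SpikeTrain, params: BurstParams) -> list[Burst]:
    """Scan one spike train for bursts.

    Opens a burst when an ISI <= ``max_isi_start_s``; extends it while ISIs
    <= ``max_isi_in_burst_s``; keeps it only with >= ``min_spikes_per_burst``
    spikes and duration >= ``min_burst_duration_s``.  Output bursts are
    non-overlapping and time-ordered.
    """
    t = train.times_s
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("spike train must be sorted strictly increasing")
    bursts: list[Burst] = []
    n = t.size
    i = 0
    while i < n - 1:
        if t[i + 1] - t[i] <= params.max_isi_start_s:
            j = i + 1
            while j < n - 1 and t[j + 1] - t[j] <= params.max_isi_in_burst_s:
                j += 1
            n_spikes = j - i + 1
            duration = t[j] - t[i]
            if (n_spikes >= params.min_spikes_per_burst
                    and duration >= params.min_burst_duration_s):
                bursts.append(Burst(train.electrode_id, float(t[i]), float(t[j]), n_spikes))
            i = j + 1
        else:
            i += 1
    return bursts


def _merge_spans(qualifying: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge qualifying (first, last) burst-index spans that overlap."""
    groups: list[tuple[int, int]] = []
    for lo, hi in qualifying:
        if groups and lo <= groups[-1][1]:
            groups[-1] = (groups[-1][0], max(groups[-1][1], hi))
        else:
            groups.append((lo, hi))
    return groups


def detect_network_bursts(
    session: SessionRecord,
    bursts_by_electrode: Mapping[str, Sequence[Burst]],
    params: BurstParams,
    min_rate_hz: float = DEFAULT_MIN_RATE_HZ,
) -> list[NetworkBurst]:
    """Detect network bursts from per-electrode bursts.

    A window of ``nb_window_s`` anchored at each burst onset qualifies when it
    contains onsets from at least ``nb_min_fraction`` of the session's active
    electrodes; overlapping qualifying windows merge, and each merged group
    becomes one NB spanning the union of its bursts.
    """
    active = [m.electrode_id for m in electrode_metrics(session, min_rate_hz) if m.active]
    n_active = len(active)
    if n_active == 0:
        warnings.warn("no active electrodes: no network bursts detectable", stacklevel=2)
        return []
    required = int(np.ceil(params.nb_min_fraction * n_active))

    all_bursts = [b for bl in bursts_by_electrode.values() for b in bl]
    if not all_bursts:
        return []
    all_bursts.sort(key=lambda b: (b.start_s, b.electrode_id))
    onsets = np.array([b.start_s for b in all_bursts])
    electrodes = [b.electrode_id for b in all_bursts]
    n = onsets.size

    # two-pointer sweep: for each anchor onset, the window [t_k, t_k + w];
    # tied onsets before the anchor index belong to the window too
    qualifying: list[tuple[int, int]] = []
    hi = 0
    for k in range(n):
        if hi < k:
            hi = k
        while hi + 1 < n and onsets[hi + 1] <= onsets[k] + params.nb_window_s:
            hi += 1
        lo = int(np.searchsorted(onsets, onsets[k], side="left"))
        distinct = len(set(electrodes[lo : hi + 1]))
        if distinct >= required:
            qualifying.append((lo, hi))

    groups = _merge_spans(qualifying)
    nbs: list[NetworkBurst] = []
    for lo, hi in groups:
        members = all_bursts[lo : hi + 1]
        nbs.append(
            NetworkBurst(
                start_s=min(b.start_s for b in members),
                end_s=max(b.end_s for b in members),
                participating_electrodes=tuple(sorted({b.electrode_id for b in members})),
            )
        )
    return nbs


def brute_force_network_bursts(
    session: SessionRecord,
    bursts_by_electrode: Mapping[str, Sequence[Burst]],
    params: BurstParams,
    min_rate_hz: float = DEFAULT_MIN_RATE_HZ,
) -> list[NetworkBurst]:
    """Exhaustive-enumeration oracle for :func:`detect_network_bursts`.

    Same definition, naive O(n^2) evaluation: every onset anchors a window
    checked against every other onset.  Guarded to small instances.
    """
    all_bursts = [b for bl in bursts_by_electrode.values() for b in bl]
    if len(all_bursts) > 2000:
        raise ValueError("brute-force oracle restricted to small fixtures")
    active = [m.electrode_id for m in electrode_metrics(session, min_rate_hz) if m.active]
    if not active:
        return []
    required = int(np.ceil(params.nb_min_fraction * len(active)))
    all_bursts.sort(key=lambda b: (b.start_s, b.electrode_id))
    n = len(all_bursts)

    qualifying: list[tuple[int, int]] = []
    for k in range(n):
        inside = [
            j for j in range(n)
            if all_bursts[k].start_s <= all_bursts[j].start_s <= all_bursts[k].start_s + params.nb_window_s
        ]
        if len({all_bursts[j].electrode_id for j in inside}) >= required:
            qualifying.append((min(inside), max(inside)))

    merged = _merge_spans(qualifying)
    out = []
    for lo, hi in merged:
        members = all_bursts[lo : hi + 1]
        out.append(
            NetworkBurst(
                start_s=min(b.start_s for b in members),
                end_s=max(b.end_s for b in members),
                participating_electrodes=tuple(sorted({b.electrode_id for b in members})),
            )
        )
    return out


def network_burst_rate(nbs: Sequence[NetworkBurst], duration_s: float) -> float:
    """Network bursts per minute."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    return len(nbs) / (duration_s / 60.0)


def session_bursts(session: SessionRecord, params: BurstParams) -> dict[str, list[Burst]]:
    """Convenience: burst lists for every electrode of a session."""
    return {tr.electrode_id: detect_bursts(tr, params) for tr in session.trains}
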