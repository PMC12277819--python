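"""Threshold-based multi-unit spike detection from raw extracellular traces.

Pipeline: zero-phase band-pass filter -> robust per-channel noise estimate
(median absolute deviation / 0.6745) -> threshold crossing at k*sigma with
the configured polarity -> refractory collapse keeping the larger-amplitude
event.  No spike sorting is attempted: every threshold crossing on an
electrode contributes to one multi-unit train, matching an electrode-level
analysis.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .types import DetectionParams, RawRecording, SpikeTrain

MAD_TO_SD = 0.6745  # Phi^-1(0.75): median(|X|) of N(0, sigma) equals 0.6745*sigma


def bandpass_filter(raw: RawRecording, params: DetectionParams) -> RawRecording:
    """Zero-phase Butterworth band-pass applied per channel.

    Output traces are float valued; duration, channel count and metadata are
    unchanged.
    """
    params.validate_for_rate(raw.sampling_rate_hz)
    sos = signal.butter(
        params.filter_order,
        [params.band_low_hz, params.band_high_hz],
        btype="bandpass",
        fs=raw.sampling_rate_hz,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, raw.traces.astype(float), axis=1)
    return RawRecording(
        traces=filtered,
        sampling_rate_hz=raw.sampling_rate_hz,
        electrode_ids=raw.electrode_ids,
        duration_s=raw.duration_s,
    )


def estimate_noise_sd(channel: np.ndarray) -> float:
    """Robust noise SD: median(|x|) / 0.6745.

    Insensitive to the spikes themselves (they occupy few samples).  Returns
    0.0 for an all-zero channel; callers must treat sigma = 0 as "no signal".
    """
    x = np.asarray(channel, dtype=float)
    if x.size < 1000:
        raise ValueError("need >= 1000 samples for a stable noise estimate")
    return float(np.median(np.abs(x)) / MAD_TO_SD)


def _edge_guard_samples(params: DetectionParams, sampling_rate_hz: float) -> int:
    # 3x the filter's characteristic settling length at the low band edge
    return int(round(3.0 * sampling_rate_hz / params.band_low_hz))


def _find_extrema(x: np.ndarray, threshold: float, distance: int) -> tuple[np.ndarray, np.ndarray]:
    idx, props = signal.find_peaks(x, height=threshold, distance=max(1, distance))
    return idx, props["peak_heights"]


def detect_spikes(filtered: RawRecording, params: DetectionParams) -> list[SpikeTrain]:
    """Detect multi-unit spikes on every channel of a filtered recording.

    A spike is a local extremum exceeding ``threshold_k`` times the channel's
    robust noise SD with the configured polarity; events closer than the
    refractory period collapse to the larger-amplitude one.  Extrema within
    the filter-settling guard at either edge are discarded.  Channels with a
    zero noise estimate yield empty trains.
    """
    fs = filtered.sampling_rate_hz
    distance = int(round(params.refractory_s * fs))
    guard = _edge_guard_samples(params, fs)
    trains: list[SpikeTrain] = []
    for ch, eid in enumerate(filtered.electrode_ids):
        x = np.asarray(filtered.traces[ch], dtype=float)
        sigma = estimate_noise_sd(x)
        if sigma == 0.0:
            trains.append(SpikeTrain(eid, np.empty(0)))
            continue
        thr = params.threshold_k * sigma
        if params.polarity == "negative":
            idx, _ = _find_extrema(-x, thr, distance)
        elif params.polarity == "positive":
            idx, _ = _find_extrema(x, thr, distance)
        else:  # both: detect on each polarity, then re-collapse jointly
            ineg, hneg = _find_extrema(-x, thr, distance)
            ipos, hpos = _find_extrema(x, thr, distance)
            cand = np.concatenate([ineg, ipos])
            amp = np.concatenate([hneg, hpos])
            order = np.argsort(cand)
            cand, amp = cand[order], amp[order]
            keep: list[int] = []
            for k in range(cand.size):
                if keep and cand[k] - cand[keep[-1]] < distance:
                    if amp[k] > amp[keep[-1]]:
                        keep[-1] = k
                else:
                    keep.append(k)
            idx = cand[keep] if keep else np.empty(0, dtype=int)
        idx = idx[(idx >= guard) & (idx < filtered.n_samples - guard)]
        trains.append(SpikeTrain(eid, idx / fs))
    return trains


def score_detection(
    detected: SpikeTrain | np.ndarray,
    truth: np.ndarray,
    tolerance_s: float,
) -> tuple[float, float, float]:
    """Greedy one-to-one matching of detected against true spike times.

    Returns (precision, recall, F1).  With no detections, precision is 1.0 by
    convention (there are no false positives to penalize); with no true
    spikes, recall is 1.0 by the mirror convention.
    """
    if tolerance_s < 0:
        raise ValueError("tolerance_s must be >= 0")
    det = detected.times_s if isinstance(detected, SpikeTrain) else np.asarray(detected, float)
    tru = np.asarray(truth, dtype=float)
    i = j = matched = 0
    while i < det.size and j < tru.size:
        d = det[i] - tru[j]
        if abs(d) <= tolerance_s:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    precision = matched / det.size if det.size else 1.0
    recall = matched / tru.size if tru.size else 1.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return precision, recall, f1
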