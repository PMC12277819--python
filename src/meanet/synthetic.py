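"""Ground-truthed simulation of multi-electrode-array recordings.

Emulates a 60-electrode array recording spontaneous activity from an
organoid assembloid under a sequential baseline / GABA / picrotoxin (PTX)
protocol.  Each electrode's train is the superposition of

* a homogeneous Poisson background at ``scalar * base_rate``,
* copies of a hidden common-source Poisson train, accepted independently
  with probability ``c_i`` and jittered by a small Gaussian (this is what
  produces a near-zero-lag cross-correlogram peak whose height grows with
  the coupling probability), and
* extra spikes during Poisson-timed network-burst epochs that multiply the
  rate of a random electrode subset,

followed by deduplication and forward refractory enforcement.  The condition
scalar (GABA < 1, PTX > 1) multiplies every rate, emulating bath-applied
drug effects on net activity.

All randomness flows from ``SimulationConfig.seed`` through fixed-key
``numpy.random.SeedSequence`` streams, so identical configurations yield
identical spike trains on any platform.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .types import (
    CONDITIONS,
    ConfigurationError,
    GroundTruth,
    RawRecording,
    SessionRecord,
    SimulationConfig,
    SpikeTrain,
)

# stream keys; fixed so that adding new streams never reshuffles old ones
_BG, _SRC, _COPY, _NBEPOCH, _NBSPIKE = 1, 2, 3, 4, 5


def _rng(config_seed: int, condition: str, *key: int) -> np.random.Generator:
    cond_idx = CONDITIONS.index(condition)
    return np.random.default_rng(
        np.random.SeedSequence((int(config_seed), cond_idx, *key))
    )


def _poisson_train(rng: np.random.Generator, rate_hz: float, t0: float,
                   t1: float) -> np.ndarray:
    """Homogeneous Poisson process on [t0, t1): draw a count, place uniformly."""
    span = t1 - t0
    if rate_hz <= 0 or span <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * span)
    return np.sort(rng.uniform(t0, t1, size=n))


def enforce_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Forward deletion: keep the first spike, drop any follower closer than
    ``refractory_s`` to the last kept spike.  Deterministic for sorted input."""
    if times.size == 0 or refractory_s <= 0:
        return np.unique(times)
    times = np.sort(times)
    kept = [times[0]]
    last = times[0]
    for t in times[1:]:
        if t - last >= refractory_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def electrode_label(index: int) -> str:
    return f"E{index:02d}"


def simulate_session(
    config: SimulationConfig,
    condition: str,
    assembloid_id: str = "sim",
    genotype: str = "APOE3",
) -> tuple[SessionRecord, GroundTruth]:
    """Simulate one assembloid x condition recording.

    Returns the session together with a :class:`GroundTruth` carrying the
    injected spike times, the pairwise coupling matrix (outer product of the
    per-electrode source-copy probabilities, zero diagonal), the hidden
    source train, and the injected network-burst intervals.
    """
    if condition not in config.condition_scalars:
        raise ConfigurationError(f"no condition scalar for {condition!r}")
    scalar = float(config.condition_scalars[condition])
    T = config.duration_s
    rates = config.rate_vector()
    cvec = config.coupling_vector()
    n = config.n_electrodes

    # hidden common source (rate scaled with condition like everything else)
    src = _poisson_train(_rng(config.seed, condition, _SRC), scalar * config.source_rate_hz, 0.0, T)

    # network-burst epochs
    nb_intervals: list[tuple[float, float]] = []
    nb_participants: list[tuple[str, ...]] = []
    epoch_rng = _rng(config.seed, condition, _NBEPOCH)
    if config.nb_rate_per_min > 0:
        starts = _poisson_train(epoch_rng, config.nb_rate_per_min / 60.0, 0.0, T)
        k = max(1, int(round(config.nb_participation * n)))
        for s in starts:
            e = min(s + config.nb_duration_s, T)
            members = np.sort(epoch_rng.choice(n, size=k, replace=False))
            nb_intervals.append((float(s), float(e)))
            nb_participants.append(tuple(electrode_label(i) for i in members))

    trains: list[SpikeTrain] = []
    truth_times: dict[str, np.ndarray] = {}
    for i in range(n):
        parts = [
            _poisson_train(_rng(config.seed, condition, _BG, i), scalar * rates[i], 0.0, T)
        ]
        if src.size and cvec[i] > 0:
            crng = _rng(config.seed, condition, _COPY, i)
            accept = crng.random(src.size) < cvec[i]
            copies = src[accept]
            if config.copy_jitter_sd_s > 0 and copies.size:
                copies = copies + crng.normal(0.0, config.copy_jitter_sd_s, copies.size)
            parts.append(np.clip(copies, 0.0, T))
        if nb_intervals:
            brng = _rng(config.seed, condition, _NBSPIKE, i)
            extra_rate = scalar * rates[i] * (config.nb_rate_multiplier - 1.0)
            label = electrode_label(i)
            for (s, e), members in zip(nb_intervals, nb_participants):
                if label in members:
                    parts.append(_poisson_train(brng, extra_rate, s, e))
        merged = np.sort(np.concatenate(parts)) if parts else np.empty(0)
        merged = merged[(merged >= 0) & (merged <= T)]
        merged = enforce_refractory(merged, config.refractory_s)
        label = electrode_label(i)
        trains.append(SpikeTrain(label, merged))
        truth_times[label] = merged

    cmat = np.outer(cvec, cvec)
    np.fill_diagonal(cmat, 0.0)

    session = SessionRecord(
        assembloid_id=assembloid_id,
        genotype=genotype,
        condition=condition,
        duration_s=T,
        trains=tuple(trains),
    )
    truth = GroundTruth(
        spike_times=truth_times,
        coupling_matrix=cmat,
        source_times_s=src,
        nb_intervals=tuple(nb_intervals),
        nb_participants=tuple(nb_participants),
        condition_scalar=scalar,
    )
    return session, truth


def default_spike_template(sampling_rate_hz: float = 25000.0,
                           amplitude: float = 8.0) -> np.ndarray:
    """Biphasic (negative-then-positive) extracellular waveform, 1.2 ms long.

    The negative trough has magnitude ``amplitude``; the rebound is ~40% of
    it.  Shape is a fixture choice, not a biophysical model.
    """
    n = max(8, int(round(1.2e-3 * sampling_rate_hz)))
    t = np.linspace(0, 1, n)
    trough = -np.exp(-((t - 0.25) ** 2) / (2 * 0.07**2))
    rebound = 0.4 * np.exp(-((t - 0.6) ** 2) / (2 * 0.12**2))
    w = trough + rebound
    return amplitude * w / np.abs(w).max()


def render_raw_traces(
    session: SessionRecord,
    template: np.ndarray,
    noise_sd: float,
    sampling_rate_hz: float = 25000.0,
    seed: int = 0,
) -> RawRecording:
    """Render 16-bit acquisition-style traces from a spike-train session.

    Per channel: Gaussian noise of SD ``noise_sd``, plus the template added
    with its onset at the nearest sample to each spike time, then rounded and
    clipped to the signed 16-bit range.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    template = np.asarray(template, dtype=float)
    n_samples = int(round(session.duration_s * sampling_rate_hz))
    if template.size >= n_samples:
        raise ConfigurationError("template longer than the recording")
    traces = np.zeros((len(session.trains), n_samples), dtype=float)
    for ch, tr in enumerate(session.trains):
        if np.any(tr.times_s > session.duration_s):
            raise ValueError("spike time beyond recording duration")
        if noise_sd > 0:
            rng = np.random.default_rng(np.random.SeedSequence((int(seed), 17, ch)))
            traces[ch] = rng.normal(0.0, noise_sd, n_samples)
        onsets = np.round(tr.times_s * sampling_rate_hz).astype(int)
        for s0 in onsets:
            s1 = min(s0 + template.size, n_samples)
            traces[ch, s0:s1] += template[: s1 - s0]
    q = np.clip(np.round(traces), -32768, 32767).astype(np.int16)
    return RawRecording(
        traces=q,
        sampling_rate_hz=sampling_rate_hz,
        electrode_ids=session.electrode_ids,
        duration_s=session.duration_s,
    )


def make_cohort(
    config_by_genotype: Mapping[str, SimulationConfig],
    n_assembloids: int,
    conditions: Sequence[str] = CONDITIONS,
    seed: int = 0,
) -> tuple[list[SessionRecord], dict[tuple[str, str], GroundTruth]]:
    """Simulate a full cohort: every genotype x assembloid x condition.

    Within one assembloid the conditions share base rates and coupling
    (same derived seed), differing only by the condition scalar; distinct
    assembloids get distinct derived seeds.  Returns the session list and a
    ground-truth map keyed by (assembloid_id, condition).
    """
    if not config_by_genotype:
        raise ConfigurationError("at least one genotype required")
    if not conditions:
        raise ConfigurationError("at least one condition required")
    sessions: list[SessionRecord] = []
    truths: dict[tuple[str, str], GroundTruth] = {}
    seen_ids: set[str] = set()
    for g_idx, (genotype, cfg) in enumerate(sorted(config_by_genotype.items())):
        for a in range(n_assembloids):
            aid = f"{genotype}-{a + 1:02d}"
            if aid in seen_ids:
                raise ConfigurationError(f"duplicate assembloid id {aid!r}")
            seen_ids.add(aid)
            # one seed per assembloid: conditions share rates and coupling
            child = np.random.SeedSequence((int(seed), g_idx, a)).generate_state(1)[0]
            acfg = cfg.with_seed(int(child) % (2**31))
            for condition in conditions:
                ses, truth = simulate_session(acfg, condition, assembloid_id=aid,
                                              genotype=genotype)
                sessions.append(ses)
                truths[(aid, condition)] = truth
    return sessions, truths
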