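"""Core domain types for MEA spike-train analysis.

The central unit of analysis is a :class:`SessionRecord`: the spike trains of
one assembloid recorded under one pharmacological condition (baseline, GABA,
or picrotoxin).  Raw multi-channel voltage traces are carried by
:class:`RawRecording`; all parameter bundles are frozen dataclasses so that a
run is fully described by its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

GENOTYPES = ("APOE3", "APOE4", "A3CO", "A4CO")
CONDITIONS = ("BL", "GABA", "PTX")


class ConfigurationError(ValueError):
    """Raised when a parameter bundle violates its invariants."""


def _as_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("spike times must be one-dimensional")
    return t


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (seconds) of one electrode, strictly increasing."""

    electrode_id: str
    times_s: np.ndarray

    def __post_init__(self):
        t = _as_times(self.times_s)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError(
                f"spike times of electrode {self.electrode_id!r} are not "
                "strictly increasing"
            )
        if t.size and (t[0] < 0 or not np.all(np.isfinite(t))):
            raise ValueError("spike times must be finite and non-negative")
        object.__setattr__(self, "times_s", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)


@dataclass(frozen=True)
class SessionRecord:
    """One assembloid x one condition: a labelled set of spike trains."""

    assembloid_id: str
    genotype: str
    condition: str
    duration_s: float
    trains: tuple[SpikeTrain, ...]

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        object.__setattr__(self, "trains", tuple(self.trains))
        ids = [tr.electrode_id for tr in self.trains]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate electrode ids in session")
        for tr in self.trains:
            if tr.times_s.size and tr.times_s[-1] > self.duration_s:
                raise ValueError(
                    f"electrode {tr.electrode_id!r} has spikes beyond duration_s"
                )

    @property
    def electrode_ids(self) -> tuple[str, ...]:
        return tuple(tr.electrode_id for tr in self.trains)

    def train(self, electrode_id: str) -> SpikeTrain:
        for tr in self.trains:
            if tr.electrode_id == electrode_id:
                return tr
        raise KeyError(electrode_id)


@dataclass(frozen=True)
class RawRecording:
    """Multi-channel extracellular traces: channels x samples at a fixed rate.

    Acquisition-style recordings are 16-bit integers; band-pass filtered
    traces reuse the same container with float samples.
    """

    traces: np.ndarray
    sampling_rate_hz: float
    electrode_ids: tuple[str, ...]
    duration_s: float

    def __post_init__(self):
        tr = np.asarray(self.traces)
        if tr.ndim != 2:
            raise ValueError("traces must be channels x samples")
        if tr.shape[0] != len(self.electrode_ids):
            raise ValueError("one electrode id per channel required")
        expected = int(round(self.duration_s * self.sampling_rate_hz))
        if tr.shape[1] != expected:
            raise ValueError(
                f"samples ({tr.shape[1]}) != round(duration*rate) ({expected})"
            )
        object.__setattr__(self, "traces", tr)
        object.__setattr__(self, "electrode_ids", tuple(self.electrode_ids))

    @property
    def n_channels(self) -> int:
        return int(self.traces.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.traces.shape[1])


@dataclass(frozen=True)
class DetectionParams:
    """Spike-detection settings.

    Detection thresholds are expressed in multiples of the per-channel robust
    noise SD so that detections are invariant to amplitude rescaling.
    """

    band_low_hz: float = 300.0
    band_high_hz: float = 3000.0
    filter_order: int = 2
    threshold_k: float = 5.0
    refractory_s: float = 0.001
    polarity: str = "negative"

    def __post_init__(self):
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ConfigurationError("require 0 < band_low_hz < band_high_hz")
        if self.threshold_k <= 0:
            raise ConfigurationError("threshold_k must be positive")
        if self.refractory_s < 0:
            raise ConfigurationError("refractory_s must be non-negative")
        if self.polarity not in ("negative", "positive", "both"):
            raise ConfigurationError("polarity must be negative|positive|both")

    def validate_for_rate(self, sampling_rate_hz: float) -> None:
        if self.band_high_hz >= sampling_rate_hz / 2:
            raise ConfigurationError(
                f"band_high_hz ({self.band_high_hz}) must be below Nyquist "
                f"({sampling_rate_hz / 2})"
            )


@dataclass(frozen=True)
class BurstParams:
    """Max-Interval-style burst criteria plus network-burst windowing."""

    max_isi_start_s: float = 0.1
    max_isi_in_burst_s: float = 0.2
    min_spikes_per_burst: int = 5
    min_burst_duration_s: float = 0.05
    nb_window_s: float = 0.1
    nb_min_fraction: float = 0.25

    def __post_init__(self):
        if min(self.max_isi_start_s, self.max_isi_in_burst_s,
               self.min_burst_duration_s, self.nb_window_s) <= 0:
            raise ConfigurationError("burst time parameters must be positive")
        if self.min_spikes_per_burst < 2:
            raise ConfigurationError("min_spikes_per_burst must be >= 2")
        if not (0 < self.nb_min_fraction <= 1):
            raise ConfigurationError("nb_min_fraction must be in (0, 1]")


@dataclass(frozen=True)
class CCGParams:
    """Cross-correlogram and jitter-surrogate significance settings."""

    bin_s: float = 0.005
    window_s: float = 0.1
    peak_search_s: float = 0.05
    n_surrogates: int = 100
    jitter_halfwidth_s: float = 0.02
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.bin_s <= 0:
            raise ConfigurationError("bin_s must be positive")
        if self.peak_search_s > self.window_s:
            raise ConfigurationError("peak_search_s must be <= window_s")
        if self.window_s < 1.5 * self.bin_s:
            raise ConfigurationError("window must cover at least 3 bins")
        if self.n_surrogates < 19:
            raise ConfigurationError("n_surrogates must be >= 19")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.alpha < 1.0 / (self.n_surrogates + 1):
            raise ConfigurationError(
                "alpha below 1/(n_surrogates+1): the add-one empirical p-value "
                "can never reach it; increase n_surrogates or relax alpha"
            )
        if self.jitter_halfwidth_s <= self.bin_s:
            raise ConfigurationError("jitter_halfwidth_s must exceed bin_s")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative specification of one simulated assembloid.

    Coupling follows a common-source model: a hidden Poisson train at
    ``source_rate_hz`` whose spikes each electrode receives independently with
    probability ``coupling`` (scalar, shared, or one value per electrode),
    jittered by a Gaussian of SD ``copy_jitter_sd_s``.  Network bursts are
    Poisson-timed epochs that multiply rates for a random electrode subset.
    """

    n_electrodes: int = 60
    duration_s: float = 1800.0
    sampling_rate_hz: float = 25000.0
    base_rates_hz: float | Sequence[float] = 1.0
    coupling: float | Sequence[float] = 0.0
    source_rate_hz: float = 1.0
    copy_jitter_sd_s: float = 0.002
    refractory_s: float = 0.002
    nb_rate_per_min: float = 0.0
    nb_duration_s: float = 0.5
    nb_rate_multiplier: float = 30.0
    nb_participation: float = 0.8
    condition_scalars: Mapping[str, float] = field(
        default_factory=lambda: {"BL": 1.0, "GABA": 0.5, "PTX": 2.0}
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_electrodes < 1:
            raise ConfigurationError("n_electrodes must be >= 1")
        if self.duration_s <= 0 or not np.isfinite(self.duration_s):
            raise ConfigurationError("duration_s must be positive and finite")
        rates = self.rate_vector()
        if np.any(~np.isfinite(rates)) or np.any(rates < 0):
            raise ConfigurationError("base rates must be finite and >= 0")
        c = self.coupling_vector()
        if np.any(~np.isfinite(c)) or np.any(c < 0) or np.any(c > 1):
            raise ConfigurationError("coupling probabilities must lie in [0, 1]")
        if self.source_rate_hz < 0 or not np.isfinite(self.source_rate_hz):
            raise ConfigurationError("source_rate_hz must be finite and >= 0")
        if self.copy_jitter_sd_s < 0:
            raise ConfigurationError("copy_jitter_sd_s must be >= 0")
        if self.refractory_s < 0:
            raise ConfigurationError("refractory_s must be >= 0")
        if self.nb_rate_per_min < 0 or self.nb_duration_s <= 0:
            raise ConfigurationError("invalid network-burst timing parameters")
        if self.nb_rate_multiplier < 1:
            raise ConfigurationError("nb_rate_multiplier must be >= 1")
        if not (0 < self.nb_participation <= 1):
            raise ConfigurationError("nb_participation must be in (0, 1]")
        for cond, s in self.condition_scalars.items():
            if s <= 0 or not np.isfinite(s):
                raise ConfigurationError(
                    f"condition scalar for {cond!r} must be positive and finite"
                )

    def rate_vector(self) -> np.ndarray:
        r = np.asarray(self.base_rates_hz, dtype=float)
        if r.ndim == 0:
            r = np.full(self.n_electrodes, float(r))
        if r.shape != (self.n_electrodes,):
            raise ConfigurationError("base_rates_hz length must equal n_electrodes")
        return r

    def coupling_vector(self) -> np.ndarray:
        c = np.asarray(self.coupling, dtype=float)
        if c.ndim == 0:
            c = np.full(self.n_electrodes, float(c))
        if c.ndim == 2:
            raise ConfigurationError(
                "pairwise coupling matrices are not supported by the "
                "common-source model; pass a scalar or per-electrode vector"
            )
        if c.shape != (self.n_electrodes,):
            raise ConfigurationError("coupling length must equal n_electrodes")
        return c

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator injected, for validating the analysis."""

    spike_times: dict[str, np.ndarray]
    coupling_matrix: np.ndarray
    source_times_s: np.ndarray
    nb_intervals: tuple[tuple[float, float], ...]
    nb_participants: tuple[tuple[str, ...], ...]
    condition_scalar: float


@dataclass(frozen=True)
class ElectrodeMetrics:
    electrode_id: str
    spike_count: int
    mfr_hz: float
    active: bool


@dataclass(frozen=True)
class Burst:
    electrode_id: str
    start_s: float
    end_s: float
    n_spikes: int


@dataclass(frozen=True)
class NetworkBurst:
    start_s: float
    end_s: float
    participating_electrodes: tuple[str, ...]

    @property
    def n_participants(self) -> int:
        return len(self.participating_electrodes)


@dataclass(frozen=True)
class CCGResult:
    """Cross-correlogram of one electrode pair with its significance verdict.

    ``coupling_strength`` is the maximum of the normalized correlogram
    (counts / sqrt(N_i * N_j)) within the peak-search window; ``significant``
    means the peak exceeded the jitter-surrogate max-statistic threshold.
    """

    pair: tuple[str, str]
    lags_s: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray
    peak_lag_s: float
    coupling_strength: float
    z_peak: float
    significant: bool
    null_threshold: float
    p_value: float
    testable: bool = True


@dataclass(frozen=True)
class CouplingDistribution:
    """Coupling strengths of the significantly coupled pairs of one session."""

    assembloid_id: str
    condition: str
    strengths: np.ndarray
    n_pairs_tested: int
    n_significant: int

    def __post_init__(self):
        s = np.asarray(self.strengths, dtype=float)
        object.__setattr__(self, "strengths", s)
        if self.n_significant != s.size:
            raise ValueError("n_significant must equal len(strengths)")
        if self.n_significant > self.n_pairs_tested:
            raise ValueError("more significant pairs than pairs tested")


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one statistical comparison, flagged when degenerate."""

    test_name: str
    statistic: float
    df: float
    p_value: float
    group_sizes: tuple[int, ...]
    adjustment: str = "none"
    p_adjusted: float | None = None
    degenerate: bool = False
    label: str = ""
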