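# Methods

This note documents the models, parameter choices, and numerical conventions
behind `meanet`, and what validation on synthetic data does and does not
establish.

## Synthetic recordings

### Generative model

One simulated session (one assembloid × one condition) draws, per electrode
`i`:

1. **Background**: a homogeneous Poisson process at rate `s·r_i`, where
   `r_i` is the electrode's base rate (Hz) and `s` the condition scalar.
2. **Coupled spikes**: a hidden common-source Poisson train at rate
   `s·r_src`; electrode `i` receives each source spike independently with
   probability `c_i ∈ [0, 1]`, jittered by Gaussian noise of SD
   `copy_jitter_sd_s`. Two electrodes therefore share source spikes with
   probability `c_i·c_j`, which produces a cross-correlogram peak near zero
   lag whose height grows with the coupling probabilities — the synchrony
   construct the coupling analysis is designed to detect. The exported
   ground-truth pair matrix is `c_i·c_j` with zero diagonal.
3. **Network bursts**: epochs arrive as a Poisson process at
   `nb_rate_per_min`, last `nb_duration_s`, and recruit a random subset of
   `round(nb_participation · n)` electrodes; recruited electrodes add extra
   Poisson spikes at `s·r_i·(nb_rate_multiplier − 1)` inside the epoch, so
   the within-epoch rate is `multiplier × base`.

The superposition is deduplicated and refractory-enforced by forward
deletion (keep the first spike, drop any follower closer than
`refractory_s`; deterministic for sorted input). Condition scalars multiply
*all* rates: GABA suppression is a scalar < 1, PTX disinhibition a scalar
> 1, applied uniformly.

Randomness flows from a single seed through fixed-key
`numpy.random.SeedSequence` streams, one per (condition, role, electrode),
so identical configurations reproduce identical trains on any platform and
adding new streams cannot reshuffle existing ones. In a cohort, each
assembloid gets one derived seed shared by its three conditions — the
conditions of one assembloid share base rates and coupling and differ only
in the condition scalar and in the realization stream.

### Raw-trace rendering

Sessions can be rendered to acquisition-style traces: per channel, Gaussian
noise of chosen SD plus a biphasic (negative-then-positive) 1.2 ms template
added at the nearest sample to each spike time, then rounded and clipped to
signed 16-bit at 25 kHz. The template shape is a conventional extracellular
waveform and is a fixture choice, not a biophysical claim.

### What the generator emulates — and does not

It reproduces the statistical structure the analysis assumes: heterogeneous
background rates, tunable pairwise synchrony with near-zero lag, synchronized
burst epochs, multiplicative drug effects, and a realistic acquisition format
(60 electrodes, 30 min per condition, 25 kHz/16-bit are the defaults).

It does **not** model membrane or synaptic dynamics, directed or delayed
coupling, waveform diversity, electrode drift or impedance variation,
oscillatory rhythms, or slow nonstationarity. Passing the validation suite
therefore shows the *pipeline* is correct and calibrated under its stated
assumptions; it does not certify performance on real recordings whose
structure departs from them (e.g. lag-asymmetric coupling or strong
rate drift). Default base rates (0.1–3 Hz range in examples) are plausible
for organoid cultures but are fixtures, not reproductions of any measured
values.

## Spike detection

Zero-phase 2nd-order Butterworth band-pass (300–3000 Hz default, applied
forward-backward so spike times are not skewed), per-channel robust noise
estimate `σ = median(|x|)/0.6745` (the MAD-to-SD factor for Gaussian noise;
robust to the spikes themselves), and local-extremum threshold crossing at
`k·σ` (default `k = 5`, negative polarity — the dominant polarity of
extracellular somatic spikes). Events closer than the refractory period
(default 1 ms) collapse to the larger-amplitude one. Extrema within a guard
of 3× the filter's settling length at the low band edge (≈10 ms at
300 Hz/25 kHz) are discarded to avoid filter-transient false positives. A
channel whose noise estimate is zero yields an empty train. Because the
threshold is σ-relative, detections are invariant to positive rescaling of a
trace. No spike sorting is attempted: the analysis unit is the electrode
(multi-unit activity), not the neuron.

Detection settings are deliberately exposed as parameters with logged
defaults rather than asserted as any particular instrument's or study's
values.

## Burst and network-burst detection

Single-electrode bursts use a Max-Interval-style scan: a burst opens at an
inter-spike interval ≤ `max_isi_start_s` (default 0.1 s), extends while ISIs
stay ≤ `max_isi_in_burst_s` (0.2 s), and is kept with ≥ 5 spikes and
≥ 50 ms duration. A network burst is declared wherever burst onsets from at
least `nb_min_fraction` (default 0.25) of the session's *active* electrodes
fall within a sliding `nb_window_s` (0.1 s) window; windows are anchored at
burst onsets, tied onsets belong to the anchor's window, overlapping
qualifying windows merge transitively, and the NB extent is the union of the
participating bursts' spans (a deterministic merge rule independent of scan
order). An exhaustive O(n²) enumeration of the same definition serves as the
test oracle. All burst criteria are package defaults in the Max-Interval
tradition, configurable and recorded in outputs.

## Coupling analysis

For a pair `(i, j)`, lags `τ = t_j − t_i` are histogrammed in bins of
`bin_s` (5 ms) centered on zero spanning ±`window_s` (100 ms); bins are
half-open `[center − bin/2, center + bin/2)`, so the histogram total equals
the exact number of spike pairs inside the support, and `CCG_ij(τ) =
CCG_ji(−τ)` at count level. Counts are normalized by `√(N_i N_j)`
(geometric-mean normalization): the zero-lag value of a train against itself
is exactly 1, and duplicating a recording leaves the value unchanged, making
the peak a rate-scale-free coincidence measure. The **coupling strength** is
the maximum normalized value within ±`peak_search_s` (50 ms).

Significance uses a spike-time jitter null: each surrogate displaces every
spike of the second train by Uniform(±20 ms), clipped to the recording and
re-sorted — preserving spike count, rate, and slow co-fluctuations while
destroying fine-timescale synchrony. The null statistic is the *maximum*
normalized bin over the same search window, which absorbs the multiplicity
of bins searched. With `n` surrogates the add-one empirical p-value is
`p = (1 + #{surrogate max ≥ observed peak}) / (n + 1)`; a pair is
significant when `p ≤ α` (defaults `n = 100`, `α = 0.01`, so significance
requires the observed peak to beat every surrogate). Ties count against the
observed peak, which makes the test conservative for sparse, discrete CCGs —
measured false-positive rates under independence sit at or below the nominal
α. Configurations where `α < 1/(n+1)` are rejected outright since no pair
could ever be significant. Surrogate RNG streams are keyed by (seed, pair
labels, session, surrogate index), so verdicts are independent of iteration
order. A per-session coupling distribution tests all unordered pairs in
scope (default: active electrodes, since near-silent electrodes yield
degenerate CCGs; pairs with an empty train are excluded from the tested
count) and retains the strengths of significant pairs only.

The normalization and null model are this package's declared choices for the
generic construct "normalized cross-correlogram peak with significance
filtering"; both are recorded in output metadata.

## Group statistics

- **Kruskal-Wallis** (chi-square approximation, average ranks for ties with
  the standard `1 − Σ(t³−t)/(N³−N)` correction) compares coupling-strength
  distributions between genotypes; both poolings — pair-level pooled across
  assembloids, or one summary per assembloid — are supported, and the
  pooling used is recorded in the comparison label.
- **Paired t** (df = n−1, pairing by assembloid) for drug effects;
  **Welch t** (Satterthwaite df) for unpaired contrasts.
- **Genotype × condition factorial**: fixed-effects two-way ANOVA on a
  per-assembloid metric (the assembloid is the experimental unit — electrode
  values are never pooled, avoiding pseudo-replication), followed by
  per-condition genotype contrasts with Šidák adjustment
  `p_adj = 1 − (1 − p)^m`.
- Zero-variance degenerate inputs return flagged results (statistic 0,
  p = 1) rather than raising, so synthetic edge cases cannot abort a run.

Standard tests are delegated to scipy/statsmodels and verified in the test
suite against independent hand and rank-formula oracles.

## Metrics conventions

- Active electrode: MFR ≥ 0.1 Hz over the full recording (a common MEA
  convention; no numeric criterion is asserted as anyone else's).
- Session MFR averages per-electrode rates over *all* electrodes by default;
  active-only scope is available and always recorded, since the choice
  couples the MFR to the activity threshold.
- Log transforms are base 10 with offset 0 by default; zeros are out of
  domain and must be excluded explicitly (exclusion counts are logged).
- Drug response = MFR(drug)/MFR(BL) per assembloid; undefined (NaN with a
  warning) when the baseline MFR is zero.
- Analysis always uses the full recording; short display windows (e.g. the
  5-minute raster panels) are rendering conventions only.

## Pipeline, determinism, and problem sizes

All analysis products are TSV/JSON with fixed float formatting; HDF5 is used
only for raw traces. The manifest echoes the full configuration and master
seed, and rerunning from a manifest reproduces every text output
byte-identically (covered by tests). The pipeline can start from rendered
raw traces (render → filter → detect) or directly from simulated spike
tables; the raw route is exercised at desk scale (tens of seconds of
recording), while cohort-level runs use the spike-table route with 600 s
sessions and 12 electrodes — sizes chosen so the full validation suite runs
in minutes on one core while keeping every statistical check well powered.

## Known limitations

- The coupling test is one-sided for peaks (excess synchrony); troughs
  (inhibition signatures) are not tested.
- Jitter surrogates displace one train of the pair; lag structure broader
  than the jitter half-width (20 ms) is preserved under the null by design
  and will not be flagged.
- The common-source coupling model cannot realize an arbitrary symmetric
  pair-coupling matrix — only rank-one structures `c_i·c_j`; richer motifs
  (chains, delayed projections) are out of scope.
- The NB detector requires bursts detectable per electrode; electrodes whose
  within-burst rate is too low to satisfy the burst criteria are invisible
  to it, so NB participation is a lower bound at low rates.
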