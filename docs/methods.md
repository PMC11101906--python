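# Methods

## Generative model

The synthetic session generator is phenomenological: it reproduces the
statistical structure the analyses are sensitive to, not the biophysics
of dorsal-horn circuitry.  Per unit *i* and indentation trial *t* with
force *F*, private spikes are drawn from an inhomogeneous Poisson process
with rate

```
λ_i(τ) = g_t · [ b_i + 1{F ≥ θ_i} · w_i(F) ·
                 (A_on·α(τ; τ_on) + A_sus·box(τ) + A_off·α(τ−D; τ_off)) ]
```

where `b_i` is the baseline rate (Hz), `θ_i` the force threshold (mN),
`α` an alpha kernel with unit peak, `box` the indicator of the step
(duration `D` = 0.5 s), and `g_t` a trial-shared lognormal gain with unit
mean and configurable CV.  `w_i(F)` is a per-unit force-tuning weight
mixing a shared saturating template with a private lognormal template
(mixing weight `ρ`, normalized to unit mean so amplitudes keep their Hz
meaning); increasing `ρ` increases expected signal correlation.
Sampling is by thinning, which is exact for bounded rates.

Millisecond synchrony is injected by a **population-event process**
rather than a common Gaussian latent: events occur Poisson at
window-specific rates (ON/sustained/OFF of each step, and brush epochs),
and unit *i* emits one spike per event with probability `p_i` at the
event time plus `N(0, σ_sync)` jitter.  This gives independently tunable
per-unit coupling (`p_i`) and timescale (`σ_sync`), and — conditional on
the event train and the gains — units are independent, so analytic
moments are available for estimator tests (e.g. the expected lag-0
co-spike count `N_events·p_i·p_j·q(σ_sync, bin)` with `q` the probability
that two jittered spikes share a bin).  Stimulus-locked events recruit a
unit only on trials whose force reaches that unit's threshold; otherwise
sub-threshold forces would inherit evoked synchrony and every unit would
appear to respond at the weakest force.

The first spike of the ON response is forced to `N(µ_i, SD_i)` after
onset whenever the trial's ON response would otherwise start later,
modeling the reliable, low-jitter ON transient
(`force_first_spike=False` disables this, e.g. for flat-response
populations used in signal-correlation tests).  Event and private spikes
are merged and deduplicated at the 20 kHz sampling resolution (50 µs).
All randomness flows from one seed through a named-stream splitter
(`SeedSequence` spawn keys hashed from stream names), so adding units
does not perturb existing ones and identical seeds give byte-identical
sessions.

The stationary variant (`simulate_correlated_population`) drops the
stimulus machinery and adds a **slow shared gain**: a piecewise-constant
lognormal gain (default blocks of 5 s, CV 0.5 where enabled) multiplying
all background rates.  Real population recordings carry slow shared-state
fluctuations of roughly this size; they matter for the bin-size sweep
(below) because they contribute to coupling at every bin size while
millisecond events do not.

Defaults for the condition presets (16 units, 8 per depth stratum,
baseline 6 Hz, `A_on/A_sus/A_off` = 40/20/30 Hz, `p_i` = 0.4,
`σ_sync` = 1 ms, gain CV 0.2, thresholds drawn from {5, 10, 20} mN,
12 trials per force at 1–75 mN) are stated conventions chosen to give
clearly resolvable effects at desk scale.  The preset perturbations
(`sni_like`: superficial `p_i` halved, `A_sus` × 0.7, latency SD doubled;
`pv_silenced_like`: rates × 1.3, `p_i` halved; `psi_ko_like`: rates
× 1.3, `p_i` × 1.5, thresholds one force step lower) encode the
*directions* of the corresponding biological manipulations; their
magnitudes are conventions for recovery testing, not estimates of
biology.

### What the generator does not emulate

No conductance-based network, no afferent conduction delays, no
receptive-field geometry, no bursting or refractory structure beyond the
50 µs floor, no electrode drift, and no spike-sorting errors.  Passing
recovery tests therefore demonstrates estimator correctness under the
stated statistical assumptions, not robustness to every failure mode of
real recordings.

## Estimators and calibration

**Population coupling.**  Counts are binned at 1 ms (configurable) over
an epoch — a union of windows, concatenated; lagged statistics never
straddle a window boundary.  For unit *i* with per-bin counts `n_i` and
population counts `pop`, the spike-triggered population rate at lag 0 is
`Σ_b n_i[b]·(pop[b] − n_i[b]) / Σ_b n_i[b]`, converted to Hz by the bin
width.  The null redraws unit *i*'s spikes uniformly over the epoch bins
with the population held fixed; coupling is observed minus the null
median (100 shuffles by default).  Shuffling only the trigger unit keeps
the population structure intact so the null is interpretable as chance
coupling of this unit to the real population; a whole-population
shuffle would also destroy the reference structure being measured.
Units with fewer than 10 epoch spikes are flagged null; coupling requires
at least 5 simultaneous units in the analyzed stratum.  The depth
boundary is half-open (superficial = [0, 240) µm) so boundary units are
assigned deterministically.

**Pairwise statistics.**  Synchrony and cross-correlograms are Pearson
correlations of binned counts (1 ms, lags to ±50 ms); noise correlations
are Pearson correlations of per-window counts over the per-trial 1.5 s
pre-stimulus baselines (≥20 windows); signal correlations are Pearson
correlations of trial-averaged PSTHs at 50 ms bins concatenated across
stimuli of one class.  Pearson is used throughout for consistency.  The
Pearson helper uses a symmetric dot-product form so that
`ccg(i→j, ℓ) = ccg(j→i, −ℓ)` holds bit-for-bit.  Under a shared gain
with CV `c`, counts over windows of length `T` at rates µ have expected
pairwise correlation `c²µ_iµ_jT² / √[(µ_iT + c²µ_i²T²)(µ_jT +
c²µ_j²T²)]`; this closed form (exact for any unit-mean gain
distribution) is the oracle for the noise-correlation tests.

**Threshold detection.**  Baseline firing is measured over the 1.5 s
before each step.  A naive bootstrap of full-length baseline means has
far smaller variance than a 50 ms window trial-mean, so comparing the two
is badly miscalibrated on Poisson data.  The bootstrap here therefore
resamples, per replicate, `n` per-trial baseline rates measured in
randomly placed windows **length-matched** to the tested response window,
with `n` the per-force trial count — giving the null replicate the same
sampling variance as the test statistic.  Because three windows are
tested at each force, the default applies a Bonferroni correction across
all tested force × window combinations (family-wise α = 0.05);
`correction="none"` recovers the single-test bound.  The threshold is
the smallest force (ascending, ties impossible) whose ON, OFF, or
SUSTAINED trial-mean rate exceeds its bound; units that never cross are
excluded as baseline-only.  With these choices, pure-noise units return
null ≈ 95–97% of the time and an injected 10 mN threshold (ON response
30 Hz over a 3 Hz baseline, 50 trials/force) is recovered in ≈ 99% of
units.

**Latency and jitter.**  Per-trial first-spike latencies in a 100 ms
search window (an undocumented convention; configurable) are accumulated
into a cumulative count curve at 1 ms bins and compared against the band
of the same curve on surrogate trains with spike times redrawn uniformly
per trial over (onset − 1.5 s, onset + window], preserving counts.  The
cumulative curve is preferred over the per-bin histogram (available via
`mode="histogram"`) because its crossing time is well defined with
sparse counts.  A per-bin 95% band tested over ~100 bins would flag
roughly a quarter of pure-noise units, so the default band is
simultaneous: the studentized maximum statistic across bins sets the
band height, making the family-wise crossing rate α by construction
(`band="pointwise"` keeps the per-bin reading).  Latency is the left
edge of the first crossing bin; jitter is the SD of defined per-trial
latencies (trials without a window spike count toward `n_trials` only).
Results are null below 50 trials (hard error) or without a crossing.
The opto-tag classifier reuses this machinery per light block
(response window 10 ms, ≥25 pulses/block); tagged requires
responsiveness both pre- and post-blocker, median latency < 10 ms, and
jitter ≤ 3 ms.

**LFP.**  Zero-phase (forward-backward) 8-pole Butterworth low-pass at
250 Hz, Welch PSD with segments the power of two nearest 2 s and 50%
overlap (conventions; configurable), channel-averaged; relative band
power integrates the PSD by trapezoid over the band against (0, 250] —
the post-filter range is used as the denominator.  The waveform "slope"
feature is the post-peak repolarization slope over 0.5 ms (a common
convention; the choice is configurable).  K-means uses standardized
features, k-means++ seeding, best of 20 restarts.

## Bin-size sweep

The sweep compares coupling at 1, 3, and 10 ms bins between
high-synchrony (`p` = 0.4) and low-synchrony (`p` = 0.1) conditions with
`σ_sync` = 1 ms, 12 sessions per arm, 20 units, 60 s each.  In Hz units
the event-driven coupling contribution scales like `q(σ_sync, bin)/bin`
and so falls ≈ 3.6-fold from 1 to 10 ms bins, while the slow-gain
contribution and the session-level variability it induces are
bin-insensitive; the standardized (Cohen's d) group difference at 10 ms
is therefore well under half the 1 ms difference, while the 3 ms
difference remains significant — the millisecond-timescale signature the
sweep is designed to resolve.  Without the slow shared gain this
collapse does not occur, because estimator noise also shrinks with bin
size.

## Problem sizes

Recovery tests and the acceptance script run at desk scale, chosen as
the smallest sizes at which the effects are statistically unambiguous:
100 s / 20 units for coupling calibration and recovery; 12 sessions per
arm for the sweep and the condition contrasts (16 units, 72 trials
each); 100 units at 50 trials/force for threshold recovery; 100 trials
for latency; 200 baseline windows for noise correlations; 30 s traces at
1 kHz for spectra.

## Known limitations

- The shuffle null for coupling redraws spikes uniformly, which destroys
  slow rate structure of the trigger unit; coupling therefore includes
  slow shared covariation as well as millisecond events (the bin sweep is
  the tool that separates the timescales).
- Signal correlations inherit any shared within-step temporal profile;
  tuning-similarity claims should be read against the flat-response
  oracle used in the tests.
- The latency estimate is the null-band crossing of a cumulative curve:
  it tracks the earliest *reliable* response (≈ 2 SD before the mean of a
  Gaussian first-spike distribution), not the mean latency.
- Group contrasts assert effect directions with rank-sum tests; no
  mixed-effects or per-animal nesting is implemented.
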