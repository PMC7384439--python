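# Methods

This note documents the models and estimators implemented in `songsel`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot establish about real recordings.

## Timing conventions

All times are seconds from trial start; t = 0 at trial start, stimulus
onset at `pre_silence_s` (0.5 s); every interval is half-open `[a, b)`;
spike times are stored at microsecond precision. A trial window is
pre-silence + stimulus duration + post-silence. PSTHs use 20 ms bins
tiling the trial window; the last bin may be partial.

## Generative model for synthetic sessions

Each unit is an inhomogeneous Poisson process

    lambda(t) = max(0, spont + g · T(stim) · k(t) · e(t)),

where `spont` is the spontaneous rate (spikes/s), `g` the response gain
scaled by the song-type gain (`con_gain`/`het_gain`), `T` the frequency
tuning, `k` the temporal kernel and `e` the stimulus amplitude
envelope. For stimuli the unit is inhibited by, the drive enters with a
negative sign; the rate is clamped at zero. Sampling discretizes the
rate at 1 ms (piecewise-constant), draws Poisson counts per bin and
places spikes uniformly within bins — exact for that rate function.

**Tuning** is Gaussian in log2-frequency around the unit's preferred
frequency (bandwidth in octaves, default σ = 0.5). Tones are evaluated
at the tone frequency; white noise and songs use the mean tuning over a
log-spaced grid spanning the stimulus's aggregate band descriptor
(floored at 100 Hz so the log grid is defined for a 0 Hz descriptor).

**Temporal kernels** act from each envelope syllable onset, within the
syllable (τ = 30 ms throughout):

- onset: `5·exp(−Δ/τ)`;
- sustained: 1;
- primary-like: `1 + 2.5·exp(−Δ/τ)`;
- primary-like with notch: primary-like suppressed to 5% during
  50–100 ms after onset.

The kernel applies to the tone and white-noise probes — the stimuli the
pattern taxonomy is defined on. Song responses are *isomorphic*: they
follow the song's amplitude envelope for every unit, which is how most
midbrain units respond to song regardless of their tone-probe class.
This also means a unit's CON-vs-HET response difference is governed by
the song-type gains rather than by incidental interactions between the
unit's probe-response kernel and syllable bookkeeping — the property
the rearing scenarios are meant to isolate.

**Song envelopes** are abstract syllable sequences, not audio:
conspecific songs use 50–200 ms syllables (broad harmonic-stack bands,
500 Hz – 8 kHz) with 20–80 ms gaps; heterospecific songs use 20–60 ms
trill syllables with 10–40 ms gaps, individually narrow bands whose
centres wander over the same overall range. Every song's envelope is
normalized to a time-average amplitude of 0.5, so a song's mean drive
is set by the unit, not by its syllable statistics. Durations are drawn
uniformly within the species ranges (CON 1.816–2.691 s, HET
1.940–3.091 s). The reversed version of a song is the exact time mirror
of its envelope.

**Population hyperparameters** (module defaults, chosen to emulate
midbrain response statistics, not measured values): spontaneous rates
from a mixture of 20% exactly 0, a majority uniform on (0.2, 5) and an
8% tail up to 15 spikes/s (group-independent, so the null scenario
keeps birds exchangeable across groups); response gain lognormal with
median 40 spikes/s and log-SD 0.5; preferred frequencies concentrated
at 1–3 kHz; pattern mix 20/40/25/15% (onset/sustained/primary-like/
notch); 10% of units inhibited by 1–3 stimuli. Ground-truth recovery is
benchmarked at a gain of 80 spikes/s (`HIGH_SNR_GAIN`), where labels
are unambiguous by construction.

**Scenarios.** `null`: both groups have `con_gain = het_gain = 1`;
birds are exchangeable across groups, which is exactly the invariance
the bird-level permutation test needs. `rearing_effect`: ZF-ZF units
get `con_gain = 1.3`, all other gains stay 1.

**Protocol.** Each unit receives all 19 stimuli × 15 repeats (285
trials) in randomized order, a per-sequence constant inter-stimulus
interval drawn from {0.5, 0.6, …, 1.5} s, and a 30 s baseline segment.
A session is bit-reproducible from its seed.

A second sampling path, `simulate_rs_long_table`, draws only the window
spike counts that Response Strength needs (Poisson with the integrated
rate as mean) — an exact marginal of the spike-train path, used for the
thousand-replicate calibration studies; a test pins the two paths to
the same rate model.

## Estimators

**Spontaneous rate**: spike count in the first 20 s of the 30 s
baseline, divided by 20.

**Auditory criterion**: a unit responds to a stimulus when at least one
20 ms stimulus-period PSTH bin exceeds a threshold of mean + 5 SD of
the pre-stimulus baseline bins. The baseline statistics pool every
trial's 25 pre-stimulus bins (375 values at 15 repeats). Because the
PSTH bin being tested is a sum over repeats, the threshold is expressed
on that scale: a sum of n independent baseline bins has mean n·μ and SD
√n·σ. A floor of 3 summed spikes guards the degenerate silent baseline
(SD = 0): one stray spike cannot make a silent unit auditory, while a
response repeated across trials still can. The alternative
single-trial-rate scaling is available (`baseline_stat=
"per_trial_rate"`); it is far more conservative because single-trial
bins at these rates are dominated by Poisson noise. Measured on
pure-spontaneous units at 5 spikes/s, the default rule's false-positive
rate is ≈ 3.5% per unit × stimulus and matches a direct Monte-Carlo
oracle of the same rule; the criterion is blind to inhibition by
construction.

**Response sign**: excited when the criterion passes; otherwise
inhibited when the mean stimulus-period rate falls 2 standard errors
(SD of per-trial pre-stimulus rates over √n) below the mean
pre-stimulus rate and the unit has nonzero spontaneous activity;
otherwise none. The SE scaling (rather than raw SD) is what makes an
80% suppression of a 10 spikes/s unit reliably detectable at 15 trials.

**Best frequency**: the tone with the largest mean evoked rate among
tones with an excited sign; ties go to the lowest frequency; absent
when no tone excites the unit (such units can still be auditory through
songs).

**Temporal patterns** (a deterministic version of a visual taxonomy):
with `early` = mean rate in the first 100 ms after onset, `steady` =
mean rate from 100 ms to offset, `peak` = maximum bin within 150 ms of
onset, and a 1 spike/s floor `s0` standing in for spont in ratio tests:
onset requires `early ≥ 2·s0` and `steady` below the midpoint of spont
and `early`; otherwise primary-like requires `peak ≥ 2·steady` with
`steady > spont + 1`, with notch if any bin within 150 ms after the
peak drops below half the plateau; otherwise sustained requires
`steady ≥ 2·s0`; anything else is unclassified. The rules are validated
by generator-label recovery (≥ 90% at the high-SNR benchmark), not by
visual agreement.

**Response Strength**: per trial, evoked rate (spike count during the
stimulus divided by its duration — the 500 ms post-silence is excluded)
minus that same trial's 500 ms pre-stimulus rate; RS is the mean over
available repeats, and may legitimately be negative for suppressed
responses. The variance uses the n−1 denominator (small trial counts).

**Selectivity Index**: `RS_A/(RS_A + RS_B)`, defined only when both
means are positive (otherwise the ratio leaves [0, 1] and is not
interpretable; the absence is recorded with its reason). The cut-offs
are SI ≤ 0.33 or SI ≥ 0.66 — note they are asymmetric around the exact
2:1 boundary: 2/3 meets the upper cut-off while the mirrored 1/3 does
not fall below the lower one. The asymmetry is applied as stated, not
"fixed", and a test pins it.

**d′**: `2(RS̄_A − RS̄_B)/√(σ²_A + σ²_B)`; antisymmetric under pair
swap, invariant to shifting or scaling both trial vectors. When both
sample variances vanish, d′ is 0 for equal means and a signed infinite
sentinel otherwise — reported, flagged, counted as selective (infinite
discriminability for any mean difference), and excluded from
cumulative-distribution summaries.

**Song panels**: each forward song is compared against its own reverse
and the other five forward songs (six comparisons per forward song for
a complete unit). Missing stimuli are skipped and the per-song
comparison counts expose the gap, so incomplete units are analysed, not
dropped.

**Forward/reverse bias**: in the (RS_FOR, RS_REV) plane the minimum
distance of a unit-song point to the identity line, signed positive
when the forward response is larger: `(RS_FOR − RS_REV)/√2`.

## Group inference

**Long table and transform.** One row per unit × song stimulus. The
natural-log transform uses `ln(RS + c)` with `c = 1 − min(RS)` over the
table, making the smallest log argument exactly 1 so that negative RS
values stay representable; c is stored with the table.

**Random-intercept REML.** A two-level linear mixed model with random
intercepts for bird and unit-within-bird and fixed effects for rearing
group, song type, direction, song-within-type and group × song type.
Song dummies are nested within song type (first song of each type as
reference); a flat song coding is exactly collinear with the song-type
column. The restricted likelihood is optimized over log variance
components (L-BFGS-B with a Nelder-Mead fallback); all linear algebra
goes through the q × q Woodbury factor `σ²_e G⁻¹ + Z'Z`, so the cost is
O(nq) + O(q³) rather than O(n³). A dense O(n³) evaluation of the same
objective exists purely as a test oracle, and the fit is cross-checked
against an independent mixed-model implementation in the test suite.
Components touching the lower bound (log-variance −12) are boundary
estimates. This model deliberately simplifies a repeated-measures
analysis with unstructured covariance: the random-intercept structure
captures the clustering that matters for the headline question, and the
permutation test below does not depend on the covariance model at all.

**Bird-level permutation test** (the headline inference). Statistic:
the group difference of bird-mean (CON − HET) response strength, where
bird means pool all units and songs of a bird. The null distribution
reassigns rearing labels across whole birds — exhaustively when the
number of assignments is at most 20,000 (6 vs 6 birds gives
C(12,6) = 924), otherwise by seeded Monte-Carlo with the add-one
correction. Because birds are the independent replicates and the null
scenario makes them exchangeable, the test is valid under arbitrary
within-bird correlation; with exact enumeration the p-value is exact up
to the discreteness of 924 assignments. Measured calibration: type-I
error 0.045 at α = 0.05 over 1,000 null datasets (12 birds × 8 units);
power 1.0 over 200 replicates under `rearing_effect` with a 1.3×
conspecific gain.

**Mann–Whitney U**: rank-sum U with the exact enumeration null when
min(n₁, n₂) ≤ 8 and there are no ties, otherwise the normal
approximation with tie and continuity corrections. **Levene**: the
Brown–Forsythe variant (absolute deviations from group medians into a
one-way ANOVA F). Both match their scipy counterparts in tests but are
implemented independently.

## Numerical choices

- Sample (ddof = 1) SDs/variances throughout.
- Threshold comparisons use a 1e-12 slack so exact-boundary counts
  (e.g. the 3-spike floor) pass deterministically.
- Permutation p-values compare |T| with a 1e-12 tolerance; the observed
  assignment is always included.
- d′'s antisymmetry is exact in floating point; shift/scale invariance
  holds to 1e-12 relative tolerance and is tested at that level.
- Spike times are rounded to 1 µs at generation, which is what makes
  the session format round-trip bit-exact.
- The REML optimizer runs on log variances with bounds [−12, 8];
  boundary convergence is reported, not an error.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis
assumes: Poisson spiking with stimulus-locked drive, clustered units
within birds, protocol bookkeeping, inhibition, missing stimuli. It
does not reproduce real-data features such as non-Poisson spiking
statistics (refractoriness, bursting), adaptation across repeats,
correlated noise between units, spike-sorting artifacts, or genuinely
heterogeneous song-feature selectivity. Passing tests therefore
establish that the estimators compute what they claim and that the
inference is calibrated under the stated model — not that the model is
a complete account of midbrain physiology. Calibration studies run at
desk scale (e.g. 1,000 replicate datasets at the RS level, 500 units
for criterion calibration, 200 units for recovery benchmarks), chosen
as the sizes at which the binomial error of the measured rates is well
below the margins being tested.

## Known limitations

- The criterion's false-positive rate depends on the spontaneous rate;
  the conservative 5 SD rule plus floor keeps it low but nonzero, and
  inhibited-only units are invisible to it (an explicit inhibition test
  partially compensates).
- SI is undefined for non-positive mean RS; comparisons involving
  suppressed responses rely on d′ only.
- The REML model omits the repeated-measures covariance between songs
  within a unit; variance-component estimates are interpretable under
  the random-intercept structure only.
- With 12 birds the exact permutation p-value has granularity 2/924, so
  attainable significance levels are discrete.
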