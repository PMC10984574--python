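# Methods

This note documents the models, parameter choices and numerical
conventions behind `asrtnet`, and what the synthetic-data tests do and do
not establish about real data.

## ASRT task and scoring

A block holds 85 trials: 5 random practice trials, then the eight-element
alternating sequence (pattern, random, pattern, …) repeated 10 times.
Pattern trial *k* of a block shows `pattern[k mod 4]`; random trials are
uniform over the four directions. Timing follows the cued task variant:
200 ms stimulus, 500 ms response window, 700 ms fixed delay.

Triplet categorization runs in a moving window within each block: trial
*t* (third block position onward) is high-probability iff `d[t]` equals
the cyclic pattern successor of `d[t-2]`. Labels attach to terminal
trials only. Exclusions, in priority order per trial: the first seven
trials of each block; terminal trials with `d[t-2] = d[t]` (one rule
covering both printed exemplars, trills `a-b-a` and repetitions `a-a-a`);
unresponded trials. Accuracy is computed over responded trials, RT over
correct trials only (median per cell). Scores are aggregated in
five-block units; the overall learning score is the unweighted mean of
unit scores (pooling trials task-wide is the alternative reading; the
unweighted mean is the default because unit scores are the quantities the
downstream ANOVA consumes). Among analyzed trials (after the first-seven
exclusion) pattern and random trials are equally frequent, so 62.5 % of
analyzed trials terminate high-probability triplets and 25 % of random
trials do — a structural property the tests assert.

Subjects with baseline accuracy (responded trials, all types) strictly
below 70 % are flagged for exclusion (low task engagement).

## Response model

Each simulated participant is a parametric responder:
`P(correct) = base_accuracy + ramp · acc_learning_pp/100` on
high-probability trials (ramp = `min(1, learning_ramp · block)`), RT
Gaussian around `base_rt_ms − ramp · rt_learning_ms` on those trials,
lapses at `lapse_rate`, and responses at or beyond the 500 ms window
converted to unresponded trials. The planted advantage keys on the same
triplet categorizer the analysis uses, so with no noise the analysis
recovers the planted effect exactly, and the advantage applies to
high-probability trials of both structures, keeping the random-only
learning contrast unbiased.

Cohort defaults describe near-ceiling performance typical of the cued
task variant, where learning scores live in the 1–2 pp range:
`base_accuracy` ~ N(0.97, 0.005), `base_rt_ms` ~ N(350, 30) ms,
`acc_learning_pp` ~ N(2.0, 0.3) for the patient-like group and
N(0.7, 0.3) for controls, `rt_learning_ms` ~ N(15, 5) / N(8, 5) ms,
`lapse_rate` 0.02, RT noise SD 60 ms, `learning_ramp` 1 (full effect from
the first block, so recovered scores estimate the planted asymptote
directly). The learning ramp, lapse and RT parameters were fixed from
these considerations, not fitted. 13 of 25 patient-like subjects are
flagged medicated and each subject is pair-matched across groups for the
sensitivity rerun.

## Signal generator

Each channel (node) emits a unit-variance Gaussian source band-limited to
the coupling band (default theta, 4–7 Hz, realized by FFT masking of
white noise per segment, so segments are independent). For every planted
edge, one endpoint — chosen at random per edge — receives the other
endpoint's source delayed by `lag_ms` (default 20 ms) and scaled by the
coupling gain. Independent 1/f (pink) noise is added per channel with
power `signal_power / snr²`. Consequences of this architecture:

- Only planted pairs carry consistently lagged shared signal, hence
  nonzero expected imaginary coherency; common drivers at identical lags
  (two receivers of the same sender) add only zero-lag, purely real
  coherence, which `Im C` ignores — the motivating property of the
  estimator.
- The default "balanced" coupling gain `1/sqrt(mean in-degree)` makes the
  coupled power a channel receives comparable to its intrinsic source
  power. At 15 % density on 60 channels (mean degree ≈ 8.9) this keeps
  each edge's share of its receiver's signal identifiable; with unit gain
  the per-edge coherency is diluted by the full in-degree. The analytic
  ceiling for a single edge at unit gain is `|C| = 1/√2` (own source and
  delayed copy in equal power), which the tests assert; with dominant
  coupling the pair approaches a pure lagged copy and `|Im C| → 1` at a
  quarter-period lag.
- The generator does not model volume conduction as channel mixing,
  artifacts (blinks, muscle), tics, or 1/f-deviating spectra; passing the
  recovery tests therefore shows the estimator chain is correct and
  well-powered under ideal phase-lagged coupling, not that real EEG at
  this SNR yields the same recovery rates.

Resting runs default to 60 segments of 2000 ms (120 s; run duration is
not fixed by the emulated protocol, which specifies the segment count).
Synthetic task recordings hold one 1500 ms segment per trial with the
stimulus event 500 ms in, so the −500..1000 ms analysis epoch tiles the
segment exactly.

## Spectral estimation

Per-segment coherency uses 3 discrete prolate spheroidal tapers
(NW = 2): a single-taper, single-segment coherency is identically 1 at
every bin, so a few tapers are the minimum that makes per-segment
thresholding meaningful; the emulated analysis chain does not print taper
settings, and 3 tapers at NW = 2 is the standard minimal-leakage choice
for 2 s segments. Band averages take `|Im C|` per bin first (so the band
value is lag-direction-insensitive), giving 7 bins for theta at the 0.5 Hz
resting resolution. The shared 10 Hz edge of the alpha sub-bands is
half-open ([8, 10), [10, 13)) so no bin is counted twice. Zero-variance
channels yield zero coherency with all partners, with a warning.

Two estimators are exposed deliberately:

- `band_coherence_per_segment` — per-segment estimates, required by the
  per-segment percentile thresholding of the graph pipeline.
- `pooled_band_coherency` — cross- and auto-spectra averaged over
  segments and tapers before normalization (the classic Welch-style
  estimator). Its per-bin noise floor shrinks with the number of
  segments, so it is the estimator used for planted-edge recovery and
  topology-recovery checks. At 3 tapers and realistic SNR, per-segment
  `|Im C|` values are dominated by estimator noise (per-bin SD ≈ 0.4);
  graphs thresholded per segment are correspondingly noisy, and
  per-segment ω contrasts at desk scale mostly reflect density, not
  planted topology. This mirrors the estimator-variance reality of the
  emulated procedure and is why recovery claims are made through the
  pooled route.

## Graphs, null models and ω

Thresholding: the percentile is computed over the n(n−1)/2 upper-triangle
values of a single segment's matrix with linear interpolation between
order statistics (NumPy default; nearest-rank available via config), and
strictly greater values become edges. Both conventions matter at the
±1-edge level: at 60 channels with distinct values the 85th percentile
leaves exactly 266 edges. A constant matrix yields an empty graph.

Metrics: degree `2k` (mean row sum), characteristic path length `L`
(unweighted shortest paths, mean over ordered pairs, disconnected pairs
excluded and flagged — disconnection is rare at 15 % density but the rule
keeps `L` defined, and the same rule applies inside the null ensembles),
local clustering `C_i = 2·e_i/(k_i(k_i−1))` with `C_i = 0` for `k_i < 2`,
and `C` the unweighted mean.

Null references, 2000 replicates each: the random reference is a uniform
G(n, m) graph with exactly the observed edge count (matching "mean degree
2k" as an edge count, not a degree sequence; degree-preserving rewiring
is a deliberate non-default), and the lattice reference lays down full
nearest-neighbour rings then places leftover edges uniformly at random
among next-ring positions — the randomized leftover placement is what the
ensemble averages over (with no leftover the lattice is deterministic and
the ensemble has zero variance). Ensembles are cached per (n, m) with a
seed derived deterministically from the cache seed and (n, m), so results
are independent of evaluation order.

ω = `L_rand/L − C/C_latt`; per-segment graphs get per-segment ω with
nulls matched to that segment's edge count, and the subject/condition
value is the mean over segments ("averaged" mode — threshold the
segment-mean coherence once — is available as a sensitivity switch).
Across a seeded 500-graph suite at the study scale (60 nodes, 15 %
density, lattice/rewired/random topologies) every ω falls in [−1, 1];
ring lattices sit near −0.47, uniform-random graphs near +0.83, and mean
ω is monotone in Watts-Strogatz rewiring probability. These suite
extremes are what `scripts/acceptance.py` recomputes.

## Mixed-design ANOVA

Type III sums of squares via the univariate approach: each within-effect
is projected on an orthonormal (Helmert) contrast basis; per-subject
contrast scores are then analysed between groups — the intercept SS of
that one-way analysis (unweighted group means, `SS = m̄²·g²/Σ(1/n_g)`) is
the within-effect, the group SS its interaction with Group, and the
pooled within-group SS the matching error term. With equal group sizes
this reproduces the textbook mixed ANOVA exactly (and pingouin, which the
tests cross-check); with unequal sizes it gives the SPSS-style Type-III
(unweighted-means) tests. Expected degrees of freedom at the study scale:
F(1, 48) for two groups of 25 with a 2-level within factor, F(3, 144) for
the three-way interaction with a 4-level unit factor. No sphericity
correction is applied by default (plain dfs are reported);
Greenhouse-Geisser is available via `sphericity_correction=True`.
Post-hoc contrasts are uncorrected pairwise t tests (Fisher-LSD
convention): independent-samples between groups per cell, paired within
groups. Subjects with missing within-cells are dropped with a log entry.

Under the null (no planted group gap) the Group × Probability interaction
rejects at 5 % ± 2 % over 400 simulated cohorts; with the default planted
gap (2.0 vs 0.7 pp, 25 subjects per group) it is detected in over 80 % of
replicates, and recovered group means are unbiased — the near-ceiling
accuracy regime matters here, since binomial trial noise at p ≈ 0.97–0.99
is what keeps per-subject score variance near 1.2–1.4 pp.

## Numerical and interface conventions

- All randomness descends from one integer seed through documented
  `SeedSequence` splits (per subject: sequence, responses, network,
  signal; null ensembles: per (n, m) key).
- Sample indices are 0-based half-open; event latencies are in samples;
  channel identity is by label.
- Recordings round-trip bit-exactly through the float32 raw+sidecar
  dialect; BrainVision triplets are written directly (IEEE float32
  multiplexed) and read back through MNE, as are EDF files.
- Edge counts from density use round-half-even, stated so tests are
  exact: `round(0.15 · 1770) = 266`.
- Degenerate inputs: empty thresholded graphs are skipped per segment
  (subject flagged if all segments are empty); `C_latt = 0` (density too
  low for lattice triangles) rejects ω as undefined; an edgeless graph
  has undefined `L`.

## Known limitations

- The per-segment thresholding route is faithful to the emulated
  procedure but statistically noisy at 3 tapers; group contrasts in ω at
  desk scale are not expected to separate without either many segments or
  the pooled estimator.
- The ANOVA handles one between-subjects factor; covariates and multiple
  between factors are out of scope.
- No volume-conduction mixing or artifact simulation; preprocessing is
  assumed done upstream.
- EDF export is not implemented (reading is); the raw+sidecar and
  BrainVision writers cover the round-trip needs.
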