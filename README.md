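# asrtnet

Statistical learning in the cued alternating serial reaction time (ASRT)
task, and the small-world architecture of EEG functional-connectivity
networks around it — as one tested, reusable pipeline. The package is
aimed at cognitive-neurophysiology researchers who want to score ASRT
behaviour, build imaginary-coherence brain graphs from multichannel
recordings, and run the mixed-design group statistics that tie the two
together, with a synthetic-cohort generator providing ground truth for
every stage.

## What it computes

**Behaviour.** In the ASRT task, pattern and random trials alternate
(`1-r-2-r-3-r-4-r`). Every trial from the third position of a block
terminates a triplet `(d[t-2], d[t-1], d[t])`; the triplet is
*high-probability* when `d[t]` is the pattern successor of `d[t-2]`.
After the standard exclusions (first seven trials per block, trills and
repetitions `d[t-2] = d[t]`, unresponded trials), the statistical-learning
score per five-block unit is

    acc_learning = acc(high-probability random) − acc(low-probability random)   [pp]
    rt_learning  = RT(low-probability random) − RT(high-probability random)     [ms]

using mean accuracy over responded trials and median RT over correct
trials.

**Connectivity.** Recordings are segmented (2000 ms resting segments;
−500..1000 ms stimulus-locked task epochs with correct responses only)
and, per segment, the complex coherency
`C_xy(f) = S_xy(f) / sqrt(S_xx(f) S_yy(f))` is estimated with 3 DPSS
tapers. Band values (theta 4–7, low alpha 8–10, high alpha 10–13, beta
13–30 Hz) are the mean of `|Im C_xy(f)|` over in-band bins; the imaginary
part discards zero-lag (volume-conducted) coupling by construction.

**Graphs.** Each segment's coherence matrix is thresholded at its own
85th percentile into a binary graph. From degree (`2k`), characteristic
path length `L` and clustering `C`, the small-world coefficient

    ω = L_rand / L − C / C_latt

is computed against 2000-replicate ensembles of edge-count-matched
uniform-random graphs (`L_rand`) and ring lattices (`C_latt`); ω < 0 is
lattice-like, ω > 0 random-like, ω ≈ 0 small-world.

**Statistics.** Type-III mixed-design ANOVAs (one between-subjects group
factor, any crossed within factors) with partial η², Fisher-LSD post-hoc
contrasts, severity correlations against the packaged clinical table, and
a medication-free sensitivity rerun.

## Worked example

```
asrtnet run-all --config configs/demo.yaml --out demo_out
```

simulates a 6+6-subject cohort (20 ASRT blocks each; 32-channel
theta-coupled resting recordings with planted watts-strogatz topologies),
scores it, and writes learning scores, per-subject graph metrics and the
ANOVA tables. On this demo:

```
>>> pd.read_csv("demo_out/subject_summary.csv").groupby("group")["overall_acc_learning_pp"].mean()
GTS    0.790
HC     1.099
>>> pd.read_csv("demo_out/graph_metrics_rest.csv").groupby("group")[["omega", "L_real", "C_real"]].mean()
       omega  L_real  C_real
GTS    0.806   2.348   0.109
HC     0.806   2.354   0.107
```

The patient-like group carries a planted 2.0 pp learning advantage
(vs 0.7 pp), but at 6 subjects per group the Group × Probability
interaction is not significant (`demo_out/anova_behavior.csv`:
F(1,10) = 0.21, P = 0.65) — the study-scale power analysis in
`tests/test_acceptance.py` shows the interaction is detected in over 80 %
of 25+25-subject replicates. Likewise the per-segment resting ω is
noise-dominated at desk scale (both groups ≈ 0.81); planted topology
differences are recoverable from pooled (cross-segment) coherency, see
`docs/methods.md`.

The full study conditions (25+25 subjects, 60 channels, 60 segments,
four bands, 2000 null replicates) are in `configs/study.yaml`.

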