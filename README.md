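# plvmotif

Longitudinal phase-locking-value (PLV) connectivity and permutation motif
statistics for the default mode network (DMN), with a synthetic
phase-coupled cohort generator so the entire inferential chain can be
exercised, calibrated and stress-tested without any MEG or MRI recordings.

## The scientific problem

Adolescent binge drinking has been linked to *hypersynchronisation* of
resting-state brain networks: over a two-year follow-up, the functional
connectivity of the DMN in young binge drinkers increases while it
decreases slightly (normal maturation) in non-drinking controls, with no
detectable change in white-matter microstructure.  Detecting that pattern
requires a fairly involved statistical pipeline, which this package
implements as a reusable, tested library:

1. **Connectivity.** Node-level source time series are band-limited (delta
   2–3.9 Hz, theta 4.1–7.9 Hz, alpha 8.1–11.9 Hz, beta 12.1–29.9 Hz; FIR
   order 1500 at 1 kHz, two-pass/zero-phase), segmented into 4-s trials
   (≥ 15 per subject) and summarised per node pair by the PLV

   $$\mathrm{PLV}_{ij} = \frac{1}{K}\sum_{k=1}^{K}
     \left|\frac{1}{T}\sum_{t} e^{\,i(\phi_i(t,k)-\phi_j(t,k))}\right|,$$

   the across-trial mean modulus of the time-averaged phase-difference
   phasor (0 = independent phases, 1 = perfect locking).
2. **Longitudinal ratio.** Each link is reduced to the ratio
   post-PLV / pre-PLV; values above 1 mean the link synchronised further
   over the follow-up interval.
3. **Link-wise permutation ANCOVA.** Per link within an ROI-pair universe,
   an OLS F-test of `ratio ~ group + sex`, with significance from a
   Freedman–Lane residual permutation null (5000 permutations, add-one
   p-values).
4. **Motifs.** Links with p < 0.05 form a graph; a connected component is a
   *motif* iff it covers ≥ 25% of the nodes of each ROI of the pair and its
   significant links number ≥ 10% of the link universe.  Family-wise error
   over motifs is controlled by a max-statistic permutation test on the
   motif mass (sum of member-link F values).
5. **Summaries.** Each motif is scored per subject by its *degree* (mean
   PLV ratio over motif links), followed by a group ANCOVA (Bonferroni ×5
   over bands), Cohen's d (pooled SD), one-sample t-tests of each group's
   degree against 1, and a leave-one-out logistic-regression accuracy.
6. **Structural arm.** Per JHU-style tract and DTI metric (FA/MD/RD/AD), a
   repeated-measures ANCOVA (difference-score decomposition) with sex as
   covariate tests group, session, and group × session effects.

The synthetic cohort generator produces two groups × two sessions of
narrowband oscillators whose pairwise phase offsets are von Mises
distributed, so each coupled pair's population PLV is known in closed form
(`expected_plv(κ) = I₁(κ)/I₀(κ)`).  Its defaults plant the study's
qualitative structure: a frontal–parietal (FMC–rIPL) coupling whose
concentration shrinks ×0.95 at follow-up in controls and grows ×1.15 in
binge drinkers.

## Worked example

```bash
plvmotif run-all --quick --seed 7 --n-perm 199 --out runs/demo
plvmotif report --report-json runs/demo/report.json
```

prints

```
config hash: 8b2814b8504d435b
subjects: 39, nodes: 24
[theta] FMC-rIPL: 4/16 significant links, 1 motif(s)
    motif mass=239.73 p=0.005 BD ratio 1.094±0.035 CN ratio 0.978±0.033 d=3.39 acc=97%
DTI: 20 tests, 5.0% interaction p<0.05
```

Reading: on a 39-subject desk-scale cohort (22 controls, 17 binge
drinkers; 24-node atlas), 4 of the 16 FMC–rIPL links show a significant
group difference in their theta-band FC ratio, forming one connected motif
whose corrected p is 0.005 (the minimum attainable with 199 permutations).
The binge-drinking group's motif degree is 1.094 ± 0.035 (ratio > 1:
hypersynchronisation), the control group's 0.978 ± 0.033 (ratio ≤ 1:
maturation), the pooled-SD effect size is d = 3.39, and leave-one-out
classification separates the groups with 97% accuracy.  The structural arm
is null by construction: 5% of the tract/metric interaction tests fall
below p = 0.05, as expected under the null.

The same run is available from Python:

```python
from plvmotif.pipeline import RunConfig, run_pipeline
report = run_pipeline(RunConfig(seed=7, n_perm=199, out_dir="runs/demo"))
```

`RunConfig.paper_scale()` switches to the full 156-node / 1 kHz / 5000-
permutation geometry.

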