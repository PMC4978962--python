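# Methods

## Generative model of the synthetic cohort

Each subject's session is a set of trials of node-level instantaneous
phases.  Root oscillators follow

φ(t) = 2π f₀ t + θ₀ + W(t),

with f₀ the band centre frequency, θ₀ ~ U(0, 2π) per trial, and W a
Brownian phase walk with diffusion `phase_diffusion` (rad² per sample,
default 2.0).  Coupling is declared as a symmetric matrix of von Mises
concentrations κ ≥ 0; the κ > 0 graph must be a **forest**.  Phases
propagate parent → child along tree edges:

φ_child(t) = φ_parent(t) + μ + δ(t),   μ ~ U(−π, π) per trial,
δ(t) ~ i.i.d. von Mises(0, κ) per sample,

so the within-trial phase difference of a tree edge is von Mises
distributed and the population PLV of that edge is the mean resultant
length R(κ) = I₁(κ)/I₀(κ) (`expected_plv`).  Pairs connected by a path of
length ℓ couple at the product of the ℓ edge resultant lengths; pairs in
different trees are independent.

Two consequences of the estimator drive this design.  The PLV used
throughout is the *per-trial modulus* of the time-averaged phase-difference
phasor, averaged across trials.  (a) If the offset were constant within a
trial, every coupled pair would read PLV ≈ 1 regardless of κ; the offset
must therefore wander within the trial, which the per-sample von Mises
draws provide.  (b) For uncoupled pairs the estimator has a finite-sample
floor ≈ √(π/(4T)) per trial (T effective samples); the large default phase
diffusion makes root phases decorrelate within a few samples so uncoupled
pairs actually sit at that floor rather than above it.

Why a forest: a generative phase model cannot satisfy arbitrary pairwise
κ constraints simultaneously — a cycle imposes a multiplicative consistency
condition that generally has no solution.  Cyclic plans are rejected as
invalid rather than silently approximated.

Between-subject variability enters as a lognormal multiplier on each
edge's κ, independent per subject × session × edge, with
`subject_kappa_sd = 0.06`.  By the delta method this makes the
between-subject SD of a planted link's post/pre ratio ≈ 0.66 × 0.06 ≈ 0.04
at κ = 2, so the default group × session multipliers (control ×0.95,
binge-drinking ×1.15) separate the groups by roughly three between-subject
SDs — the effect-size regime (pooled d ≈ 1.5–3) of the reference cohort's
printed link summaries.

Output is either instantaneous phases (`mode="phases"`, the default for
simulation studies) or `cos(φ)` plus white Gaussian noise
(`mode="signal"`), which exercises the analytic-signal phase extraction.
In signal mode a smaller phase diffusion is physically sensible (phase
wander is then limited by the band's width); the statistical chain only
relies on PLV being monotone in κ, not on exact calibration.

### What the generator does and does not emulate

Emulated: two groups × two sessions, group/sex marginals of a 39-subject
cohort (22 controls, 12 F; 17 binge drinkers, 8 F), ≥ 15 trials of 4 s,
narrowband phase coupling with known population PLV, a control-group
maturation trend (ratio ≤ 1) versus a binge-drinking increase (ratio > 1),
and a complete DTI tract-metric table with an optional planted
group × session shift.

Not emulated: sensor-space mixing and volume conduction, beamformer source
reconstruction, artifacts and their rejection, 1/f background spectra,
spatially correlated noise, amplitude dynamics, and any real anatomical
node placement (coordinates are a synthetic 1-cm grid around typical MNI
seeds of the six ROIs and feed reporting only).  Passing tests therefore
demonstrate correctness and calibration of the *statistical chain* on an
exchangeable, phase-coupled null/effect model — not robustness to the
physiological confounds of real MEG.

## Connectivity estimation

Filtering uses a windowed-sinc (Hamming) FIR band-pass applied
forward–backward (zero net phase).  The tap count scales as
1500 × fs/1000 so the transition width in Hz (~3.3/order × fs ≈ 2.2 Hz)
is rate-invariant.  The delta band (1.9 Hz wide) is narrower than that
transition, so its passband has droop at these settings; bands wider than
the transition are flat to within 5%.  Filtering is applied to the
continuous record *before* segmentation so trial edges are clean.

Phases come from the analytic signal per trial; 10% of samples per trial
end are discarded before the phasor average (the analytic-signal phase is
unreliable there).  Phase-kind data skip the trim — there is no edge
artifact to remove.  Ratios floor the pre-session PLV at 1e-6 with a
warning; an exactly zero PLV is measure-zero but possible in synthetic
edge cases, and an error would be disproportionate.

## Statistical chain

*Link test.*  For each node pair in the ROI-pair universe, the observed
statistic is the extra-sum-of-squares F for the group term of
`ratio ~ 1 + sex + group`.  The permutation null is Freedman–Lane:
residuals of the sex-only fit are permuted as whole subjects, the reduced
fit is added back, and F is recomputed; p = (1 + #{F* ≥ F}) / (B + 1).
The add-one convention guarantees valid, non-zero p with support
{1/(B+1), …, 1}; with B = 199 the finest attainable level below 0.05 is
9/200 = 0.045, which is what the type-I calibration study checks against.
Links with exactly constant ratios across subjects are flagged (warning)
and never significant.  The F computation is vectorised over links and
permutations via QR projections; statsmodels OLS is the cross-check oracle
in the tests.

*Motif extraction.*  Connected components of the significant-link graph
are kept iff each ROI of the pair contributes ≥ 25% of its nodes and the
component's significant links number ≥ 10% of the link universe.  The
density denominator is the full universe by default ("the links among
them" read as the analysed pair universe); `denominator="component"`
switches to component-internal pair counts.  The node criterion is applied
to *each* ROI of the pair — the stricter reading of an ambiguous rule.
Motif mass is the sum of member-link F values.

*Motif-level correction.*  One set of B permutations serves both levels:
within permutation b a link counts as significant iff its permuted F would
itself attain p < α against the same permutation distribution (equivalent
to exceeding the per-link (1−α) permutation quantile under the add-one
rule), the extraction procedure is replayed, and the maximum motif mass
(0 if none) forms the family-wise null.  A literally nested permutation
test (B² link tests) is computationally prohibitive; the synchronized
scheme is the standard cluster-correction practice and its family-wise
error is verified by simulation in the acceptance suite.

*Summaries.*  Motif degree is the per-subject mean ratio over motif links.
The degree ANCOVA (`degree ~ group + sex`, F on group) is parametric;
p is Bonferroni-corrected ×5 for the five frequency bands an analysis of
this design inspects.  Cohen's d uses the pooled SD
√(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)); the reference cohort's printed Δ
values are not reproducible from their own printed means/SDs under any
common d variant, so they are not used as calibration targets.  One-sample
t-tests against 1 accept either raw values or a (mean, SD, n) summary —
the latter is how the printed reference rows are validated.  Leave-one-out
logistic regression is effectively unpenalised (C = 1e12); at predicted
probability exactly 0.5 the subject is classified as control, and a
constant predictor degrades gracefully to the intercept (majority-class)
rule, giving 22/39 ≈ 0.564 at the default cohort size.

## Structural arm

With a complete two-session crossing, the repeated-measures ANCOVA
decomposes exactly: interaction = F for group on the difference score
(post − pre) adjusted for sex; session main effect = F for the intercept
of the difference score with centred covariates; group main effect = F for
group on the subject mean.  The interaction F equals the subject-dummy
mixed two-way F on balanced data (tested to 1e-8).  Subject-mean responses
are centred before projection to avoid cancellation when a metric's
baseline (e.g. MD ≈ 7.5e-4 mm²/s) dwarfs its variance.  Tests are reported
uncorrected per tract × metric, with Benjamini–Hochberg available as an
option; the reference analysis states no multiplicity handling for this
arm, and inventing one silently would misrepresent it.

## Problem sizes and numerical choices

Simulation studies run on the desk-scale geometry — 24 nodes (4 per ROI),
250 Hz, 20 trials of 4 s, 199 permutations — chosen so the full acceptance
battery (hundreds of replicates) completes in minutes; the 156-node / 1 kHz
/ 5000-permutation geometry is a configuration switch
(`RunConfig.paper_scale()`), not a code path.  The generator-PLV
calibration study runs at 1 kHz so the independence floor (≈ 0.016) sits
well below its 0.03 tolerance.  Per-ROI node counts of the full 156-node
layout are not published; 26 per ROI is a declared default, overridable
per ROI.  The pipeline expands its global seed into per-stage substreams
(SeedSequence spawning), making reports byte-identical across re-runs of
the same configuration and seed.

## Known limitations

- The coupling plan cannot represent cyclic pairwise constraints (by
  design; see above).
- Calibration of empirical PLV to R(κ) holds for phase-mode output; the
  signal path (cos + noise + filtering + Hilbert) attenuates PLV towards
  the floor and is validated qualitatively, not in closed form.
- The degree-level ANCOVA is parametric while the link/motif levels are
  permutation-based; with n = 39 and an approximately continuous degree
  this is the conventional compromise.
- Alpha-band group effects are computed but no planted alpha effect is
  shipped in the defaults, mirroring the reference analysis's null alpha
  ratio findings.
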