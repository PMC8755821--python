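# Methods

`pigeonvis` re-implements, as a reusable and fully tested pipeline, the
single-unit and population-level analysis chain used to compare visual
responses across three stations of the pigeon visual forebrain — the Wulst
(thalamofugal pathway), the entopallium (ENTO) and the mesopallium
ventrolaterale (MVL, both tectofugal) — during a response-inhibition task
with five stimulus groupings (human faces, scrambled human faces, pigeon
faces, scrambled pigeon faces, sine gratings).  Because no recordings are
deposited publicly, every stage runs against a synthetic session generator
whose structure matches the task, so the statistical machinery can be
exercised, calibrated and regression-tested without animal data.

## Session model

A session is 160 completed trials: 5 groupings × 4 exemplars × 8
presentations, in a seeded random order.  Each trial has a 6 s inter-trial
interval (ITI), a pause period drawn uniformly from [2, 4] s and a stimulus
period drawn uniformly from [1.5, 3] s.  Firing rates are reported for a
500 ms baseline window inside the ITI, the full pause period, and a 500 ms
post-onset analysis window (`analysis_window_s`, configurable because the
rate window used for the selectivity and decoding analyses is a free
choice; 500 ms is the responsiveness-analysis window and the default).

Spikes are homogeneous Poisson within each period: counts are drawn with
mean `rate × window` and divided by the window length.  A unit is described
by a baseline rate (spikes/s, > 0), a stimulus gain (excitatory > 1,
inhibitory < 1, non-responsive = 1) and a pause gain.  This is the simplest
generative model consistent with a rate-window analysis; it deliberately
omits adaptation, latency structure, bursting, trial-to-trial gain drift
and any behavioural covariates, so passing tests demonstrate correctness
and calibration of the *analysis*, not realism of pigeon physiology.
Correction trials (pecks during the stimulus) are not simulated, since only
completed trials enter the analysis.

### Planting selectivity

A tuned unit carries a preferred grouping and a target selectivity index
`s`.  With `r_other = baseline × stim_gain` the preferred-grouping rate is
obtained by inverting the SI definition:

    excitatory:  r_pref = r_other (1 + s) / (1 - s)
    inhibitory:  r_pref = r_other (1 - s) / (1 + s)

so the planted population contrast equals `s` in expectation (`s = 1/3`
is a 2:1 rate ratio; `s = 0.5` a 3:1 ratio).  `s ≥ 1` is unreachable with
positive rates and rejected.  Parameter recovery is verified end-to-end:
across 400 seeded single-unit sessions per value, the empirical SI obtained
through the full ANOVA → Tukey → SI path is unbiased within 3 standard
errors at s ∈ {0.2, 0.33, 0.5} (an independent Monte-Carlo oracle puts the
delta-method bias of the SI ratio at ~2 × 10⁻⁴ for these rates, far below
the resolution of the test).

## Single-unit statistics

*Responsiveness.* Two-tailed paired t-test of the stimulus-window rate
against the baseline-window rate across the 160 trials, p < 0.05; the sign
of the mean difference types the unit excitatory or inhibitory.  The same
contract against the pause-period rate yields pause activity.  A unit with
identically zero differences is non-responsive with p = 1.  Type-I error is
verified at α ± 2·SE(α) on 500 simulated null units.  Period time courses
z-score each unit's mean period rate against its own baseline mean and SD
(units with zero baseline variance are excluded with a warning) and average
within response classes.

*Selectivity.* One-way fixed-effects ANOVA of stimulus-window rates over
the five groupings (p < 0.05), then Tukey HSD pairwise comparisons.  The
preferred grouping is the one whose mean rate deviates most from the
unit's baseline mean — upward for excitatory units, downward for inhibitory
ones (preference must be sign-aware because the SI is defined for either
response polarity) — and must take part in at least one significant Tukey
pair, otherwise preference is ambiguous and no SI is assigned.  Tukey
decisions use the Tukey–Kramer q statistic against a studentized-range
critical value cached per (α, k, df); this is the same accept/reject rule
as thresholding per-pair p-values and is verified against
`scipy.stats.tukey_hsd` in the tests.

The selectivity index uses raw window rates (not baseline-subtracted — the
2:1 ↔ 0.33 anchor only holds for raw-rate ratios):

    SI = (P - O) / (P + O)   excitatory,   (O - P) / (O + P)   inhibitory

with P the preferred-grouping mean and O the mean of the other groupings'
means, clipped at 0 if the preferred direction is violated.  SI is
dimensionless, lies in [0, 1] and is invariant to common rescaling of all
rates (property-tested).

*Chance simulation.* To estimate how many units would appear selective
with no tuning, each simulated unit draws per-trial rates i.i.d. uniform
between its own minimum and maximum (per-unit ranges supported; 32 trials
per grouping, matching 8 repetitions × 4 exemplars) and the same ANOVA is
applied.  Per-trial draws — not per-grouping means — are required for the
ANOVA to have within-group variance.  The significant fraction converges
to α (binomial-CI tested at n = 77 and n = 10 000).

*Scrambled vs original.* Two-tailed paired t-test across units of each
unit's mean rate to scrambled images against its mean rate to the intact
face images.

## Population decoding

Units are recorded in separate sessions, so true simultaneous population
vectors do not exist.  Pseudo-population vectors are built by independently
shuffling each unit's trial order within a stimulus grouping (trial counts
truncated to the minimum per cell so every unit contributes equally) and
concatenating the i-th shuffled trial of every unit.  The classifier is a
linear discriminant (LDA); when the training set is small relative to the
number of units the within-class scatter can be singular, and the solver
switches automatically to least-squares LDA with Ledoit–Wolf shrinkage
(logged).  Performance is read out per grouping as the one-vs-rest area
under the ROC curve of the classifier's decision scores on a stratified
75/25 held-out split (the split ratio is configurable; no particular split
is canonical for this analysis).

The whole construction is repeated 1200 times (fresh shuffles) for the
labelled distribution, and 1200 more times with grouping labels permuted
across rows before training for the "no information" null.  The per-
grouping p-value is the add-one permutation estimator with the labelled
median as observed statistic:

    p = (1 + #{null ≥ median(labelled)}) / (1 + n_resamples),
    SE(p) = sqrt(p (1 - p) / n_resamples)

so p is never exactly 0.  A consequence of using the labelled *median* as
the observed statistic: when the labels carry no information the labelled
and null distributions coincide, and the median of 1200 labelled draws
concentrates at the null's median — p then concentrates near 0.5 rather
than being uniform.  The estimator is therefore conservative, and the
calibration tests check the operationally meaningful properties: under a
no-information population the rejection rate at α = 0.05 stays at or below
α, and decoding performance sits at chance (AUC ≈ 0.5).  Power is checked
at full scale: 77 units planted at SI 0.5 give p < 0.01 for all five
groupings at 1200 resamples, the qualitative analogue of a population
whose labelled performance exceeds > 99 % of the null samples.

Generalization to held-out exemplars builds exemplar-resolved
pseudo-vectors (shuffling within image rather than within grouping),
trains on vectors from all but one exemplar per grouping and tests on the
held-out exemplar's vectors, averaging the per-grouping AUC over exemplar
folds and resamples.  Grouping-tuned populations generalize
(held-out ≈ within-exemplar performance); untuned ones stay at chance.

Decoding is multiclass (all five groupings jointly) with a one-vs-rest ROC
readout per grouping; per-grouping binary decoding would be a trivial
variant but the joint problem is the stricter and more informative one.

## Stimulus images and spectra

Gratings are `0.5 + 0.5 sin(2π f x / width)` at f cycles/image (f ≥ 1 and
below Nyquist).  Because the face photographs used in the original stimuli
are copyrighted, the naturalistic surrogate is a random-phase field with
amplitude spectrum ∝ 1/f^(exponent/2) (default exponent 2, the canonical
natural-scene statistic), rescaled to [0, 1]: it reproduces the two
properties the spectral analysis depends on — low-frequency dominance and
strong low-frequency correlation between exemplars — without reproducing
any photograph.

Scrambling divides the image into a 15-column × 32-row grid (480 tiles),
permutes tile positions uniformly and re-orients each tile independently.
Square tiles draw from the rotations {0°, 90°, 180°, 270°} (plus mirror
flips by default); non-square tiles are restricted to the shape-preserving
subset {0°, 180°} plus horizontal/vertical flips.  Whether the original
procedure included flips is not documented, so flips sit behind an
`allow_flips` flag.  Every operation is a pixel permutation, so the
intensity multiset — and hence mean luminance — is conserved exactly; this
is the testable core of the control's luminance-matching argument.

Spectra: the cross-section spectrum is the mean 1-D FFT amplitude over all
rows (or columns) — robust to the arbitrary choice of a single line; a
central-line mode exists.  The energy-weighted spectral average is the
spectral centroid Σ f·|A(f)|² / Σ |A(f)|² over non-DC frequencies
(amplitude weighting available as an option), in cycles/image.  No
windowing is applied by default; a Hann option exists.  Spectral
correlations normalise each spectrum to unit energy and take pairwise
Pearson correlations, packing the horizontal direction in the upper
triangle and the vertical in the lower triangle of one matrix.  The
sign-test property — scrambling raises the centroid on both axes for 20/20
seeded 1/f surrogates — is asserted in the acceptance suite.  The
vertical spectrum of a pure horizontal grating is identically zero and its
centroid undefined; summaries report NaN there.

## Contingency statistics

Between-region proportion comparisons use the Pearson chi-square statistic
Σ (O − E)²/E with margin-derived expected counts, (r−1)(c−1) degrees of
freedom and *no* Yates continuity correction: recomputation from the
published count tables shows all eight printed statistics (3.18 with 2 df;
21.1, 1.64, 7.05, 2.55, 7.77, 8.14, 14.99 with 1 df) match the uncorrected
statistic to the printed precision (the printed values are truncated, so
tests compare within one unit in the last printed digit).  A brute-force
expected-count implementation serves as the oracle in the tests.

## Problem sizes and numerical choices

The default test and acceptance runs use: 160-trial sessions; 77-unit
populations for the full-scale decoding-power check (1200 + 1200
resamples) and 10–40 units for calibration checks; 50–60 replicates of the
77-unit chance simulation; 400 replicates per SI value for parameter
recovery; 20 seeded 480×480 surrogates for the scrambling sign test.
Permutation p-values are floored at 1/(n+1) by construction; ANOVA on
identical rates returns F = 0 without calling the F distribution;
degenerate uniform ranges (min = max) short-circuit the chance simulation
with a warning.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; every stage is reproducible bit-for-bit from
(inputs, config, seed).

## Known limitations

- The Poisson generator has no trial-to-trial correlation, so the
  pseudo-population construction (whose purpose is to destroy such
  correlation) is exercised structurally but its effect cannot be measured
  here.
- Region-specific published quantities (counts of responsive units per
  region, SI means such as 0.62 ± 0.22, the region-wise decoding
  histograms) depend on the unavailable recordings and are represented
  only by structurally matching synthetic analogues.
- The surrogate images share natural images' second-order statistics only;
  nothing face-like (configural structure, phase alignment) is modelled.
- The SI of a unit whose ANOVA is significant but whose Tukey screen finds
  no significant pair is undefined (reported as ambiguous), which can
  slightly undercount selective units at very low planted SI.
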