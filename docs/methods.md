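# Methods

## Scope and data model

`condrel` analyses a two-timepoint (T0, T1), 2-day differential fear
conditioning protocol: habituation (7 CS+ / 7 CS−) and acquisition training
(14 CS+ / 14 CS−, every CS+ reinforced by an electrotactile US) on day 1;
extinction training (14 + 14), reinstatement (3 unsignalled USs) and a
reinstatement test (7 + 7) on day 2. All trial-based analyses operate on a
tidy long table with one row per participant × timepoint × phase × stimulus
× trial; map-based analyses operate on 3D statistic grids (`StatMap`) and
boolean masks (`BinaryMask`), read and written as NIfTI through nibabel.

## SCR scoring and exclusions

Amplitudes are scored trough-to-peak on the 10 Hz grid: the trough is the
earliest minimum 0.9–3.5 s after CS onset (0.9–2.5 s after US onset), the
peak is the maximum within 5 s of the trough, truncated at the next US onset
when one occurs earlier. Window endpoints are inclusive on the sample grid
(endpoint handling is not dictated by the method description, so the
inclusive convention is fixed here), and ties between equal minima resolve to
the earliest sample. Amplitudes below 0.01 µS are floored to exact zero
responses, so outputs are never in the open interval (0, 0.01).

Participants are flagged as day-1 non-responders when more than two-thirds of
the 14 acquisition USs (i.e. more than 9) evoke zero responses, and as day-2
non-responders when none of the 3 reinstatement USs does. Flags are
annotations; dropping flagged participants (`drop_nonresponders`) is a
separate pipeline switch, on by default in the CLI.

The first CS+ and CS− of acquisition are dropped (no learning can have
occurred before the first US), leaving 26 CS trials / 13 differential
responses; the first extinction CS+ and CS− are relabelled `fear_recall` — a
24-h delayed test of fear memory — and removed from the extinction pool. All
14 US trials are retained. Exclusions key on the original trial index, so the
operation is idempotent.

## Transformation ladder

The ladder is RAW → LOG → LOG_RC. The log transform is ln(1 + x): the method
description says only "natural logarithm", but exact-zero responses must stay
representable, and ln(1+x) is the standard SCR convention with ln(1+0) = 0.
Range correction divides each trial by the participant's day-specific maximum
over all CS and US trials; under LOG_RC the maximum is taken over the
log-transformed values (transform, then correct), and participant-days with a
zero maximum become missing since the ratio is undefined. Trial-level CS
discrimination pairs the k-th CS+ with the k-th CS− by within-phase ordinal
position — the only order-preserving pairing; summary-level discrimination is
the difference of summaries. Ordinal ranking assigns average ranks across
participants to the already-operationalized phase measures (one number per
participant), so ranked results are invariant to any monotone transform of
the raw values.

## Reliability estimators

**Internal consistency** splits the retained, chronologically ordered trials
of one session into odd and even positions (position 1 = odd; numbering
restarts after exclusions, chosen for determinism), averages each half per
participant and correlates the halves across participants. The Spearman–Brown
prophecy correction is deliberately not applied; the CI is the Fisher-z
interval (undefined, hence NaN, below n = 4).

**ICCs** are the two-way single-measure forms computed directly from the
ANOVA mean squares (subjects MSR, sessions MSC, residual MSE; k = 2
sessions, listwise-complete pairs): consistency ICC(3,1) tolerates a
systematic session shift, absolute agreement ICC(2,1) does not. 95% CIs use
the standard F-based formulas (exact for the consistency form; the
Satterthwaite-style approximation for absolute agreement). Negative estimates
are reported as computed, never truncated. ICCs are computed on non-ranked
data only: ranking both sessions and then computing a consistency ICC would
nearly duplicate the unranked consistency coefficient, which already ignores
monotone session shifts only up to an additive constant — the two are related
but not identical, and the standard ICC(3,1) definition is what is
implemented. Estimates are cross-checked against pingouin in the tests to
1e-6. The trial-accumulation curve recomputes the ICC of the mean over the
first m retained trials for m = 1..M.

**Similarity** correlates each participant's trial (or voxel) vector at T0
with their own T1 vector (within, one Fisher z per participant) and with all
n−1 other participants' T1 vectors (between, averaged in z-space).
Participants with an all-zero or constant vector at either timepoint, or a
within-correlation of |r| = 1, are excluded with a reason code: such vectors
cannot be correlated, and r = 1 maps to an infinite z. The comparison is a
paired t-test by default, switching to a Welch two-sample test when Levene's
test rejects equal variances at α = 0.05 (the named fallback needs a trigger;
Levene is the conventional one). This switch matters because between-subject
similarities are averages of n−1 coefficients and have far smaller variance
than the unaveraged within-subject similarities. Cohen's d is the mean
difference over the SD of differences. Type-I calibration under
exchangeability is verified by simulation in the tests (rejection rate
0.05 ± 0.02 over 1000 cohorts).

## Maps

Thresholding of t-maps is one-sided positive at uncorrected p (activation
contrasts; the sidedness used upstream is not always documented, so it is
configurable via `side`). Jaccard and Dice are computed on the binarized
maps; an empty-∩-empty pair is defined as 0 overlap (with `both_empty`
flagged) rather than NaN, since near-zero extinction overlaps make the case
reachable. For any single pair D = 2J/(1+J) holds exactly; averages of
per-participant coefficients need not satisfy the identity, which is why
individual-level overlap is summarized as the arithmetic mean of per-pair
coefficients while group-level overlap is computed once on the two group
maps. Box ROIs are axis-aligned boxes in mm; a voxel belongs when its centre
lies in the half-open interval [c − s/2, c + s/2) per axis, so a 20×16×16 mm
box on a 2 mm grid is exactly 640 voxels. Synthetic maps use voxel-index
geometry; affines from real NIfTI files are passed through untouched.
Voxel-wise ICC applies the same ANOVA estimator per voxel across participants
and averages over the region, skipping and counting degenerate voxels.

## Group level and cross-phase prediction

Group reliability regresses trial-wise group means at T1 on T0
(available-case per trial, since upstream missing-trial handling at the group
level is unstated); CS analyses use the 13 retained trials (df2 = 11), US
analyses all 14 (df2 = 12), and phases with fewer than 3 trials are rejected
— two points cannot be meaningfully correlated. R² equals the squared Pearson
correlation of the trial-mean vectors and F = (R²/(1−R²))·df2 by identity.

Cross-phase regressions use OLS with the HC3 sandwich covariance
(statsmodels), weighting squared residuals by (1−h)⁻²; the test suite checks
the result against an explicit hat-matrix computation to 1e-10. The
standardized beta equals the Pearson correlation; |beta| < 0.4 / ≥ 0.4 /
≥ 0.7 are labelled weak / moderate / strong. The default grid crosses the 11
predictor→criterion operationalization pairs with stimulus, transform and
ranking; a specification whose predictor does not precede its criterion in
paradigm order is rejected at validation. The minimum of 3 complete pairs
(df2 = 1) is the algebraic floor for the HC3 fit. No multiple-testing
correction is applied across the grid by default (a Benjamini–Hochberg switch
would be trivial to add at the consumer side since per-cell p-values are
emitted); pooled contrasts compare Fisher-z betas, paired when the two groups
match cell-by-cell on every other specification and Welch otherwise.
In map-based cross-phase prediction, per-participant pattern correlations of
|r| = 1 are clipped at z = atanh(1 − 1e-12) rather than excluded, because the
exclusion rule is specific to the similarity analysis.

## Benchmark labels

Internal consistency: unacceptable < 0.5, poor [0.5, 0.6), questionable
[0.6, 0.7), acceptable [0.7, 0.8), good [0.8, 0.9), excellent ≥ 0.9. ICC:
poor < 0.5, moderate [0.5, 0.75), good [0.75, 0.9), excellent ≥ 0.9. The
customary verbal rules are ambiguous exactly at the cut points, so intervals
are left-closed; values above 1 are a domain error.

## Synthetic cohort generator

Per stimulus class, a trial amplitude is
max(0, µ + trend + b_subject + b_subject×session + ε), floored to exactly 0
with probability `zero_p`; b_subject ~ N(0, σ_s²) is stable across
timepoints, b_subject×session ~ N(0, σ_ss²) is redrawn per timepoint, and
ε ~ N(0, σ_t²) per trial. Under this decomposition the ICC of an m-trial
average is σ_s²/(σ_s² + σ_ss² + σ_t²/m) (`true_icc`), which is what the
recovery tests target. The CS+ trend is a linear ramp saturating at
`learning_gain` over the first 5 acquisition trials and an exponential decay
from that height during extinction — shapes chosen only to create
phase-dependent means; the US adds `us_gain`. Ratings are a discretized
latent Gaussian clipped to the 0–25 scale with per-(stimulus, occasion)
population means. A configurable fraction of participants is simulated as US
non-responders (all US amplitudes zero). One RNG stream per participant,
keyed by (seed, participant index), makes cohorts bit-reproducible and lets a
cohort grow without perturbing existing participants.

Default component values (µ = 0.3 µS, σ_s = 0.25, σ_ss = 0.15, σ_t = 0.25,
zero_p = 0.1, CS+ gain 0.4, US gain 0.8, US zero_p 0.05) are free parameters
chosen to give realistic SCR magnitudes, a zero-response rate around 20–25%,
and mid-range reliabilities; they are a property of the generator, not claims
about any empirical dataset. What the generator deliberately omits: raw
waveform physiology (only the scorer's tests build canonical bumps),
autocorrelated habituation beyond the deterministic trends, drift mechanisms
over the 6-month interval beyond σ_ss, and spatial smoothness in the
synthetic maps (voxels are i.i.d. bivariate Gaussian with a controlled
cross-timepoint correlation ρ). Passing tests therefore demonstrate
estimator correctness and calibration under the assumed variance structure,
not robustness to every artefact of real psychophysiology.

## Problem sizes and numerical choices

Calibration tests use the sizes at which the checks are informative yet
quick: ICC parameter recovery uses 500 replicate cohorts of n = 100 with an
acquisition-only paradigm (the closed form does not depend on the other
phases); similarity type-I calibration uses 1000 cohorts of 16 participants ×
13 trials; the trial-accumulation check averages 5 cohorts of n = 500
because a single cohort's sampling error (~0.05 at m = 1) is the size of the
tolerance itself. Degenerate inputs raise ValueError with a descriptive
message (all-zero variance, fewer than 3 subjects, zero-variance split
halves, leverage-one designs); multiverse cells trap these per cell and
record the reason instead of aborting the sweep. Paired comparisons with
byte-identical groups return a null result (t = 0, p = 1) while constant
non-zero differences raise, with a relative tolerance of 1e-10 on the SD of
differences to absorb floating-point cancellation.

## Known limitations

- The generator's zero-inflation interacts with the truncation at 0, so the
  observed zero rate is zero_p plus the truncated Gaussian mass, and extreme
  zero rates compress the effective reliability below `true_icc`'s
  prediction (the recovery tests avoid this regime with µ ≫ σ).
- Welch's fallback treats the within- and between-subject similarity samples
  as independent, although both derive from the same cohort; simulation shows
  the size of the test is nonetheless close to nominal under exchangeability.
- Map analyses assume voxel-aligned grids; no registration, smoothing, or
  atlas lookup is provided.
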