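# Methods

`gcgut` implements an end-to-end analysis of how maternal glucocorticoid (GC)
exposure during three developmental windows — early gestation, late
gestation, and lactation — relates to offspring gut bacterial diversity,
composition, and (optionally) predicted function, together with a synthetic
cohort generator that makes every stage testable against known ground truth.
This note records the models, the defaults and why they were chosen, and
what the synthetic tests do and do not establish about real data.

## Developmental-window covariates

Maternal fecal GC metabolite concentrations (ng/g) are averaged per window:
early gestation is days 1–82 of a 164-day gestation (a day-82 sample counts
as early), late gestation is day 83 to birth, and the postnatal window is
the first six months of lactation, implemented as days 0–182 inclusive
(6 × ~30.4 days, boundary inclusive). Offspring GC samples are averaged
separately per season (rich = March–October, lean = November–February).
Window means are unweighted arithmetic means; no weighting by sample-date
spacing is attempted.

All concentration covariates are ln-transformed and then z-scaled (sample
SD, n−1 denominator), and the scaling is computed over the analysis set that
is actually fitted, so each model's covariates have mean 0 and SD 1 by
construction. Age enters diversity models as a three-level class
(infant/juvenile/adult, infant reference) and enters the differential
abundance and F/B models as a continuous z-scored variable — the latter is
required for the interaction (moderation) analysis. Sex, season, and group
are treatment-coded with female, lean, and the first-sorted group as
references. A variance-inflation screen (VIF\_k = 1/(1−R²\_k)) flags
predictors above 5 for exclusion.

## Profiles and taxonomy

Taxonomy best hits are accepted when (%identity + %coverage)/2 ≥ 93;
rejected features are unclassified (`UN`) at all ranks. Rank aggregation
sums counts over shared labels and pools unclassified features under
`UN:<nearest classified parent>`, one pooled row per parent, conserving
per-sample totals exactly. Relative abundances are per-sample proportions;
seasonal biological replicates are merged to one record per
individual-season by averaging relative abundances (library depth varies
across replicates, so averaging proportions is the depth-fair choice);
where a downstream fit needs counts, the per-feature mean counts rounded to
the nearest integer are used instead, and this choice is deliberate and
documented rather than derivable. Depth summaries report the mean truncated
toward zero (integer division), SD with n−1, median, and range.

## Alpha diversity and mixed models

Five indices per sample: observed features; ACE with the standard Chao–Lee
rare/abundant threshold of 10 (when every feature exceeds 10 the rare-class
correction is vacuous and ACE equals observed richness; when the rare class
consists solely of singletons, where the ACE coverage estimate is undefined,
bias-corrected Chao1 is substituted); Shannon entropy in nats; inverse
Simpson; and Faith's PD (total branch length of the minimal subtree spanning
the root and observed leaves), all via scikit-bio.

Index-on-covariate models are Gaussian linear mixed models with a subject
random intercept, fitted by maximum likelihood (not REML) so that full/null
likelihood-ratio comparisons are valid; random slopes are omitted by
default. The LBFGS optimizer's Hessian turns singular when the
random-intercept variance sits at the zero boundary, so fitting falls back
to derivative-free optimizers (Powell, then Nelder–Mead). Wald intervals are
±1.96 SE; conditional R² is Nakagawa-style, (fixed + random variance) /
(fixed + random + residual). Model reduction removes all predictor-by-age
interactions with p ≥ 0.05 and keeps main terms.

## Bias-corrected differential abundance

Counts are modelled on the log scale as

    ln(count_ij + 1) = d_i + alpha_j + x_i' beta_j + eps_ij,

where `d_i` is the sample's log sampling fraction — the nuisance that makes
observed counts compositional. `d` and the coefficient field are confounded
(`d → d + Xc`, `beta_j → beta_j − c` leaves the likelihood unchanged), which
is exactly the bias the engine corrects:

1. **Alternating least squares.** Given `d`, every feature is fitted by OLS
   on the offset-corrected logs; given the coefficients, `d_i` is updated as
   the mean over features of the residual. Iterated to convergence
   (max |Δd| < 1e-6, cap 100 iterations; in practice 2–3).
2. **Mode centering.** Each non-intercept predictor's cross-feature
   coefficient vector is centered on a 20%-trimmed mean — the premise being
   that most features are null, so the mode of the coefficient field
   identifies `c`. This replaces the Gaussian-mixture E-M of the original
   bias-correction framework with a simpler robust location estimate.
3. **Small-count handling.** The log(count+1) response floors at zero
   counts, which attenuates large coefficients of low-abundance features.
   Two corrections are applied by default (`curvature_correction=True`):
   the expected offset E[ln(N+1)] − ln λ under a Poisson model at the
   fitted cell means is subtracted from the response (three fixed-point
   iterations), and a final per-feature refit excludes zero-count cells
   whose fitted mean is below one (such cells are nearly uninformative).
   With the correction disabled, and the sampling fractions fixed at known
   values, the engine reduces exactly to per-feature OLS — the brute-force
   oracle used in the tests.

Wald tests use heteroscedasticity-robust (HC3 sandwich) standard errors with
normal tails: the log-scale noise mixes a homoscedastic overdispersion
component with count noise whose variance grows as abundance shrinks, and
classical OLS errors understate uncertainty precisely at extreme design
points. Benjamini–Hochberg correction is applied within each predictor
across features, separately per rank-level and per-season analysis; zeros
are handled by the pseudo-count of 1 (a config option); structural-zero
(presence/absence) screening is deliberately not implemented.

On synthetic cohorts (200 samples × 150 features, 20% non-null, dispersion
0.5, sampling-fraction SD 0.5) the engine recovers non-null coefficients
with mean absolute error ≈ 0.035 log-fold, ~93% empirical coverage of
nominal 95% intervals, and a pre-BH false-positive rate of ≈ 4.6% —
numbers recomputed by `scripts/acceptance.py`, not quoted from anywhere.

**Known limitation.** Features whose mean count is below ~10 remain poorly
identified: most of their cells sit at the zero floor, point estimates of
large effects stay attenuated, and intervals undercover. This is a property
of the log-linear model class on rare taxa, not of a particular
implementation; practitioners usually filter such features. The package does
not filter silently.

## Moderation by age

For each feature with a significant predictor-by-age interaction (BH q <
0.05), the conditional effect of a one-SD predictor increase at age anchor
`z` is the simple slope `e_z = beta_main + z·beta_interaction`, evaluated at
z = −1, 0, +1 of the z-scaled age (real-age annotations such as 2.3/4.7/7.1
years are dataset-specific descriptions, not inputs). Classification:

- **reverse** — sign(e₋₁) ≠ sign(e₊₁);
- **amplify** — same sign and |e₊₁| > |e₋₁| (suffix `_pos`/`_neg` by the
  sign of e₀);
- **attenuate** — same sign and |e₊₁| < |e₋₁|.

An anchor effect within ε = 1e-9 of zero borrows the other anchor's sign so
numerical zeros never fabricate a reversal; exact ties and all-zero triples
return `none`. Classification uses point estimates only — no anchor-wise
significance testing — because the class of every significant feature is
reported, not re-tested. Per-predictor summaries report counts and
one-decimal percentages both among significant features and among all
analyzed features, plus the ordinal relevance scale on the percent of
features affected: [0,5) not, [5,10) slightly, [10,20) mildly, [20,40)
considerably, [40,100] highly relevant (half-open bins; the boundary 10.0
is "mildly"). Seasonal concordance compares the sign of the mean-age effect
for features significant in both seasons. The same machinery applies
unchanged to predicted-function (KO pathway) tables; pathway grouping is an
input, not computed here.

## Firmicutes/Bacteroidota ratio

Per individual-season, the ratio of the two phyla's relative abundances is
modelled on the natural-log scale by OLS with the standard predictor set
plus GC-by-age interactions. Records with a zero phylum are excluded with a
warning. Each deletable term (interactions always; main terms only when not
inside a retained interaction — marginality) gets a drop1 likelihood-ratio
test, 2Δloglik against the refit without the term, df = 1; a full-vs-null
comparison and a pseudo-R² (squared correlation of fitted and observed, the
formula being otherwise unspecified) are also reported. Reduction removes
non-significant interactions one at a time, largest p first.

## Synthetic cohort generator

The generator is first-class, tested code, and its defaults are the study
conditions, not tuning knobs:

- 30 mother–offspring dyads; cross-sectional offspring mix of 16 infants,
  7 juveniles, 7 adults, with continuous ages drawn around cluster means
  0.5, 4.5, and 8 years; three social groups; balanced sexes.
- 164-day gestation split at day 82; six-month lactation window; GC
  sampling per window (default 4 maternal samples per window, 4 offspring
  samples per season).
- Subject-level window concentrations are log-normal with SDs matching the
  one-SD anchors used throughout (59.3, 67.0, 52.7 ng/g for the three
  maternal windows, 130.1 ng/g for offspring GC); the corresponding means
  (180, 210, 160, 450 ng/g) are the package's own choice of a plausible
  fecal GC metabolite scale, since only the SDs anchor the analysis (all
  covariates are z-scaled before modelling). Per-sample noise is log-normal
  with ~30% CV around the subject level.
- Counts are Poisson-lognormal: `count ~ Poisson(exp(log s_i + alpha_j +
  x_i' beta_j + eps))` with `eps ~ N(0, dispersion²)` (default 0.5),
  `log s_i ~ N(0, 0.5²)`, and baselines scaled to an expected library size
  of 60,000 reads. The Poisson-lognormal law (rather than negative
  binomial) keeps the exact linear-model-on-logs structure the DA engine
  assumes, which is the point of the recovery tests.
- Feature lineages follow a dominant Firmicutes/Bacteroidota community
  (~59%/18% with five minor phyla), with ~10% of features unclassified at
  genus rank to exercise the `UN` pooling path.
- Designed effects attach to one focal predictor (early-gestation GC by
  default): six features per class for amplify/attenuate in each sign
  (main ±0.8, interaction ∓0.6) and six reversals (main ±0.5, interaction
  ∓1.5, mirrored halves so the cross-feature coefficient field stays
  balanced for the trimmed-mean centering). The remaining 120 of 150
  features are null. Evaluating the true coefficients at the age anchors
  reproduces the designed class labels exactly, by construction and by
  test.

What the generator does **not** emulate: read-level artifacts (quality,
chimeras, denoising), phylogenetic signal in the effects, compositional
closure beyond the sampling-fraction mechanism, diet/kinship/social
covariance structure, and longitudinal within-individual dynamics beyond
the season split. Passing recovery tests therefore demonstrates that the
estimators are correct under the model they assume — not that the model
captures everything in real amplicon data.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale problems chosen
to make the statistics stable: 50 seeded cohorts of 200 samples × 150
features for coefficient recovery and moderation-label recovery, and 200
replicates each for the two likelihood-ratio calibration checks
(Kolmogorov–Smirnov against uniform at α = 0.01). Every random quantity
flows from a single integer seed through `numpy.random.default_rng`;
identical configs produce bit-identical tables, trees, and report files.
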