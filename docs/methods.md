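# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions taken where the design was genuinely
open.

## Data model

The substrate is the beta value — the fraction of methylated signal at a CpG,
in [0,1] — over a fixed, ordered CpG reference (BED4, 0-based half-open, each
interval spanning the CG dinucleotide's forward-strand C). Reference order is
the single source of truth for column order everywhere: every matrix,
discovery-mean vector, embedding, and signature in a trained bundle shares
it, and mismatches are hard errors rather than silent reindexing. Missing
observations are explicit (NaN); linear and survival modeling uses M-values,
M = log2(β/(1−β)), with β clamped to [ε, 1−ε], ε = 10⁻⁶ by default, because
β ∈ {0,1} genuinely occurs in low-coverage nanopore data and M must stay
finite. The transform is strictly monotone and odd around β = 0.5.

## Quality control and harmonization

The QC cascade applies six exclusions in a fixed order — masked probes,
unreliable probes, externally listed failing samples, CpGs with a missing
fraction strictly above 0.05, non-hematopoietic samples, PCA outliers — and
reports per-stage counts. The order matters: the counts are order-dependent,
so reproducibility requires fixing it. Detection-p-value sample failures are
consumed as an external list because this package operates on beta matrices,
not raw array intensities.

The PCA outlier rule had to be pinned down: a sample is flagged when the
Euclidean norm of its per-component standardized scores on the top 2
principal components exceeds k = 4. Degenerate (zero-variance) components
contribute nothing. This is one reproducible instantiation of "outliers by
PCA"; both the component count and k are configurable.

Missing values are filled with the probe mean within the sample's batch
(falling back to the global probe mean when a batch has no observation, with
a log record); observed entries are never altered. Batch correction is
parametric empirical-Bayes location/scale adjustment with a batch-only
design, delegated to scanpy's ComBat implementation. Two local choices on
top of it: after correction each probe is recentred to its pre-correction
grand mean (so balanced designs preserve probe means exactly), then clamped
to [0,1], since correction happens on the beta scale. Correction on the beta
rather than M scale is the default because downstream stages expect betas;
the shrinkage behavior is scale-sensitive, and the residual batch-mean
difference after correcting a planted 0.1 shift at the default cohort size
is measured by the test suite rather than assumed.

A caveat worth knowing: empirical-Bayes shrinkage deliberately does not
chase per-probe sampling noise, so with homoscedastic probes and small
batches the residual batch-mean difference is the sampling noise itself.
Real methylomes are strongly heteroscedastic across probes, which keeps
shrinkage mild and removal nearly exact; the tests use heteroscedastic
fixtures for this reason.

## Embedding

The atlas is a neighbor-graph manifold embedding (UMAP) of the complete,
corrected beta matrix — 2 components for visualization, 5 for
classification. The reducer is consumed as a dependency at its published
defaults (15 neighbors, min_dist 0.1, Euclidean metric); this package owns
what actually matters for reproducibility and deployment: the seed (fit and
transform are deterministic given it, and serialized models are
byte-reproducible because per-process compiled-function state is stripped
from the pickle and rebuilt on load), the probe-order contract, and the
out-of-sample semantics. The native transform is the default; a weighted
k-nearest-neighbor interpolation of training coordinates in probe space is
available as a fallback for single-specimen inference. The 2D and 5D fits
are independent fits with the same seed.

A property of neighbor-graph transforms that users should expect: a specimen
lying *between* two well-separated training clusters is usually projected
onto whichever cluster is marginally nearer, not into the gap — the
transform's local-connectivity scaling makes membership nearly binary. See
"Ambiguous specimens" below.

## Classifiers

Both classifiers are LightGBM gradient-boosted trees on the 5 embedding
coordinates: one-vs-rest for subtypes, binary for death within the 60-month
horizon. Hyperparameters are tuned by stratified 5-fold cross-validation
over a small fixed grid (tree count 100/300, leaves 7/31, L1 and L2 penalty
0/1; learning rate 0.1) with inverse-frequency class weights; boosting is
forced single-threaded and deterministic so a fixed seed reproduces the
model bit-for-bit. The subtype vocabulary is configuration, not code: a
controlled list (by default 27 WHO-2022-style acute-leukemia subtype names
plus otherwise-normal control) against which labels are validated; synthetic
cohorts supply their own list. Subtype calls gate at max class probability
0.5 — below it the reported label is "Not confident" and, in the specimen
path, the prognostic models are not applied. The mortality label follows the
dead/alive rule: dead if the event occurred at or before 60 months, alive if
followed past 60 months; samples censored earlier have an undefined label
and are excluded from training (logged) but still scored at inference. The
high/low risk group cutoff on the predicted probability defaults to 0.5.

Per-class concordance is reported as the diagonal of the row-normalized
confusion matrix (per-class recall); kappa uses the standard
marginal-product chance correction.

## CpG survival signature

The signature is derived in four steps.

**EWAS.** One Cox proportional-hazards fit per CpG of overall survival on
(M-value + adjustment covariates), with risk group one-hot encoded when
present and administrative censoring at 60 months (events after the horizon
become censored at it). Ties are handled by the Efron approximation;
non-estimable or non-converging CpGs are flagged with p = 1 rather than
aborting a scan. The significance threshold is 10⁻⁵ by default. The source
convention "10e-5" is ambiguous between 10⁻⁵ and 10⁻⁴; the Manhattan-plot
reading 10⁻⁵ is the default and the literal reading is selectable.

**Stability selection.** Candidates passing the threshold enter repeated
L1-penalized Cox fits; CpGs with non-zero coefficients in at least 95% of
fits are kept. The resampling scheme is the decision that required care.
Refitting the *full* cohort while only reshuffling cross-validation folds —
with the penalty chosen by maximum mean held-out partial likelihood — turns
out to be nearly deterministic: every CpG in the full-data support at the
chosen penalty reaches frequency ~1.0, so the 95% rule cannot reject chance
associations (and the CV-maximum penalty itself over-selects, the familiar
lambda.min behavior; the one-standard-error variant helps but not enough).
The default procedure therefore draws a random half of the cohort per
iteration, fits the lasso path (scikit-survival coxnet, shared penalty grid
from the full-data path, loose tolerance at the selection stage), and
records the support at the largest penalty admitting at least 15% of the
candidates. Half-sample perturbation is what makes the frequency rule
selective — a borderline CpG is in and out of the support across subsamples
— while strong signals survive every subsample. On planted-signal cohorts
the behavior is flat across a wide range of the support cap (roughly
0.13–0.16 of the candidate count), so the 15% default is not a tuned edge.
The literal fold-reshuffling CV procedure remains available
(`penalty_rule="cv"`).

**Refit and score.** Kept CpGs get a joint unpenalized Cox refit (ridge
1e-4 on singularity); the signature is the linear score s = Σᵢ βᵢ·Mᵢ — by
construction linear in the M-values — with the dichotomization cutoff at the
median training score (strictly above → high).

**What to expect at desk scale.** Marginal per-CpG effects are attenuated
when several prognostic CpGs and subtype structure all contribute hazard
(omitted-covariate non-collapsibility in Cox models), so a genome-wide scan
at 10⁻⁵ on a 600-sample cohort legitimately recovers only the strongest few
candidates even when ten CpGs were planted. The signature-recovery tests
therefore feed the candidate block directly, matching how the candidate set
is defined in practice (a prior genome-wide scan at larger n).

## Nanopore ingestion

bedMethyl records (modkit dialect, nine core columns, extended count columns
used when present) are filtered to one modification code (5mCG by default;
5hmC records are ignored unless pooling is requested), checked for
percent/count consistency (±0.1), and strand-collapsed: for a reference CpG
at forward position p, the + record at p pools with the − record at p+1, and
β = Σ n_mod / Σ coverage. Pooled coverage below `min_coverage` (default 1 —
the protocol this emulates imputed rather than thresholded, and ran down to
~1x genomes) leaves the locus missing; missing loci take the
discovery-cohort probe mean, with per-locus provenance (observed/imputed)
retained. A locus hit rate below 1% aborts with a genome-build-mismatch
error; below 10% observed loci the report carries a warning but a call is
still made. The gated path then runs: embedding transform → subtype call →
if confident and myeloid (per the bundle's configured myeloid label set),
mortality probability and hazard score.

## Synthetic cohorts

`CohortSpec` defaults are the package's reference study conditions: 600
samples × 2,000 CpGs, six subtypes with 100 marker probes each shifted by
0.35 beta toward the farther bound, three batches with a +0.05 additive
shift per batch index, 2% MCAR missingness, and survival from a proportional
hazards model — linear predictor = Σ planted log-HR × centered M-value
(10 planted CpGs in a 200-CpG candidate block, log-HR 1.0 per M-unit,
alternating sign) plus a per-subtype offset spread over ±1 — with an
exponential baseline calibrated by bisection so ~40% of samples have an
event by the 60-month horizon, under independent uniform censoring. Probe
baselines are a bimodal Beta mixture (methylomes concentrate near 0 and 1)
with per-sample Beta noise at concentration 30 (beta SD ≈ 0.07–0.09 at
intermediate means — biological within-group variation, not just array
noise). Everything is deterministic given the seed, byte-for-byte.

What the generator does *not* emulate: probe-type chemistry bias,
cell-composition mixtures, clonal evolution, spatially correlated CpGs
(probes are independent given their means), informative censoring, or
class-imbalanced cohorts. Consequently the passing tests demonstrate the
pipeline's mechanics and statistical calibration, not clinical performance:
perfectly separated synthetic clusters make subtype recovery essentially
exact, which real 28-class cohorts are not.

Two desk-scale behaviors follow directly from this design and are worth
flagging:

- **Mortality AUC from coordinates is information-limited.** The planted
  prognostic CpGs are deliberately orthogonal to cluster structure, so the
  only hazard visible to the 5 coordinates is the per-subtype offset; with
  the default ±1 spread the best achievable AUC from subtype alone is ≈0.58
  on the reference cohort (the full linear predictor scores ≈0.98). The
  coordinate-based mortality model hitting ~0.53 is near its ceiling, not
  broken. In real cohorts subtype structure is the dominant prognostic axis,
  which is why the analogous classifier is clinically useful there.
- **Ambiguous specimens are rarely flagged.** Specimens generated midway
  between two subtype centroids are *not* reliably reported as
  "Not confident": the embedding transform projects them onto the marginally
  nearer cluster (their own sampling noise at the 200 marker probes shifts
  the mean distance by more than the within-cluster distance spread), and
  boosted-tree probabilities are piecewise-constant, so even exact mid-gap
  coordinates score a max probability of 1/K, ~0.5 (a two-way tie, which the
  strict < 0.5 gate calls confident), or ~1.0. The gate earns its keep on
  real, genuinely overlapping cohorts; on idealized separated clusters it
  has almost nothing to catch and fails to catch the midpoints it was aimed
  at. This is reported as measured.

## Numerical choices

- Cox fits: lifelines Newton-Raphson at precision 10⁻¹⁰, Efron ties
  (Breslow selectable); Wald CIs on the log-HR scale.
- Held-out partial likelihood for penalty scoring: Breslow form, computed
  locally (risk sets by cumulative logsumexp over descending time, tied
  times sharing the risk set).
- Coxnet path: 40 alphas, alpha_min_ratio 0.005; tolerance 10⁻⁴ at the
  selection stage (support patterns are insensitive to it; verified against
  10⁻⁷), full precision elsewhere.
- AUC: Mann-Whitney with half credit for ties; chi-squared without
  continuity correction by default.
- Dichotomization boundary: score strictly above the cutoff is high; ties go
  low. Candidate selection uses strict inequality at the p-value threshold.
- Bundle serialization: a single joblib container with an embedded schema
  tag, checked on load; no timestamps, so identical training runs produce
  byte-identical files.

## Known limitations

- The reducer's out-of-sample transform is trusted for specimens resembling
  the training distribution; out-of-distribution inputs snap to the nearest
  cluster with high classifier confidence (see above). Interpret single-
  specimen confidence accordingly.
- The EWAS loops lifelines fits per CpG; at a few hundred candidates this is
  seconds, but a genuinely genome-scale scan (hundreds of thousands of CpGs)
  would want a vectorized score test first pass.
- ComBat here supports batch-only designs; biological covariates in the
  correction are out of scope.
- The 28-label vocabulary ships as configuration with no claim of clinical
  completeness; users supply their own controlled list.
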