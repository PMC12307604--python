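# methatlas

Epigenomic diagnosis and prognosis for acute leukemia from CpG methylation,
as one reusable pipeline: harmonize beta-value matrices from methylation
arrays, compress methylomes into a low-dimensional atlas, call WHO-2022-style
subtypes and 5-year mortality risk from the atlas coordinates, derive a
compact stability-selected CpG survival signature, and classify
nanopore-derived methylomes (modkit bedMethyl) end to end.

It is written for computational biologists and translational researchers who
work with Illumina 450k/EPIC-style beta matrices or long-read 5mCG calls and
want a reproducible desk-scale implementation of this class of
methylation-classifier workflow, testable entirely on synthetic cohorts.

## The models

A methylome is a vector of beta values β ∈ [0,1] over a fixed, ordered CpG
reference. The pipeline stages are:

1. **QC cascade** — six exclusion stages in fixed order: masked
   (sex-linked/non-CpG) probes, literature-flagged unreliable probes,
   externally listed failing samples, CpGs with >5% missing values,
   non-hematopoietic samples, PCA outliers (score distance > k·SD on the top
   components). Remaining gaps are filled by the batch mean, and batch
   effects removed by parametric empirical-Bayes location/scale adjustment
   (ComBat), clamped back to [0,1].
2. **Atlas embedding** — a seeded neighbor-graph manifold embedding (UMAP)
   of the complete beta matrix: 2 coordinates for visualization, 5 for
   classification, with an out-of-sample transform for new specimens.
3. **Subtype classifier** — one-vs-rest gradient-boosted trees (LightGBM) on
   the 5 coordinates, tuned by stratified 5-fold CV over a small grid
   including L1/L2 penalties, with inverse-frequency class weights. Calls
   with max class probability < 0.5 are reported as *Not confident*.
4. **Mortality classifier** — a binary LightGBM model of death within 60
   months on the same coordinates (dead if the event occurred by the
   horizon, alive if followed past it; samples censored earlier are excluded
   from training but still scored).
5. **CpG survival signature** — per-CpG Cox proportional-hazards EWAS of
   5-year overall survival on M-values, M = log2(β/(1−β)), adjusted for risk
   group, with administrative censoring at 60 months; candidates at
   p < 10⁻⁵; stability selection over repeated L1-penalized Cox fits on
   half-samples, keeping CpGs with non-zero coefficients in ≥95% of fits; a
   joint unpenalized refit defines the linear hazard score
   s = Σᵢ βᵢ·Mᵢ, dichotomized high/low at the median training score.
6. **Nanopore ingestion** — modkit-style bedMethyl records are filtered to
   5mCG, strand-collapsed onto the reference (pooling + and − counts per CG),
   imputed at unobserved loci with the discovery-cohort probe means, and run
   through the gated inference path: subtype first; the prognostic models
   only for confident myeloid (AML/MDS) calls.

A `synthetic` module generates fully specified cohorts with bimodal
beta-mixture baselines, subtype marker shifts, additive batch effects, MCAR
missingness, proportional-hazards survival tied to planted prognostic CpGs,
and coverage-limited bedMethyl observations — so every stage is testable
without any data download.

## Worked example

```python
from methatlas.synthetic import (CohortSpec, generate_cohort, make_reference,
                                 generate_specimens, write_bedmethyl)
from methatlas.pipeline import PipelineConfig, train_pipeline, predict_matrix
from methatlas.nanopore import (parse_bedmethyl, collapse_strands,
                                impute_discovery_mean, classify_specimen)

spec = CohortSpec(seed=7)                    # 600 samples x 2,000 CpGs, 6 subtypes
matrix, samples, truth = generate_cohort(spec)
config = PipelineConfig(seed=7, stability_iterations=200,
                        myeloid_labels=("Subtype_A", "Subtype_B", "Subtype_C"))
bundle, reports = train_pipeline(matrix, samples, reference=make_reference(spec),
                                 config=config, candidate_probes=truth.candidate_probes)
print("subtype CV accuracy:", reports["subtype_cv"]["best_cv_accuracy"])
preds = predict_matrix(bundle, matrix)
```

prints (seed 7):

```
subtype CV accuracy: 1.0
             subtype  confidence  ...  hazard_score signature_group
S0000      Subtype_D         1.0  ...         1.764            high
S0001      Subtype_E         1.0  ...         0.270             low
```

Each row is one sample: the gated subtype call with its confidence, the
probability of death within 5 years with its high/low group, and the linear
CpG hazard score with its median-split group. On this cohort the six
synthetic subtypes separate perfectly in the embedding (CV accuracy 1.0);
the genome-wide EWAS at p < 10⁻⁵ retains 4 candidate CpGs of which 1 is
stably selected — marginal per-CpG effects are diluted when several planted
CpGs and the subtype structure all carry hazard, which is expected behavior
(see `docs/methods.md`).

A nanopore specimen of the same synthetic world, observed at 12x:

```python
beta = generate_specimens(spec, truth, "Subtype_B", 1, seed=99).iloc[0]
write_bedmethyl(beta.reindex(bundle.reference.probe_ids), bundle.reference,
                mean_coverage=12, seed=99, path="specimen.bed")
vec = collapse_strands(parse_bedmethyl("specimen.bed"), bundle.reference,
                       sample_id="case_01")
vec = impute_discovery_mean(vec, bundle.discovery_means)
print(classify_specimen(bundle, vec).to_text())
```

```
Specimen         : case_01
Subtype          : Subtype_B (confidence 1.00)
Second call      : Subtype_C
Observed loci    : 100.0% (mean coverage 12.0x)
5y death prob.   : 0.86 (high)
Hazard score     : 0.117 (low)
```

Because `Subtype_B` is configured as a myeloid class and the call is
confident, both prognostic models were applied; a lymphoid or unconfident
call would leave them blank with the reason recorded.

The same workflow is scriptable from the shell via the `methatlas` command
(`simulate`, `train`, `predict`, `ewas`, `signature`, `ingest-nanopore`,
`evaluate`); every run writes a machine-readable manifest with its full
configuration.

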