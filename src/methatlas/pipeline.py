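"""End-to-end training and inference recipes.

``train_pipeline`` runs the full discovery recipe on a labeled cohort:
QC cascade -> batch-mean imputation -> ComBat -> 2D + 5D embeddings ->
subtype and 5-year-mortality classifiers -> risk-adjusted Cox EWAS ->
stability-selected CpG signature -> a serializable :class:`ModelBundle`.

``predict_matrix`` applies a bundle to array-style beta matrices; the
bedMethyl path lives in :mod:`methatlas.nanopore`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    MortalityRiskClassifier,
    SubtypeClassifier,
    default_myeloid_labels,
)
from .datamodel import BetaMatrix, CpGLocus, CpGReference, ModelBundle, ValidationError
from .embedding import ManifoldEmbedding
from .preprocess import combat_correct, impute_batch_mean, m_matrix, qc_cascade
from .signature import cox_ewas, select_candidates, stability_select

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, serialized into every run log."""

    missing_threshold: float = 0.05   # CpG dropped if missing fraction exceeds this
    pca_components: int = 2
    pca_k_sd: float = 4.0
    epsilon: float = 1e-6             # M-value clamp
    embedding_neighbors: int = 15
    ewas_alpha: float = 1e-5          # EWAS significance threshold
    max_candidates: int = 200
    stability_iterations: int = 1000
    stability_folds: int = 10
    stability_threshold: float = 0.95
    confidence_threshold: float = 0.5
    horizon_months: float = 60.0
    seed: int = 0
    vocabulary: tuple | None = None
    myeloid_labels: tuple | None = None

    def validate(self) -> "PipelineConfig":
        if not (0.0 < self.missing_threshold < 1.0):
            raise ValidationError("missing_threshold must be in (0, 1)")
        if not (0.0 < self.ewas_alpha < 1.0):
            raise ValidationError("ewas_alpha must be in (0, 1)")
        if not (0.0 < self.stability_threshold <= 1.0):
            raise ValidationError("stability_threshold must be in (0, 1]")
        if not (0.0 < self.confidence_threshold < 1.0):
            raise ValidationError("confidence_threshold must be in (0, 1)")
        if self.stability_iterations < 1 or self.stability_folds < 2:
            raise ValidationError("invalid stability-selection settings")
        if self.horizon_months <= 0:
            raise ValidationError("horizon_months must be positive")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("vocabulary", "myeloid_labels"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data).validate()


def _pseudo_reference(probe_ids) -> CpGReference:
    loci = tuple(CpGLocus(p, "chrU", 1000 + 10 * i, 1000 + 10 * i + 2)
                 for i, p in enumerate(probe_ids))
    return CpGReference(loci, "unplaced")


def _risk_covariates(samples: pd.DataFrame, index) -> pd.DataFrame | None:
    """One-hot risk-group indicators for the EWAS adjustment, if available."""
    if "risk_group" not in samples.columns:
        return None
    rg = samples.loc[index, "risk_group"]
    if rg.isna().all():
        return None
    dummies = pd.get_dummies(rg.fillna("unknown"), prefix="risk", drop_first=True)
    return dummies.astype(float)


def train_pipeline(
    matrix: BetaMatrix,
    samples: pd.DataFrame,
    reference: CpGReference | None = None,
    config: PipelineConfig | None = None,
    sex_noncpg_mask: set = frozenset(),
    unreliable_mask: set = frozenset(),
    qc_fail_sample_ids: set = frozenset(),
    nonhematopoietic_sample_ids: set = frozenset(),
    candidate_probes=None,
) -> tuple[ModelBundle, dict]:
    """Run the full discovery recipe; return (bundle, reports).

    ``candidate_probes`` optionally restricts the EWAS scan (otherwise every
    surviving CpG is tested).  Samples must carry ``batch``; subtype training
    uses rows with ``who2022_label``; survival models use ``os_time``/``os_event``.
    """
    config = (config or PipelineConfig()).validate()
    reports: dict = {"config": dataclasses.asdict(config)}

    qc_matrix, qc_report = qc_cascade(
        matrix, samples,
        sex_noncpg_mask=sex_noncpg_mask,
        unreliable_mask=unreliable_mask,
        qc_fail_sample_ids=qc_fail_sample_ids,
        missing_threshold=config.missing_threshold,
        nonhematopoietic_sample_ids=nonhematopoietic_sample_ids,
        pca_outlier_kwargs={"n_components": config.pca_components, "k_sd": config.pca_k_sd},
    )
    reports["qc"] = qc_report
    samples = samples.loc[qc_matrix.sample_ids]

    batches = samples["batch"]
    imputed = impute_batch_mean(qc_matrix, batches)
    corrected = combat_correct(imputed, batches) if batches.nunique() > 1 else imputed

    probe_ids = corrected.probe_ids
    if reference is None:
        reference = _pseudo_reference(probe_ids)
    else:
        reference = reference.subset(probe_ids)
        if reference.probe_ids != probe_ids:
            corrected = BetaMatrix(corrected.frame[reference.probe_ids], validate=False)
            probe_ids = corrected.probe_ids
    discovery_means = corrected.frame.mean(axis=0)

    embed2 = ManifoldEmbedding(n_dims=2, seed=config.seed,
                               n_neighbors=config.embedding_neighbors).fit(corrected)
    embed5 = ManifoldEmbedding(n_dims=5, seed=config.seed,
                               n_neighbors=config.embedding_neighbors).fit(corrected)
    coords5 = embed5.embedding_

    labeled = samples["who2022_label"].notna()
    subtype_model = SubtypeClassifier(
        vocabulary=config.vocabulary, seed=config.seed,
        confidence_threshold=config.confidence_threshold,
    ).fit(coords5[labeled.to_numpy()], samples.loc[labeled, "who2022_label"])
    reports["subtype_cv"] = subtype_model.cv_results_

    risk_model = None
    signature = None
    has_surv = samples["os_time"].notna() & samples["os_event"].notna() \
        if "os_time" in samples.columns else pd.Series(False, index=samples.index)
    if has_surv.any():
        surv = samples.loc[has_surv]
        coords_surv = coords5[has_surv.to_numpy()]
        risk_model = MortalityRiskClassifier(
            horizon_months=config.horizon_months, seed=config.seed,
        ).fit(coords_surv, surv["os_time"], surv["os_event"])
        reports["risk_cv"] = risk_model.cv_results_

        mvals = m_matrix(
            BetaMatrix(corrected.frame.loc[surv.index], validate=False),
            epsilon=config.epsilon,
        )
        scan = mvals[list(candidate_probes)] if candidate_probes is not None else mvals
        ewas = cox_ewas(scan, surv["os_time"], surv["os_event"],
                        adjustment_covariates=_risk_covariates(samples, surv.index),
                        horizon=config.horizon_months)
        reports["ewas"] = ewas
        candidates = select_candidates(ewas, alpha=config.ewas_alpha)
        candidates = candidates[: config.max_candidates]
        reports["n_candidates"] = len(candidates)
        if len(candidates) >= 2:
            try:
                signature = stability_select(
                    mvals[candidates], surv["os_time"], surv["os_event"],
                    n_iter=config.stability_iterations, n_folds=config.stability_folds,
                    freq_threshold=config.stability_threshold, seed=config.seed,
                    horizon=config.horizon_months,
                )
                reports["n_signature_cpgs"] = len(signature.entries)
            except ValidationError as exc:
                # a cohort can legitimately support no stable signature; the
                # other models remain usable
                logger.warning("signature not trained: %s", exc)
                reports["signature_skipped"] = str(exc)
        else:
            logger.warning("fewer than 2 EWAS candidates; signature not trained")

    myeloid = (frozenset(config.myeloid_labels) if config.myeloid_labels is not None
               else default_myeloid_labels(subtype_model.classes_))
    bundle = ModelBundle(
        reference=reference,
        discovery_means=discovery_means,
        embedding2d=embed2,
        embedding5d=embed5,
        subtype_model=subtype_model,
        risk_model=risk_model,
        signature=signature,
        myeloid_labels=myeloid,
        version=__version__,
        provenance={"config": dataclasses.asdict(config)},
    )
    return bundle, reports


def prepare_matrix_for_bundle(bundle: ModelBundle, matrix: BetaMatrix) -> BetaMatrix:
    """Align an array-style matrix to the bundle reference and impute gaps
    with the discovery means."""
    frame = matrix.frame.reindex(columns=bundle.reference.probe_ids)
    fill = bundle.discovery_means
    frame = frame.fillna(fill)
    if frame.isna().to_numpy().any():
        raise ValidationError("matrix could not be completed against the bundle reference")
    return BetaMatrix(frame, validate=False)


def predict_matrix(bundle: ModelBundle, matrix: BetaMatrix,
                   epsilon: float = 1e-6) -> pd.DataFrame:
    """Apply subtype, mortality-risk, and signature models to array samples.

    Returns one row per sample: subtype call (gated), confidence, second
    call, 5-year death probability and group, hazard score and group.
    """
    from .preprocess import beta_to_m
    from .signature import dichotomize, hazard_score

    aligned = prepare_matrix_for_bundle(bundle, matrix)
    embed5 = bundle.require("embedding5d")
    subtype_model = bundle.require("subtype_model")
    coords = embed5.transform(aligned)
    preds = subtype_model.predict_subtypes(coords, sample_ids=aligned.sample_ids)
    rows = []
    risk = None
    if bundle.risk_model is not None:
        risk = bundle.risk_model.predict_risk(coords, sample_ids=aligned.sample_ids)
    scores = None
    if bundle.signature is not None:
        mvals = pd.DataFrame(beta_to_m(aligned.values, epsilon=epsilon),
                             index=aligned.frame.index, columns=aligned.frame.columns)
        scores = hazard_score(bundle.signature, mvals)
        groups = dichotomize(scores, bundle.signature.cutoff)
    for i, p in enumerate(preds):
        row = {
            "sample_id": p.sample_id,
            "subtype": p.reported_label,
            "top_label": p.top_label,
            "confidence": float(p.class_probabilities.max()),
            "second_label": p.second_label,
        }
        if risk is not None:
            row["p_death_5y"] = risk[i].p_death_5y
            row["risk_group"] = risk[i].group
        if scores is not None:
            row["hazard_score"] = float(scores.iloc[i])
            row["signature_group"] = str(groups.iloc[i])
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
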