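"""Quality-control cascade, imputation, M-value transform, and batch correction.

The QC cascade applies six exclusion stages in a fixed order (probe masks,
unreliable probes, externally flagged samples, high-missingness CpGs,
non-hematopoietic samples, PCA outliers); the stage order matters because
the per-stage removal counts are order-dependent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datamodel import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

QC_STAGES = (
    "sex_linked_noncpg",
    "unreliable",
    "sample_qc_fail",
    "high_missing_cpgs",
    "nonhematopoietic",
    "pca_outliers",
)


@dataclass
class QCReport:
    """Per-stage removal accounting for one run of the QC cascade."""

    removed: dict = field(default_factory=dict)
    stage_log: list = field(default_factory=list)
    final_shape: tuple = (0, 0)

    def record(self, stage: str, count: int, detail: str = "") -> None:
        if count < 0:
            raise ValidationError("removed count cannot be negative")
        self.removed[stage] = count
        self.stage_log.append((stage, count, detail))


def qc_cascade(
    matrix: BetaMatrix,
    samples: pd.DataFrame | None = None,
    sex_noncpg_mask: set = frozenset(),
    unreliable_mask: set = frozenset(),
    qc_fail_sample_ids: set = frozenset(),
    missing_threshold: float = 0.05,
    nonhematopoietic_sample_ids: set = frozenset(),
    pca_outlier_kwargs: dict | None = None,
) -> tuple[BetaMatrix, QCReport]:
    """Apply the six-stage exclusion cascade in order; return matrix and report.

    Stage (iv) removes CpGs whose missing fraction strictly exceeds
    ``missing_threshold`` (default 0.05, i.e. "over 5% missing").
    Stage (vi) runs :func:`pca_outliers` on the surviving samples; pass
    ``pca_outlier_kwargs=None`` to skip it (e.g. when the matrix still has
    missingness you prefer to impute first).
    """
    if not (0.0 < missing_threshold < 1.0):
        raise ValidationError("missing_threshold must be in (0, 1)")
    frame = matrix.frame
    report = QCReport()

    # (i) sex-linked / non-CpG probes
    drop = [p for p in frame.columns if p in sex_noncpg_mask]
    frame = frame.drop(columns=drop)
    report.record("sex_linked_noncpg", len(drop))

    # (ii) literature-flagged unreliable probes
    drop = [p for p in frame.columns if p in unreliable_mask]
    frame = frame.drop(columns=drop)
    report.record("unreliable", len(drop))

    # (iii) samples failing upstream (detection-p) QC, consumed as a list
    known = [s for s in qc_fail_sample_ids if s in frame.index]
    unknown = sorted(set(qc_fail_sample_ids) - set(known))
    if unknown:
        warnings.warn(f"unknown sample id(s) in exclusion list: {unknown[:5]}", stacklevel=2)
    frame = frame.drop(index=known)
    report.record("sample_qc_fail", len(known))

    # (iv) CpGs with missing fraction over threshold
    miss_frac = frame.isna().mean(axis=0)
    drop = list(miss_frac.index[miss_frac > missing_threshold])
    frame = frame.drop(columns=drop)
    report.record("high_missing_cpgs", len(drop))

    # (v) non-hematopoietic samples, externally listed
    known = [s for s in nonhematopoietic_sample_ids if s in frame.index]
    frame = frame.drop(index=known)
    report.record("nonhematopoietic", len(known))

    # (vi) PCA outliers
    if pca_outlier_kwargs is not None:
        out = pca_outliers(BetaMatrix(frame, validate=False), **pca_outlier_kwargs)
        frame = frame.drop(index=sorted(out))
        report.record("pca_outliers", len(out))
    else:
        report.record("pca_outliers", 0, "skipped")

    report.final_shape = frame.shape
    return BetaMatrix(frame, validate=False), report


def pca_outliers(matrix: BetaMatrix, n_components: int = 2, k_sd: float = 4.0) -> set:
    """Flag samples far from the cohort in top principal-component score space.

    Each sample's score on each of the top ``n_components`` PCs is scaled by
    that component's score standard deviation; samples whose Euclidean norm of
    scaled scores exceeds ``k_sd`` are flagged.  Missing values are filled with
    the probe mean for the decomposition only.
    """
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if matrix.n_samples <= n_components:
        raise ValidationError("need more samples than components for PCA outlier screening")
    vals = matrix.frame.to_numpy(dtype=float)
    col_mean = np.nanmean(vals, axis=0)
    filled = np.where(np.isnan(vals), col_mean[None, :], vals)
    filled = filled - filled.mean(axis=0, keepdims=True)
    scores = PCA(n_components=n_components, random_state=0).fit_transform(filled)
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0.0] = np.inf  # degenerate component carries no outlier information
    dist = np.sqrt(((scores / sd) ** 2).sum(axis=1))
    flagged = np.asarray(matrix.sample_ids)[dist > k_sd]
    return set(flagged)


def impute_batch_mean(matrix: BetaMatrix, batches: pd.Series) -> BetaMatrix:
    """Fill missing betas with the probe mean within the sample's batch.

    Falls back to the global probe mean when a (batch, probe) cell has no
    observed values (logged); a probe missing in every sample is an error —
    the QC cascade should have removed it.  Observed entries are untouched.
    """
    frame = matrix.frame
    batches = pd.Series(batches).reindex(frame.index)
    if batches.isna().any():
        raise ValidationError("every sample needs a batch label for imputation")
    vals = frame.to_numpy(dtype=float).copy()
    if not np.isnan(vals).any():
        return matrix.copy()
    all_missing = np.isnan(vals).all(axis=0)
    if all_missing.any():
        bad = list(np.asarray(matrix.probe_ids)[all_missing][:5])
        raise ValidationError(f"probe(s) missing in all samples: {bad}")
    global_mean = np.nanmean(vals, axis=0)
    n_fallback = 0
    for _, idx in frame.groupby(batches, sort=False).indices.items():
        block = vals[idx]
        mask = np.isnan(block)
        if not mask.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN batch columns
            bmean = np.nanmean(block, axis=0)
        empty = np.isnan(bmean)
        n_fallback += int((mask & empty[None, :]).any(axis=0).sum())
        bmean = np.where(empty, global_mean, bmean)
        block[mask] = np.broadcast_to(bmean[None, :], block.shape)[mask]
        vals[idx] = block
    if n_fallback:
        logger.info("batch-mean imputation fell back to global mean for %d (batch, probe) cells",
                    n_fallback)
    return BetaMatrix(pd.DataFrame(vals, index=frame.index, columns=frame.columns),
                      validate=False)


def combat_correct(matrix: BetaMatrix, batches: pd.Series) -> BetaMatrix:
    """Empirical-Bayes location/scale batch correction of a complete beta matrix.

    Parametric prior, batch-only design (no biological covariates).  After
    correction each probe is recentred to its pre-correction grand mean, then
    clamped to [0, 1].  A single-batch matrix is returned unchanged.
    """
    frame = matrix.frame
    if not matrix.is_complete():
        raise ValidationError("combat_correct requires a complete matrix; impute first")
    batches = pd.Series(batches).reindex(frame.index).astype(str)
    if batches.isna().any():
        raise ValidationError("every sample needs a batch label")
    counts = batches.value_counts()
    singletons = counts.index[counts < 2].tolist()
    if singletons:
        raise ValidationError(f"batch(es) with a single sample: {singletons}")
    if counts.size == 1:
        return matrix.copy()

    import anndata

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import scanpy as sc

        adata = anndata.AnnData(
            X=frame.to_numpy(dtype=float).copy(),
            obs=pd.DataFrame({"batch": batches.to_numpy()}, index=frame.index.astype(str)),
        )
        corrected = sc.pp.combat(adata, key="batch", inplace=False)
    corrected = np.asarray(corrected, dtype=float)
    # restore per-probe grand mean, then respect the beta support
    corrected += frame.to_numpy().mean(axis=0, keepdims=True) - corrected.mean(axis=0, keepdims=True)
    corrected = np.clip(corrected, 0.0, 1.0)
    return BetaMatrix(pd.DataFrame(corrected, index=frame.index, columns=frame.columns),
                      validate=False)


def beta_to_m(beta, epsilon: float = 1e-6):
    """Logit-scale methylation: M = log2(beta / (1 - beta)), clamped to [eps, 1-eps].

    Strictly monotone in beta and odd around beta = 0.5.  The clamp keeps M
    finite for beta in {0, 1}, which occurs in low-coverage nanopore data.
    """
    if not (0.0 < epsilon < 0.5):
        raise ValidationError("epsilon must be in (0, 0.5)")
    arr = np.asarray(beta, dtype=float)
    if arr.size and (np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0):
        raise ValidationError("beta values outside [0, 1]")
    clamped = np.clip(arr, epsilon, 1.0 - epsilon)
    m = np.log2(clamped / (1.0 - clamped))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(m)
    return m


def m_matrix(matrix: BetaMatrix, epsilon: float = 1e-6) -> pd.DataFrame:
    """M-value DataFrame for a complete beta matrix (same axes)."""
    if not matrix.is_complete():
        raise ValidationError("M-value conversion requires a complete matrix")
    return pd.DataFrame(
        beta_to_m(matrix.values, epsilon=epsilon),
        index=matrix.frame.index,
        columns=matrix.frame.columns,
    )
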