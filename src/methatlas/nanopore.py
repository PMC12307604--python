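"""bedMethyl ingestion: strand collapsing, discovery-mean imputation, and the
gated specimen inference path.

Nanopore methylation callers report per-strand 5mCG tallies; an array-style
CpG reference addresses the forward-strand C of each CG.  Collapsing pools
the + record at ``start`` with the - record at ``start + 1`` into one beta
per locus.  Loci below the coverage floor are missing and are imputed with
the discovery-cohort probe mean before classification.  Prognostic models
run only when the subtype call is a confident myeloid (AML/MDS) class.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import NOT_CONFIDENT
from .datamodel import CpGReference, ModelBundle, ValidationError
from .preprocess import beta_to_m
from .signature import dichotomize, hazard_score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BedMethylRecord:
    chrom: str
    start: int
    end: int
    mod_code: str
    strand: str
    valid_coverage: int
    percent_modified: float
    n_mod: int | None = None
    n_canonical: int | None = None

    def modified_count(self) -> int:
        if self.n_mod is not None:
            return self.n_mod
        return int(round(self.percent_modified / 100.0 * self.valid_coverage))


@dataclass
class MethylomeVector:
    """One sample's betas over a reference, with per-locus provenance."""

    sample_id: str
    betas: pd.Series          # indexed by probe_id, NaN = missing
    source: pd.Series         # "observed" | "imputed" | "missing"
    coverage: pd.Series
    tissue: str = ""

    @property
    def observed_fraction(self) -> float:
        return float((self.source == "observed").mean())

    def is_complete(self) -> bool:
        return not bool(self.betas.isna().any())


def parse_bedmethyl(path, mod_code: str = "m", max_malformed_frac: float = 0.10):
    """Parse a modkit-dialect bedMethyl into records of one modification code.

    Nine core columns are required; extended count columns are used when
    present and checked for consistency with the percent column (records off
    by more than 0.1 percentage points are flagged and excluded).  More than
    ``max_malformed_frac`` malformed lines is a hard error.
    """
    records = []
    n_lines = n_malformed = n_inconsistent = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            try:
                if len(fields) < 10:
                    raise ValueError("fewer than 10 columns")
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                code = fields[3]
                strand = fields[5]
                valid_cov = int(fields[9])
                pct = float(fields[10]) if len(fields) > 10 else float(fields[4])
                n_mod = int(fields[11]) if len(fields) > 11 else None
                n_can = int(fields[12]) if len(fields) > 12 else None
            except (ValueError, IndexError):
                n_malformed += 1
                continue
            if code != mod_code:
                continue
            if not (0.0 <= pct <= 100.0):
                n_malformed += 1
                continue
            if n_mod is not None and valid_cov > 0:
                if abs(pct - 100.0 * n_mod / valid_cov) > 0.1:
                    n_inconsistent += 1
                    continue
            records.append(BedMethylRecord(chrom, start, end, code, strand,
                                           valid_cov, pct, n_mod, n_can))
    if n_lines and n_malformed / n_lines > max_malformed_frac:
        raise ValidationError(
            f"{n_malformed}/{n_lines} malformed bedMethyl lines in {path}"
        )
    if n_malformed or n_inconsistent:
        logger.info("bedMethyl %s: skipped %d malformed, %d count-inconsistent line(s)",
                    path, n_malformed, n_inconsistent)
    return records


def collapse_strands(records, reference: CpGReference, min_coverage: int = 1,
                     sample_id: str = "specimen", tissue: str = "",
                     min_hit_rate: float = 0.01) -> MethylomeVector:
    """Pool per-strand counts into one beta per reference CpG.

    For a locus at forward-strand position ``start``, the + record at
    ``start`` and the - record at ``start + 1`` are pooled:
    beta = sum(n_mod) / sum(valid_coverage).  Pooled coverage below
    ``min_coverage`` leaves the locus missing.  A locus hit rate below
    ``min_hit_rate`` suggests a genome-build mismatch and is an error.
    """
    pooled_mod: dict = {}
    pooled_cov: dict = {}
    index = {}
    for locus in reference.loci:
        index[(locus.chrom, locus.start, "+")] = locus.probe_id
        index[(locus.chrom, locus.start + 1, "-")] = locus.probe_id
    for rec in records:
        key = (rec.chrom, rec.start, rec.strand)
        probe = index.get(key)
        if probe is None and rec.strand == ".":
            probe = index.get((rec.chrom, rec.start, "+"))
        if probe is None:
            continue
        pooled_mod[probe] = pooled_mod.get(probe, 0) + rec.modified_count()
        pooled_cov[probe] = pooled_cov.get(probe, 0) + rec.valid_coverage

    probe_ids = reference.probe_ids
    cov = pd.Series([pooled_cov.get(p, 0) for p in probe_ids], index=probe_ids, dtype=float)
    if len(records) >= 100 and (cov > 0).mean() < min_hit_rate:
        raise ValidationError(
            f"only {(cov > 0).mean():.2%} of reference loci were hit; "
            "likely genome-build mismatch between bedMethyl and reference"
        )
    betas = pd.Series(np.nan, index=probe_ids, dtype=float)
    ok = cov >= min_coverage
    mods = pd.Series([pooled_mod.get(p, 0) for p in probe_ids], index=probe_ids, dtype=float)
    betas[ok] = mods[ok] / cov[ok]
    source = pd.Series(np.where(ok, "observed", "missing"), index=probe_ids)
    return MethylomeVector(sample_id=sample_id, betas=betas, source=source,
                           coverage=cov, tissue=tissue)


def impute_discovery_mean(vector: MethylomeVector, discovery_means: pd.Series) -> MethylomeVector:
    """Fill missing loci with the discovery-cohort probe mean (observed untouched)."""
    missing = vector.betas.index[vector.betas.isna()]
    absent = [p for p in missing if p not in discovery_means.index
              or pd.isna(discovery_means.get(p))]
    if absent:
        raise ValidationError(f"discovery mean absent for missing locus/loci: {absent[:5]}")
    betas = vector.betas.copy()
    source = vector.source.copy()
    betas.loc[missing] = discovery_means.reindex(missing).to_numpy()
    source.loc[missing] = "imputed"
    if len(missing) == len(betas):
        logger.warning("specimen %s: 0%% observed loci; vector equals discovery means",
                       vector.sample_id)
    return MethylomeVector(vector.sample_id, betas, source, vector.coverage.copy(),
                           vector.tissue)


@dataclass
class SpecimenReport:
    """End-to-end inference result for one specimen."""

    sample_id: str
    subtype_label: str            # "Not confident" when gated
    subtype_confidence: float
    second_label: str
    confident: bool
    coordinates: list
    observed_fraction: float
    mean_coverage: float
    risk_probability: float | None = None
    risk_group: str | None = None
    hazard_score: float | None = None
    signature_group: str | None = None
    prognosis_skipped_reason: str | None = None
    warnings: list = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent)

    def to_text(self) -> str:
        lines = [
            f"Specimen         : {self.sample_id}",
            f"Subtype          : {self.subtype_label} (confidence {self.subtype_confidence:.2f})",
            f"Second call      : {self.second_label}",
            f"Observed loci    : {self.observed_fraction:.1%} (mean coverage {self.mean_coverage:.1f}x)",
        ]
        if self.risk_probability is not None:
            lines.append(f"5y death prob.   : {self.risk_probability:.2f} ({self.risk_group})")
        if self.hazard_score is not None:
            lines.append(f"Hazard score     : {self.hazard_score:.3f} ({self.signature_group})")
        if self.prognosis_skipped_reason:
            lines.append(f"Prognosis        : not applied ({self.prognosis_skipped_reason})")
        for w in self.warnings:
            lines.append(f"Warning          : {w}")
        return "\n".join(lines)


def classify_specimen(bundle: ModelBundle, vector: MethylomeVector,
                      observed_floor: float = 0.10) -> SpecimenReport:
    """Run the gated inference path on a complete (post-imputation) methylome.

    Embedding transform -> subtype call; the mortality classifier and the CpG
    signature run only when the top label is a myeloid (AML/MDS) class called
    with >= 50% confidence.
    """
    if list(vector.betas.index) != bundle.reference.probe_ids:
        raise ValidationError("methylome vector does not follow the bundle's reference order")
    if not vector.is_complete():
        raise ValidationError("vector has missing loci; run impute_discovery_mean first")
    warnings_list = []
    if vector.observed_fraction < observed_floor:
        warnings_list.append(
            f"only {vector.observed_fraction:.1%} of loci observed; call may be unreliable"
        )
    row = vector.betas.to_numpy(dtype=float)[None, :]
    embed5 = bundle.require("embedding5d")
    coords = np.asarray(embed5.transform(row), dtype=float)
    subtype_model = bundle.require("subtype_model")
    pred = subtype_model.predict_subtypes(coords, sample_ids=[vector.sample_id])[0]
    report = SpecimenReport(
        sample_id=vector.sample_id,
        subtype_label=pred.top_label if pred.confident else NOT_CONFIDENT,
        subtype_confidence=float(pred.class_probabilities.max()),
        second_label=pred.second_label,
        confident=pred.confident,
        coordinates=[float(c) for c in coords[0]],
        observed_fraction=vector.observed_fraction,
        mean_coverage=float(vector.coverage.mean()),
        warnings=warnings_list,
    )
    if not pred.confident:
        report.prognosis_skipped_reason = "subtype call not confident"
        return report
    if pred.top_label not in bundle.myeloid_labels:
        report.prognosis_skipped_reason = "non-myeloid"
        return report
    if bundle.risk_model is not None:
        risk = bundle.risk_model.predict_risk(coords, sample_ids=[vector.sample_id])[0]
        report.risk_probability = risk.p_death_5y
        report.risk_group = risk.group
    if bundle.signature is not None:
        m_row = pd.DataFrame(beta_to_m(row), index=[vector.sample_id],
                             columns=vector.betas.index)
        score = float(hazard_score(bundle.signature, m_row).iloc[0])
        report.hazard_score = score
        report.signature_group = str(dichotomize([score], bundle.signature.cutoff).iloc[0])
    return report
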