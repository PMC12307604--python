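"""Readers and writers for the pipeline's external formats.

Matrices travel as delimited text (TSV/CSV) with samples as rows (a flag
accepts probe-rows exports); CpG references travel as BED4 (0-based
half-open, probe_id in column 4); probe masks as one probe_id per line;
trained model bundles as a versioned joblib container.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .datamodel import (
    BetaMatrix,
    CpGLocus,
    CpGReference,
    ModelBundle,
    ValidationError,
    validate_sample_table,
)

logger = logging.getLogger(__name__)


@dataclass
class MatrixImportReport:
    n_samples: int
    n_probes: int
    dropped_probes: list
    absent_probes: list


def _read_table(path, sep=None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_beta_matrix(path, reference: CpGReference | None = None,
                     orientation: str = "samples", sep=None) -> BetaMatrix:
    """Read a beta-value matrix from delimited text.

    Parameters
    ----------
    orientation
        ``"samples"`` if rows are samples (canonical), ``"probes"`` if the
        export has probes as rows (transposed on read).
    reference
        Optional :class:`CpGReference`; columns are subset/reordered to the
        reference order.  Probes absent from the file become all-missing
        columns; extra probes are dropped.  Both are recorded on the returned
        matrix's ``import_report`` attribute.

    Missing values may be empty cells or ``NA``; any non-numeric cell or a
    value outside [0, 1] raises :class:`ValidationError` naming the cell.
    """
    if orientation not in ("samples", "probes"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    frame = _read_table(path, sep=sep)
    if orientation == "probes":
        frame = frame.T
    # read_csv already maps empty cells and "NA" to NaN; anything else
    # non-numeric is a parse error we report by cell
    coerced = frame.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric value {frame.iat[r, c]!r} at sample "
            f"{frame.index[r]!r}, probe {frame.columns[c]!r}"
        )
    frame = coerced.astype(float)
    report = MatrixImportReport(frame.shape[0], frame.shape[1], [], [])
    if reference is not None:
        ref_ids = reference.probe_ids
        have = set(frame.columns)
        report.dropped_probes = [p for p in frame.columns if p not in set(ref_ids)]
        report.absent_probes = [p for p in ref_ids if p not in have]
        if report.dropped_probes:
            logger.info("dropped %d probe(s) absent from reference", len(report.dropped_probes))
        frame = frame.reindex(columns=ref_ids)
    matrix = BetaMatrix(frame)
    matrix.import_report = report
    return matrix


def write_beta_matrix(matrix: BetaMatrix, path, sep="\t") -> None:
    matrix.frame.to_csv(path, sep=sep, index_label="sample_id", na_rep="NA")


def read_sample_table(path, sep=None) -> pd.DataFrame:
    frame = _read_table(path, sep=sep)
    frame.index.name = "sample_id"
    return validate_sample_table(frame.reset_index())


def read_cpg_reference(path, genome_build: str = "hg38") -> CpGReference:
    """Read a BED4 CpG reference (0-based half-open; 4th column probe_id)."""
    loci = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end, probe_id = fields[0], fields[1], fields[2], fields[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if probe_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate probe_id {probe_id!r}")
            seen.add(probe_id)
            loci.append(CpGLocus(probe_id, chrom, start_i, end_i))
    return CpGReference(tuple(loci), genome_build)


def write_cpg_reference(reference: CpGReference, path) -> None:
    with open(path, "w") as fh:
        for l in reference.loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.probe_id}\n")


def read_probe_mask(path) -> set:
    """Read a probe mask list: one probe_id per line, ``#`` comments allowed."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.add(line.split()[0])
    if not ids:
        warnings.warn(f"probe mask {path} is empty", stacklevel=2)
    return ids


def save_bundle(bundle: ModelBundle, path) -> None:
    """Serialize a model bundle to a single versioned container file."""
    payload = {"schema": ModelBundle.SCHEMA, "bundle": bundle}
    joblib.dump(payload, path, compress=0)


def load_bundle(path) -> ModelBundle:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValidationError(f"cannot load bundle {path}: {exc}") from exc
    if not isinstance(payload, dict) or "schema" not in payload:
        raise ValidationError(f"{path} is not a model bundle container")
    if payload["schema"] != ModelBundle.SCHEMA:
        raise ValidationError(
            f"bundle schema mismatch: found {payload['schema']!r}, "
            f"expected {ModelBundle.SCHEMA!r}"
        )
    return payload["bundle"]
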