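"""Core data containers for the methylation-atlas pipeline.

The pipeline's substrate is the *beta value*: the fraction of methylated
signal observed at a CpG dinucleotide, a number in [0, 1].  Samples are
rows, CpG probes are columns, and every matrix in the pipeline is aligned
to the fixed probe ordering of a :class:`CpGReference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class MethAtlasError(Exception):
    """Base class for pipeline errors."""


class ValidationError(MethAtlasError):
    """Raised when an input violates a documented contract."""


class ComponentAbsentError(MethAtlasError):
    """Raised when a model-bundle component required for an operation is missing."""


@dataclass(frozen=True)
class CpGLocus:
    """One CpG dinucleotide on the forward strand (0-based half-open, end = start + 2)."""

    probe_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError(f"probe {self.probe_id!r}: empty chromosome name")
        if self.end != self.start + 2:
            raise ValidationError(
                f"probe {self.probe_id!r}: interval {self.chrom}:{self.start}-{self.end} "
                "does not span a CG dinucleotide (length must be 2)"
            )


@dataclass(frozen=True)
class CpGReference:
    """Ordered collection of CpG loci; its order defines column order of all matrices."""

    loci: tuple[CpGLocus, ...]
    genome_build: str = "hg38"

    def __post_init__(self) -> None:
        ids = [l.probe_id for l in self.loci]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate probe_id(s) in reference: {dupes[:5]}")
        pos = [(l.chrom, l.start) for l in self.loci]
        if len(set(pos)) != len(pos):
            raise ValidationError("duplicate (chrom, start) coordinates in reference")

    @property
    def probe_ids(self) -> list[str]:
        return [l.probe_id for l in self.loci]

    def __len__(self) -> int:
        return len(self.loci)

    def subset(self, probe_ids: Sequence[str]) -> "CpGReference":
        keep = set(probe_ids)
        return CpGReference(
            tuple(l for l in self.loci if l.probe_id in keep), self.genome_build
        )


class BetaMatrix:
    """Sample x CpG matrix of methylated fractions with explicit missingness.

    Internally a float DataFrame where NaN marks a missing observation.
    All non-missing values must lie in [0, 1].
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        if validate:
            vals = frame.to_numpy(dtype=float)
            finite = vals[~np.isnan(vals)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                bad = np.argwhere((vals < 0.0) | (vals > 1.0))
                r, c = bad[0]
                raise ValidationError(
                    f"beta value {vals[r, c]!r} outside [0,1] at "
                    f"sample {frame.index[r]!r}, probe {frame.columns[c]!r}"
                )
            if frame.index.duplicated().any():
                raise ValidationError("duplicate sample_ids")
            if frame.columns.duplicated().any():
                raise ValidationError("duplicate probe_ids")
        self.frame = frame.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.frame.to_numpy())

    @property
    def n_samples(self) -> int:
        return self.frame.shape[0]

    @property
    def n_probes(self) -> int:
        return self.frame.shape[1]

    def is_complete(self) -> bool:
        return not bool(np.isnan(self.frame.to_numpy()).any())

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.frame.copy(), validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"BetaMatrix({self.n_samples} samples x {self.n_probes} probes)"


SAMPLE_TABLE_REQUIRED = ["sample_id", "batch"]
SAMPLE_TABLE_OPTIONAL = [
    "tissue", "timepoint", "who2022_label", "risk_group", "mrd1",
    "os_time", "os_event", "efs_time", "efs_event",
    "age_group", "flt3_status", "wbc", "blast_pct",
]


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample clinical/technical annotation table.

    Survival times must be non-negative and event indicators 0/1 where present.
    Returns the table indexed by ``sample_id``.
    """
    for col in SAMPLE_TABLE_REQUIRED:
        if col not in table.columns and table.index.name != col:
            raise ValidationError(f"sample table missing required column {col!r}")
    if table.index.name != "sample_id":
        table = table.set_index("sample_id")
    if table.index.duplicated().any():
        raise ValidationError("duplicate sample_id in sample table")
    for tcol in ("os_time", "efs_time"):
        if tcol in table.columns:
            t = pd.to_numeric(table[tcol], errors="coerce")
            if (t.dropna() < 0).any():
                raise ValidationError(f"{tcol} contains negative values")
    for ecol in ("os_event", "efs_event"):
        if ecol in table.columns:
            e = table[ecol].dropna()
            if not set(pd.to_numeric(e, errors="coerce").dropna()).issubset({0.0, 1.0}):
                raise ValidationError(f"{ecol} must be 0/1")
    return table


@dataclass
class ModelBundle:
    """Everything needed to classify a new methylome, trained on one reference ordering.

    ``discovery_means`` carries the per-probe mean beta of the training cohort and is the
    imputation source for sparsely observed (e.g. nanopore) methylomes.
    """

    reference: CpGReference
    discovery_means: pd.Series
    embedding2d: object | None = None
    embedding5d: object | None = None
    subtype_model: object | None = None
    risk_model: object | None = None
    signature: object | None = None
    myeloid_labels: frozenset = frozenset()
    version: str = "1"
    provenance: dict = field(default_factory=dict)

    SCHEMA = "methatlas-bundle/1"

    def __post_init__(self) -> None:
        if len(self.discovery_means) != len(self.reference):
            raise ValidationError(
                "discovery_means length does not match reference size "
                f"({len(self.discovery_means)} vs {len(self.reference)})"
            )
        if list(self.discovery_means.index) != self.reference.probe_ids:
            raise ValidationError("discovery_means index does not follow reference order")

    def require(self, component: str):
        value = getattr(self, component)
        if value is None:
            raise ComponentAbsentError(f"bundle component absent: {component}")
        return value
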