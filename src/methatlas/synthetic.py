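"""Synthetic methylation cohorts with the statistical structure the pipeline assumes.

Each probe has a bimodal beta-mixture baseline (methylomes concentrate near 0
and 1); subtype-marker probes are shifted by a fixed beta offset per subtype;
batches add a constant shift; missingness is completely at random; survival
follows a proportional-hazards model whose linear predictor combines planted
prognostic CpG M-values with per-subtype baseline hazard offsets, under an
exponential baseline and independent uniform censoring.  A companion writer
emits modkit-style bedMethyl files that emulate coverage-limited nanopore
observation of the same methylomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, CpGLocus, CpGReference, ValidationError
from .preprocess import beta_to_m


@dataclass
class CohortSpec:
    """Fully determined recipe for one synthetic cohort.

    Defaults are the desk-scale study conditions: 600 samples x 2,000 CpGs,
    6 subtypes with 100 marker probes each at a 0.35 beta offset, 3 batches
    with a 0.05 additive shift, 2% missingness, and survival driven by 10
    planted prognostic CpGs (log-HR 1.0 per M-value unit) among a block of
    200 candidates, calibrated to ~40% events by the 60-month horizon.
    """

    n_samples: int = 600
    n_cpgs: int = 2000
    n_subtypes: int = 6
    markers_per_subtype: int = 100
    marker_offset: float = 0.35
    n_batches: int = 3
    batch_shift: float = 0.05
    missing_rate: float = 0.02
    n_candidates: int = 200
    n_prognostic: int = 10
    prognostic_loghr: float = 1.0
    subtype_loghr_spread: float = 1.0
    event_rate: float = 0.40
    horizon_months: float = 60.0
    concentration: float = 30.0
    seed: int = 0
    subtype_names: tuple = field(default=())

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        if not (0.0 < self.event_rate < 1.0):
            raise ValidationError("event_rate must be in (0, 1)")
        if self.marker_offset < 0 or self.marker_offset > 1:
            raise ValidationError("marker_offset must be in [0, 1]")
        if self.n_subtypes * self.markers_per_subtype + self.n_candidates > self.n_cpgs:
            raise ValidationError("marker and candidate blocks exceed n_cpgs")
        if not self.subtype_names:
            self.subtype_names = tuple(
                f"Subtype_{chr(ord('A') + k)}" for k in range(self.n_subtypes)
            )
        if len(self.subtype_names) != self.n_subtypes:
            raise ValidationError("subtype_names length must equal n_subtypes")


@dataclass
class TruthRecord:
    """Ground truth planted by the generator, for evaluation only."""

    subtype: pd.Series            # per sample
    linear_predictor: pd.Series   # per sample log relative hazard
    event_time_uncensored: pd.Series
    probe_roles: pd.Series        # per probe: subtype-marker / prognostic / null
    marker_probes: dict           # subtype name -> list of probes
    prognostic_probes: list
    candidate_probes: list
    baseline_means: pd.Series     # per-probe baseline beta mean
    clean_betas: pd.DataFrame     # pre-batch, pre-missingness betas


def _probe_layout(spec: CohortSpec):
    probes = [f"cg{i:06d}" for i in range(spec.n_cpgs)]
    marker: dict = {}
    cursor = 0
    for name in spec.subtype_names:
        marker[name] = probes[cursor:cursor + spec.markers_per_subtype]
        cursor += spec.markers_per_subtype
    candidates = probes[cursor:cursor + spec.n_candidates]
    return probes, marker, candidates


def make_reference(spec: CohortSpec, spacing: int = 1000) -> CpGReference:
    """A synthetic hg38-style CpG reference matching the cohort's probes."""
    probes, _, _ = _probe_layout(spec)
    loci = tuple(
        CpGLocus(p, "chr1", 10_000 + i * spacing, 10_000 + i * spacing + 2)
        for i, p in enumerate(probes)
    )
    return CpGReference(loci, "hg38")


def generate_cohort(spec: CohortSpec) -> tuple[BetaMatrix, pd.DataFrame, TruthRecord]:
    """Generate (beta matrix, sample table, truth) for one seeded cohort."""
    rng = np.random.default_rng(spec.seed)
    probes, marker_probes, candidate_probes = _probe_layout(spec)
    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    probe_index = {p: j for j, p in enumerate(probes)}

    # bimodal baseline: probe means drawn from a mixture of low- and
    # high-methylation Beta components
    comp = rng.random(spec.n_cpgs) < 0.5
    means = np.where(comp,
                     rng.beta(0.5 * 4, 4 * 4, spec.n_cpgs),
                     rng.beta(4 * 4, 0.5 * 4, spec.n_cpgs))
    means = np.clip(means, 0.03, 0.97)

    subtype = rng.integers(0, spec.n_subtypes, spec.n_samples)
    per_sample_means = np.tile(means, (spec.n_samples, 1))
    for k, name in enumerate(spec.subtype_names):
        rows = subtype == k
        cols = [probe_index[p] for p in marker_probes[name]]
        # shift toward the farther support bound so the offset survives clamping
        direction = np.where(means[cols] < 0.5, 1.0, -1.0)
        per_sample_means[np.ix_(rows, cols)] = np.clip(
            means[cols] + direction * spec.marker_offset, 0.01, 0.99)

    kappa = spec.concentration
    betas = rng.beta(per_sample_means * kappa, (1.0 - per_sample_means) * kappa)
    clean = pd.DataFrame(betas, index=sample_ids, columns=probes)

    # survival: PH with linear predictor from planted prognostic M-values
    # plus a per-subtype baseline offset; exponential baseline; uniform censoring
    prognostic = candidate_probes[: spec.n_prognostic]
    if prognostic:
        signs = np.where(np.arange(spec.n_prognostic) % 2 == 0, 1.0, -1.0)
        mvals = beta_to_m(clean[prognostic].to_numpy(), epsilon=1e-6)
        mvals = mvals - mvals.mean(axis=0, keepdims=True)
        lp = mvals @ (signs * spec.prognostic_loghr)
    else:
        lp = np.zeros(spec.n_samples)
    if spec.n_subtypes > 1:
        offsets = np.linspace(-spec.subtype_loghr_spread, spec.subtype_loghr_spread,
                              spec.n_subtypes)
    else:
        offsets = np.zeros(1)
    lp = lp + offsets[subtype]
    lp = lp - lp.mean()

    u = rng.random(spec.n_samples)
    censor = rng.uniform(0.0, 2.0 * spec.horizon_months, spec.n_samples)
    # calibrate the exponential baseline rate so the observed event fraction
    # (before the horizon, before censoring wins) matches spec.event_rate
    def event_frac(lam0: float) -> float:
        tt = -np.log(u) / (lam0 * np.exp(lp))
        return float(np.mean((tt <= censor) & (tt <= spec.horizon_months)))

    lo, hi = 1e-6, 10.0
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if event_frac(mid) < spec.event_rate:
            lo = mid
        else:
            hi = mid
    lam0 = np.sqrt(lo * hi)
    t_event = -np.log(u) / (lam0 * np.exp(lp))
    os_time = np.minimum(t_event, censor)
    os_event = (t_event <= censor).astype(int)

    # batches, additive shift, clamped
    batch = rng.integers(0, spec.n_batches, spec.n_samples)
    shifted = betas + (batch * spec.batch_shift)[:, None]
    shifted = np.clip(shifted, 0.0, 1.0)
    if spec.marker_offset > 0 and np.all((shifted <= 0.0) | (shifted >= 1.0)):
        raise ValidationError("infeasible spec: all beta mass pushed to the bounds")

    # missingness, completely at random
    if spec.missing_rate > 0:
        mask = rng.random(shifted.shape) < spec.missing_rate
        shifted = np.where(mask, np.nan, shifted)

    matrix = BetaMatrix(pd.DataFrame(shifted, index=sample_ids, columns=probes),
                        validate=False)
    subtype_labels = pd.Series([spec.subtype_names[k] for k in subtype],
                               index=sample_ids, name="who2022_label")
    samples = pd.DataFrame({
        "batch": [f"batch{b}" for b in batch],
        "tissue": "BM",
        "timepoint": "diagnosis",
        "who2022_label": subtype_labels,
        "os_time": os_time,
        "os_event": os_event,
        "efs_time": os_time * rng.uniform(0.6, 1.0, spec.n_samples),
        "efs_event": os_event,
    }, index=pd.Index(sample_ids, name="sample_id"))

    roles = pd.Series("null", index=probes, name="role")
    for name, cols in marker_probes.items():
        roles.loc[cols] = "subtype-marker"
    roles.loc[prognostic] = "prognostic"
    truth = TruthRecord(
        subtype=subtype_labels,
        linear_predictor=pd.Series(lp, index=sample_ids),
        event_time_uncensored=pd.Series(t_event, index=sample_ids),
        probe_roles=roles,
        marker_probes=marker_probes,
        prognostic_probes=list(prognostic),
        candidate_probes=list(candidate_probes),
        baseline_means=pd.Series(means, index=probes),
        clean_betas=clean,
    )
    return matrix, samples, truth


def generate_specimens(spec: CohortSpec, truth: TruthRecord, subtype_name: str,
                       n_specimens: int, seed: int = 0) -> pd.DataFrame:
    """Fresh specimens drawn from one subtype's generating distribution.

    Used to emulate new clinical samples of a known class (e.g. for the
    array-vs-nanopore concordance check); rows follow the cohort probe order.
    """
    if subtype_name not in truth.marker_probes:
        raise ValidationError(f"unknown subtype {subtype_name!r}")
    rng = np.random.default_rng(seed)
    probes = list(truth.probe_roles.index)
    probe_index = {p: j for j, p in enumerate(probes)}
    means = truth.baseline_means.to_numpy().copy()
    cols = [probe_index[p] for p in truth.marker_probes[subtype_name]]
    direction = np.where(means[cols] < 0.5, 1.0, -1.0)
    means[cols] = np.clip(means[cols] + direction * spec.marker_offset, 0.01, 0.99)
    kappa = spec.concentration
    rows = rng.beta(means[None, :] * kappa, (1.0 - means[None, :]) * kappa,
                    size=(n_specimens, len(probes)))
    ids = [f"SP{i:03d}" for i in range(n_specimens)]
    return pd.DataFrame(rows, index=ids, columns=probes)


def generate_midway_specimens(spec: CohortSpec, truth: TruthRecord,
                              n_specimens: int, seed: int = 0) -> pd.DataFrame:
    """Specimens drawn midway between two subtype centroids (ambiguous cases).

    Each specimen averages the per-probe generating means of a random subtype
    pair and samples betas at the cohort's concentration, so its methylome is
    equidistant from both clusters up to sampling noise.
    """
    rng = np.random.default_rng(seed)
    probes = list(truth.probe_roles.index)
    probe_index = {p: j for j, p in enumerate(probes)}
    means = truth.baseline_means.to_numpy()
    names = list(truth.marker_probes)
    rows = []
    ids = []
    for i in range(n_specimens):
        a, b = rng.choice(len(names), size=2, replace=False)
        mean_vec = means.copy()
        for name, weight_own in ((names[a], 0.5), (names[b], 0.5)):
            cols = [probe_index[p] for p in truth.marker_probes[name]]
            direction = np.where(means[cols] < 0.5, 1.0, -1.0)
            shifted = np.clip(means[cols] + direction * _spec_offset(spec), 0.01, 0.99)
            mean_vec[cols] = mean_vec[cols] + weight_own * (shifted - means[cols])
        kappa = spec.concentration
        beta = rng.beta(mean_vec * kappa, (1.0 - mean_vec) * kappa)
        rows.append(beta)
        ids.append(f"MID{i:03d}")
    return pd.DataFrame(rows, index=ids, columns=probes)


def _spec_offset(spec: CohortSpec) -> float:
    return spec.marker_offset


def write_bedmethyl(betas: pd.Series, reference: CpGReference, mean_coverage: float,
                    seed: int, path, mod_code: str = "m") -> None:
    """Write a modkit-dialect bedMethyl emulating coverage-limited observation.

    Per locus the total valid coverage is Poisson(mean_coverage), split
    binomially across strands; modified counts are Binomial(coverage, beta).
    Loci with zero coverage on a strand emit no record for that strand.
    """
    if mean_coverage <= 0:
        raise ValidationError("mean_coverage must be positive")
    rng = np.random.default_rng(seed)
    vals = betas.reindex([l.probe_id for l in reference.loci])
    if vals.isna().any():
        raise ValidationError("betas must cover every reference locus")
    with open(path, "w") as fh:
        for locus, beta in zip(reference.loci, vals.to_numpy(dtype=float)):
            cov = rng.poisson(mean_coverage)
            plus = rng.binomial(cov, 0.5)
            for strand, scov, start in (("+", plus, locus.start),
                                        ("-", cov - plus, locus.start + 1)):
                if scov == 0:
                    continue
                n_mod = rng.binomial(scov, beta)
                pct = 100.0 * n_mod / scov
                fh.write(
                    f"{locus.chrom}\t{start}\t{start + 1}\t{mod_code}\t{scov}\t{strand}"
                    f"\t{start}\t{start + 1}\t255,0,0\t{scov}\t{pct:.2f}"
                    f"\t{n_mod}\t{scov - n_mod}\t0\t0\t0\t0\t0\n"
                )
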