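"""Synthetic multi-stage transcriptome generator with planted truth.

The generator emulates the statistical structure of a stage-resolved bulk
RNA-seq study of flower development: a handful of whole-organ libraries
(one per stage, no replicates), log-normally distributed baseline expression,
a fraction of genes planted as stage-specific at a known fold, family-coherent
specificity (one designated family concentrated in one stage, as families
such as DUF1216 or DUF577 are in real flowers), length-biased negative-
binomial read counts so that RPKM — not raw counts — recovers the program,
and expression-dependent detectability on the orthogonal platforms (EST
libraries, genome tiling arrays, expression microarrays).

Randomness is drawn from one root seed via ``numpy.random.SeedSequence``
spawned in a fixed, documented order (annotation, programs, counts,
evidence), so each stage is individually reproducible and the whole run is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, TruthTable, ValidationError

_DEF_STAGES = ("Seedling", "IM", "F4", "F1-9", "F12", "Meiocyte")

#: Stream order for seed spawning; position in this tuple is the spawn index.
_STREAMS = ("annotation", "programs", "counts", "evidence")

_TF_FAMILIES = ("MADS", "MYB", "bHLH", "AP2", "NAC", "HB", "C2H2", "bZIP")


@dataclass
class SimulationConfig:
    """All knobs of the generator, with defaults describing the study design.

    Expression baselines are log-normal on the RPKM scale: ``ln(mean RPKM) ~
    Normal(baseline_log_mean, baseline_log_sd)``.  The default (4.0, 1.5)
    gives a median near 55 RPKM and a mean near 170, matching the
    tens-to-hundreds RPKM averages reported for detected floral genes.
    Counts are negative-binomial with ``var = mu + dispersion * mu**2``.
    """

    n_genes: int = 5000
    stages: tuple[str, ...] = _DEF_STAGES
    library_sizes: dict[str, int] | None = None  # default: 1e6 per stage
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.1
    specific_fraction: float = 0.05
    specific_fold: float = 8.0
    family_catalog: dict[str, int] = field(
        default_factory=lambda: {
            "DUF1216": 20,
            "DUF577": 30,
            "Oleosin": 20,
            "DUF220": 15,
            "PPR": 100,
            "F-box": 150,
        }
    )
    family_specific_bias: float = 0.9
    designated_family: str = "DUF1216"
    designated_stage: str = "F12"
    gene_type_props: dict[str, float] = field(
        default_factory=lambda: {"coding": 0.80, "transposon": 0.15, "pseudogene": 0.05}
    )
    # transposons/pseudogenes transcribe weakly; scales the baseline mean
    type_expression_scale: dict[str, float] = field(
        default_factory=lambda: {"coding": 1.0, "transposon": 0.02, "pseudogene": 0.05}
    )
    tf_fraction: float = 0.05
    length_log_median: float = 1500.0
    length_log_sd: float = 0.6
    min_length: int = 200
    est_detect_slope: float = 2.0
    est_detect_midpoint: float = 1.0  # log2(RPKM+1) at 50% EST detection
    probe_coverage: float = 0.9
    microarray_coverage: float = 0.7
    tiling_floor: float = 5.0
    tiling_gain: float = 0.5
    microarray_offset: float = 4.0
    microarray_gain: float = 1.0
    array_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if not self.stages or len(set(self.stages)) != len(self.stages):
            raise ValidationError("stages must be non-empty and unique")
        if self.library_sizes is None:
            self.library_sizes = {s: 1_000_000 for s in self.stages}
        if set(self.library_sizes) != set(self.stages):
            raise ValidationError("library_sizes keys must match stages")
        if any(n <= 0 for n in self.library_sizes.values()):
            raise ValidationError("library sizes must be positive")
        for frac_name in ("specific_fraction", "family_specific_bias", "probe_coverage",
                          "microarray_coverage", "tf_fraction"):
            frac = getattr(self, frac_name)
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{frac_name} must lie in [0, 1]")
        if self.specific_fold <= 1.0:
            raise ValidationError("specific_fold must exceed 1")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be non-negative")
        if sum(self.family_catalog.values()) > self.n_genes:
            raise ValidationError("family_catalog total exceeds n_genes")
        props = sum(self.gene_type_props.values())
        if abs(props - 1.0) > 1e-9:
            raise ValidationError("gene_type_props must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Generator for one named stream of the documented stream order."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS.index(stream)])


def simulate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Gene models: lengths, non-overlapping coordinates, types and families.

    Lengths are log-normal with median ``length_log_median`` (1.5 kb by
    default), truncated below at ``min_length`` by redrawing.  Genes are laid
    out in ID order along five chromosomes with random intergenic gaps, so
    adjacency in the table is adjacency on the chromosome (1-based inclusive
    coordinates).
    """
    rng = config.rng("annotation")
    n = config.n_genes

    lengths = np.exp(rng.normal(np.log(config.length_log_median), config.length_log_sd, n))
    for _ in range(100):
        short = lengths < config.min_length
        if not short.any():
            break
        lengths[short] = np.exp(
            rng.normal(np.log(config.length_log_median), config.length_log_sd, short.sum())
        )
    lengths = np.maximum(lengths, config.min_length).round().astype(np.int64)

    chroms = np.array([f"Chr{(i % 5) + 1}" for i in range(n)])
    order = np.argsort(chroms, kind="stable")
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    gaps = rng.integers(200, 2000, size=n)
    pos: dict[str, int] = {}
    for idx in order:
        cursor = pos.get(chroms[idx], 0)
        starts[idx] = cursor + gaps[idx]
        ends[idx] = starts[idx] + lengths[idx] - 1
        pos[chroms[idx]] = ends[idx]

    gene_ids = [f"AT{chroms[i][3:]}G{(i // 5 + 1) * 10:05d}" for i in range(n)]

    types = rng.choice(
        list(config.gene_type_props), size=n, p=list(config.gene_type_props.values())
    )

    families = np.array([""] * n, dtype=object)
    # families live on coding genes so detection structure is biological
    coding_idx = np.flatnonzero(types == "coding")
    pool = coding_idx if len(coding_idx) >= sum(config.family_catalog.values()) else np.arange(n)
    chosen = rng.choice(pool, size=sum(config.family_catalog.values()), replace=False)
    offset = 0
    for fam, size in config.family_catalog.items():
        families[chosen[offset:offset + size]] = fam
        offset += size

    tf_family = np.array([""] * n, dtype=object)
    n_tf = int(round(config.tf_fraction * n))
    if n_tf:
        tf_idx = rng.choice(np.flatnonzero(types == "coding"), size=min(n_tf, (types == "coding").sum()), replace=False)
        tf_family[tf_idx] = rng.choice(_TF_FAMILIES, size=len(tf_idx))

    return pd.DataFrame(
        {
            "length_bp": lengths,
            "chromosome": chroms,
            "start": starts,
            "end": ends,
            "gene_type": types,
            "families": families,
            "tf_family": tf_family,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def simulate_programs(annotation: pd.DataFrame, config: SimulationConfig) -> TruthTable:
    """Plant stage-specific expression programs on top of log-normal baselines.

    A ``specific_fraction`` of genes gets one stage whose true mean is exactly
    ``specific_fold`` times its mean everywhere else; additionally a
    ``family_specific_bias`` fraction of the designated family is forced into
    the designated stage, emulating family-coherent stage specificity.

    Transposons and pseudogenes are scaled down by ``type_expression_scale``
    — they are silenced in most tissues — EXCEPT when planted stage-specific:
    a stage-activated transposon (e.g. in meiocytes) transcribes at ordinary
    levels, so planted genes keep their full baseline.
    """
    rng = config.rng("programs")
    n = len(annotation)
    stages = list(config.stages)

    raw_baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, n))
    scale = annotation["gene_type"].map(config.type_expression_scale).fillna(1.0).to_numpy()
    baseline = raw_baseline * scale

    means = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(stages))),
        index=annotation.index,
        columns=stages,
    )
    specific_stage = pd.Series([None] * n, index=annotation.index, dtype=object)

    def plant(i: int, st: str) -> None:
        means.iloc[i] = raw_baseline[i]
        means.iloc[i, means.columns.get_loc(st)] = raw_baseline[i] * config.specific_fold
        specific_stage.iloc[i] = st

    n_specific = int(round(config.specific_fraction * n))
    if n_specific:
        planted = rng.choice(n, size=n_specific, replace=False)
        planted_stages = rng.choice(stages, size=n_specific)
        for i, st in zip(planted, planted_stages):
            plant(i, st)

    if config.family_specific_bias > 0 and config.designated_family:
        fam_mask = annotation["families"].astype(str).str.split(";").apply(
            lambda fs: config.designated_family in fs
        )
        members = np.flatnonzero(fam_mask.to_numpy())
        n_bias = int(round(config.family_specific_bias * len(members)))
        if n_bias:
            forced = rng.choice(members, size=n_bias, replace=False)
            for i in forced:
                plant(i, config.designated_stage)

    return TruthTable(means=means, specific_stage=specific_stage)


def simulate_counts(
    truth: TruthTable, annotation: pd.DataFrame, config: SimulationConfig
) -> CountMatrix:
    """Length-biased negative-binomial counts from the true programs.

    Expected count for gene g in stage s is ``mean_gs * (L_g / 1e3) *
    (N_s / 1e6)`` — i.e. the RPKM identity inverted — with NB noise of
    variance ``mu + dispersion * mu**2`` (gamma-Poisson mixture; the
    dispersion -> 0 limit is Poisson).
    """
    rng = config.rng("counts")
    lengths_kb = annotation.loc[truth.genes, "length_bp"].to_numpy() / 1e3
    counts = {}
    for stage in truth.stages:
        lib = config.library_sizes[stage]
        mu = truth.means[stage].to_numpy() * lengths_kb * (lib / 1e6)
        if config.dispersion > 0:
            lam = np.where(
                mu > 0,
                rng.gamma(1.0 / config.dispersion, config.dispersion * np.maximum(mu, 1e-300)),
                0.0,
            )
        else:
            lam = mu
        counts[stage] = rng.poisson(lam)
    frame = pd.DataFrame(counts, index=truth.genes)
    libs = pd.Series(config.library_sizes).reindex(frame.columns)
    # guard against simulated totals exceeding the nominal library
    libs = np.maximum(libs, frame.sum(axis=0))
    return CountMatrix(counts=frame, library_sizes=libs.astype(np.int64))


def simulate_platform_evidence(
    truth: TruthTable, annotation: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Per-gene detection evidence on EST, tiling-array and microarray.

    EST support is Bernoulli with a logistic probability in log2 expression
    (steeper ``est_detect_slope`` -> sharper detection limit).  Tiling
    intensity is affine in log2 expression with Gaussian noise, floored at the
    array background; microarray intensity likewise but only for the probed
    fraction of genes.
    """
    rng = config.rng("evidence")
    expr = truth.means.mean(axis=1).to_numpy()  # flower-wide true mean, RPKM
    log_expr = np.log2(expr + 1.0)

    logit = config.est_detect_slope * (log_expr - config.est_detect_midpoint)
    p_est = 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))
    est = rng.random(len(expr)) < p_est

    probe = rng.random(len(expr)) < config.probe_coverage
    tiling = config.tiling_floor + config.tiling_gain * log_expr + rng.normal(
        0.0, config.array_noise_sd, len(expr)
    )
    tiling = np.maximum(tiling, config.tiling_floor)
    tiling = np.where(probe, tiling, np.nan)

    ma_probe = rng.random(len(expr)) < config.microarray_coverage
    ma = config.microarray_offset + config.microarray_gain * log_expr + rng.normal(
        0.0, config.array_noise_sd, len(expr)
    )
    ma = np.where(ma_probe, np.maximum(ma, config.microarray_offset), np.nan)

    return pd.DataFrame(
        {
            "est_supported": est,
            "probe_present": probe,
            "tiling_intensity": tiling,
            "microarray_intensity": ma,
            "gene_type": annotation.loc[truth.genes, "gene_type"].to_numpy(),
        },
        index=truth.genes,
    )


def simulate_all(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TruthTable, CountMatrix, pd.DataFrame]:
    """Run the four stages in stream order; convenience for pipelines/tests."""
    annotation = simulate_annotation(config)
    truth = simulate_programs(annotation, config)
    counts = simulate_counts(truth, annotation, config)
    evidence = simulate_platform_evidence(truth, annotation, config)
    return annotation, truth, counts, evidence
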