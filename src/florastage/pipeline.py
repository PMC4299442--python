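"""End-to-end orchestration: quantify -> differential -> specificity ->
consensus -> enrichment, with a machine-readable JSON summary.

The pipeline reads the TSV artifacts defined in :mod:`florastage.io`, runs
every analysis stage with the configured thresholds (defaults: 10-read
expressed threshold, Fisher alpha 0.01, microarray background 5.0 log2,
fold levels 1/2/4/8, pseudocount 1 RPKM) and writes each stage's table plus
a summary mirroring the study's headline tables: expressed genes per stage,
pairwise DEG counts, stage-specific counts per fold level, consensus totals
and the top enriched families.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datatypes import CountMatrix, ValidationError
from . import consensus as cns
from . import differential as diff
from . import enrichment as enr
from . import io as fio
from . import quantify as qt
from . import specificity as spec

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run; defaults are the study's."""

    counts: str = "counts.tsv"
    annotation: str = "annotation.tsv"
    evidence: str | None = "evidence.tsv"
    outdir: str = "florastage_out"
    min_reads: int = 10
    alpha: float = 0.01
    microarray_background: float = 5.0
    fold_levels: tuple[float, ...] = (1, 2, 4, 8)
    pseudocount: float = 1.0
    stage_order: tuple[str, ...] | None = None
    enrichment_set_stage: str | None = None  # stage whose 4-fold set is tested
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValidationError("min_reads must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fold_levels", "stage_order"):
            if key in known and known[key] is not None:
                known[key] = tuple(known[key])
        return cls(**known)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the summary dict.

    Any stage failure aborts with the stage name and cause.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
    }

    stage = "load"
    try:
        counts = fio.read_counts(config.counts)
        annotation = fio.read_annotation(config.annotation)
        counts = _align_counts(counts, annotation)
        if config.stage_order:
            missing = set(config.stage_order) - set(counts.samples)
            if missing:
                raise ValidationError(f"declared stages not in counts: {sorted(missing)}")
            counts = CountMatrix(
                counts=counts.counts[list(config.stage_order)],
                library_sizes=counts.library_sizes[list(config.stage_order)],
            )

        stage = "quantify"
        expr = qt.rpkm(counts, annotation)
        log_expr = qt.log2_transform(expr, config.pseudocount)
        fio.write_matrix(expr.values, outdir / "rpkm.tsv")
        expressed = qt.call_expressed(counts, config.min_reads)
        summary["expressed_per_sample"] = {
            s: len(g) for s, g in expressed.per_sample.items()
        }
        summary["expressed_union"] = len(expressed.union)
        fio.write_gene_set(expressed.union, outdir / "expressed_union.txt")

        stage = "differential"
        samples = counts.samples
        deg_counts: dict[str, dict[str, int]] = {}
        deg_frames = []
        for i, a in enumerate(samples):
            for b in samples[i + 1:]:
                table = diff.deg_table(counts, annotation, (a, b), config.alpha,
                                       pseudocount=config.pseudocount)
                deg_frames.append(table)
                sub = table[table["is_deg"]]
                deg_counts.setdefault(a, {})[b] = int((sub["direction"] == "up_in_a").sum())
                deg_counts.setdefault(b, {})[a] = int((sub["direction"] == "up_in_b").sum())
        pd.concat(deg_frames).to_csv(outdir / "deg.tsv", sep="\t", index_label="gene_id")
        summary["deg_counts"] = deg_counts
        ss_table = diff.stage_specific_table(counts, annotation, config.fold_levels,
                                             config.alpha, config.pseudocount)
        ss_table.to_csv(outdir / "stage_specific.tsv", sep="\t")
        summary["stage_specific"] = {
            str(f): {s: int(ss_table.loc[f, s]) for s in ss_table.columns}
            for f in ss_table.index
        }

        stage = "specificity"
        z = spec.zscores(log_expr)
        fio.write_matrix(z.z, outdir / "zscores.tsv")
        summary["degenerate_z_genes"] = int(z.degenerate.sum())

        stage = "consensus"
        if config.evidence:
            evidence = fio.read_evidence(config.evidence)
            rnaseq_set = expressed.union
            est_set = set(evidence.index[evidence["est_supported"]])
            bg = cns.tiling_background(evidence, rnaseq_set, est_set)
            tiling_set = cns.call_tiling_expressed(evidence, bg.threshold)
            venn = cns.platform_venn(rnaseq_set, est_set, tiling_set)
            reliable = cns.reliable_expressed_count(venn)
            summary["consensus"] = {
                "tiling_threshold": bg.threshold,
                "tiling_specific": len(bg.specific_genes),
                "tiling_specific_breakdown": {
                    "transposon": bg.n_transposon,
                    "pseudogene": bg.n_pseudogene,
                    "other": bg.n_other,
                },
                "venn": venn.counts(),
                "reliable_any_two": reliable.any_two,
                "reliable_rnaseq_anchored": reliable.rnaseq_anchored,
            }
            pd.Series(venn.counts()).to_csv(outdir / "venn.tsv", sep="\t",
                                            header=["count"], index_label="region")
            (outdir / "consensus.txt").write_text(
                f"reliable_any_two\t{reliable.any_two}\n"
                f"reliable_rnaseq_anchored\t{reliable.rnaseq_anchored}\n"
            )

        stage = "enrichment"
        target_stage = config.enrichment_set_stage or samples[-1]
        spec_set = diff.stage_specific(counts, annotation, target_stage, 4.0,
                                       config.alpha, config.pseudocount)
        universe = set(counts.genes)
        table = enr.family_enrichment(spec_set, universe, annotation) if spec_set else None
        if table is not None:
            table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            summary["top_families"] = table.head(5)[["family", "p_value"]].to_dict("records")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _align_counts(counts: CountMatrix, annotation: pd.DataFrame) -> CountMatrix:
    """Add annotated-but-uncounted genes as zero rows so set algebra is total."""
    missing = annotation.index.difference(counts.genes)
    if len(missing) == 0:
        return counts
    logger.warning("adding %d annotated genes as zero-count rows", len(missing))
    zeros = pd.DataFrame(0, index=missing, columns=counts.samples)
    frame = pd.concat([counts.counts, zeros]).loc[annotation.index]
    return CountMatrix(counts=frame, library_sizes=counts.library_sizes)
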