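"""Core in-memory containers shared across the pipeline.

Matrices are thin, validated wrappers around :class:`pandas.DataFrame` so that
every stage of the pipeline speaks the same dialect: genes on the rows
(ordered, unique identifiers treated as opaque strings), samples/stages on the
columns.  Gene annotations and platform evidence stay as plain DataFrames with
a documented column contract (see :data:`ANNOTATION_COLUMNS` and
:data:`EVIDENCE_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column contract for annotation tables (index: gene_id).
ANNOTATION_COLUMNS = (
    "length_bp",
    "chromosome",
    "start",
    "end",
    "gene_type",
    "families",
    "tf_family",
)

#: Column contract for platform-evidence tables (index: gene_id).
EVIDENCE_COLUMNS = (
    "est_supported",
    "probe_present",
    "tiling_intensity",
    "microarray_intensity",
    "gene_type",
)

GENE_TYPES = ("coding", "transposon", "pseudogene")


class ValidationError(ValueError):
    """Raised when an input table violates its documented contract."""


@dataclass
class CountMatrix:
    """Raw uniquely-mapped read counts per gene and sample.

    Parameters
    ----------
    counts
        Integer gene x sample matrix; index = gene IDs (unique), columns =
        sample names.
    library_sizes
        Total mapped reads per sample (the ``N`` of the RPKM formula).  When
        omitted, column sums are used.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = pd.Series(self.library_sizes).reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                missing = self.library_sizes.index[self.library_sizes.isna()].tolist()
                raise ValidationError(f"library sizes missing for samples: {missing}")
            if (self.library_sizes <= 0).any():
                raise ValidationError("library sizes must be positive")
            too_big = self.counts.sum(axis=0) > self.library_sizes
            if too_big.any():
                bad = too_big.index[too_big].tolist()
                raise ValidationError(
                    f"per-sample count totals exceed library sizes for: {bad}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ExpressionMatrix:
    """Normalized expression values: RPKM or log2(RPKM + pseudocount).

    ``scale`` distinguishes the two; operations that require one scale refuse
    the other rather than silently double-transforming.
    """

    values: pd.DataFrame
    scale: str = "rpkm"

    def __post_init__(self) -> None:
        if self.scale not in ("rpkm", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.scale == "rpkm" and (self.values.to_numpy() < 0).any():
            raise ValidationError("RPKM values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check the annotation column contract and basic coordinate sanity."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValidationError(f"annotation missing columns: {missing}")
    if annotation.index.has_duplicates:
        raise ValidationError("annotation has duplicate gene IDs")
    if (annotation["length_bp"] < 1).any():
        raise ValidationError("gene lengths must be >= 1 bp")
    if (annotation["start"] > annotation["end"]).any():
        raise ValidationError("gene start must not exceed end")
    return annotation


def family_map(annotation: pd.DataFrame) -> dict[str, list[str]]:
    """Family name -> member gene IDs.

    A gene carrying several domain families (``families`` holds a
    ``;``-separated list) is counted once in each family's member list.
    """
    out: dict[str, list[str]] = {}
    for gene_id, fams in annotation["families"].items():
        if not fams or (isinstance(fams, float) and np.isnan(fams)):
            continue
        for fam in str(fams).split(";"):
            fam = fam.strip()
            if fam:
                out.setdefault(fam, []).append(gene_id)
    return out


@dataclass
class TruthTable:
    """Planted ground truth emitted by the simulator.

    ``means`` holds each gene's true expression program (RPKM scale) per
    stage; ``specific_stage`` is the planted stage name (or ``None``) and
    satisfies ``means[stage] == specific_fold * means[other]`` exactly for
    planted genes.
    """

    means: pd.DataFrame
    specific_stage: pd.Series = field(default_factory=pd.Series)

    @property
    def genes(self) -> pd.Index:
        return self.means.index

    @property
    def stages(self) -> list[str]:
        return list(self.means.columns)

    def planted_genes(self) -> pd.Index:
        return self.specific_stage.dropna().index
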