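"""Count normalization and expressed-gene calling.

RPKM (reads per kilobase of transcript per million mapped reads) is computed
as ``1e9 * C / (N * L)`` where ``C`` is the uniquely mapped read count of a
gene, ``L`` the cDNA length of its longest splice variant in bp, and ``N``
the total mapped reads of the library.  A gene is called expressed in a
sample when at least ``min_reads`` (default 10) reads map to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


def rpkm(counts: CountMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Depth- and length-normalize raw counts to RPKM.

    Every counted gene must have an annotated length; genes present in the
    annotation but missing from the count matrix are treated as count 0
    downstream and logged here for visibility.

    Raises
    ------
    ValidationError
        If any counted gene lacks a gene model or a library size is zero.
    """
    missing = counts.genes.difference(annotation.index)
    if len(missing):
        raise ValidationError(
            f"no gene model (length) for {len(missing)} genes: "
            f"{sorted(missing)[:10]}{'...' if len(missing) > 10 else ''}"
        )
    uncounted = annotation.index.difference(counts.genes)
    if len(uncounted):
        logger.warning(
            "%d annotated genes absent from count matrix (treated as count 0): %s%s",
            len(uncounted), sorted(uncounted)[:5], "..." if len(uncounted) > 5 else "",
        )
    lengths = annotation.loc[counts.genes, "length_bp"].to_numpy(dtype=float)
    libs = counts.library_sizes.to_numpy(dtype=float)
    if (libs <= 0).any():
        raise ValidationError("library sizes must be positive")
    values = 1e9 * counts.counts.to_numpy(dtype=float) / (libs[None, :] * lengths[:, None])
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=counts.genes, columns=counts.samples),
        scale="rpkm",
    )


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """``log2(RPKM + pseudocount)``; refuses an already-log2 matrix."""
    if expr.scale != "rpkm":
        raise ValidationError("log2_transform expects an rpkm-scale matrix")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return ExpressionMatrix(values=np.log2(expr.values + pseudocount), scale="log2")


@dataclass
class ExpressedSets:
    """Expressed-gene calls per sample plus their union across samples."""

    per_sample: dict[str, set[str]]
    union: set[str]
    min_reads: int


def call_expressed(counts: CountMatrix, min_reads: int = 10) -> ExpressedSets:
    """Call genes expressed by the read-count threshold, per sample and union.

    The union is the organ-wide expressed set: a gene counts as florally
    expressed if it passes the threshold in any stage.
    """
    if min_reads < 1:
        raise ValidationError("min_reads must be >= 1")
    per_sample = {
        sample: set(counts.genes[counts.counts[sample] >= min_reads])
        for sample in counts.samples
    }
    union: set[str] = set().union(*per_sample.values()) if per_sample else set()
    return ExpressedSets(per_sample=per_sample, union=union, min_reads=min_reads)
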