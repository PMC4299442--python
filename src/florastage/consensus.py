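"""Cross-platform expressed-gene triangulation.

Three orthogonal detection technologies are combined: RNA-seq (read-count
threshold), EST libraries (a gene is supported when at least one EST maps to
it) and genome tiling arrays (intensity above a background threshold).  The
tiling background is derived from the data itself: genes with a tiling probe
but no EST or RNA-seq support are mostly silent DNA (transposons,
pseudogenes, very low expressors), so the mean tiling intensity over that
platform-specific set serves as the expressed/unexpressed threshold.
Expression microarrays use a fixed log2 background instead.  The three
detected sets are partitioned into the seven Venn regions, and the
reliably-expressed consensus is the set of genes seen by at least two
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ValidationError


@dataclass
class TilingBackground:
    """Derived tiling threshold plus the platform-specific set behind it."""

    threshold: float
    specific_genes: set[str]
    n_transposon: int
    n_pseudogene: int
    n_other: int


def tiling_background(
    evidence: pd.DataFrame, rnaseq_set: set[str], est_set: set[str]
) -> TilingBackground:
    """Derive the tiling expressed/unexpressed threshold from the data.

    The platform-specific set is every probe-present gene absent from both
    the RNA-seq and EST detected sets; the threshold is its mean tiling
    intensity.  The gene-type breakdown (transposons / pseudogenes / other)
    is reported because it justifies treating the set as background.
    """
    if evidence.empty:
        raise ValidationError("empty evidence table")
    probed = evidence.index[evidence["probe_present"].astype(bool)]
    specific = [g for g in probed if g not in rnaseq_set and g not in est_set]
    if not specific:
        raise ValidationError("no tiling-specific genes; threshold undefined")
    sub = evidence.loc[specific]
    threshold = float(sub["tiling_intensity"].mean())
    types = sub["gene_type"].astype(str)
    n_t = int((types == "transposon").sum())
    n_p = int((types == "pseudogene").sum())
    return TilingBackground(
        threshold=threshold,
        specific_genes=set(specific),
        n_transposon=n_t,
        n_pseudogene=n_p,
        n_other=len(specific) - n_t - n_p,
    )


def call_tiling_expressed(evidence: pd.DataFrame, threshold: float) -> set[str]:
    """Probe-present genes with tiling intensity strictly above threshold."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    mask = evidence["probe_present"].astype(bool) & (
        evidence["tiling_intensity"] > threshold
    )
    return set(evidence.index[mask.fillna(False)])


def call_microarray_expressed(evidence: pd.DataFrame, background: float = 5.0) -> set[str]:
    """Probed genes with microarray intensity strictly above the log2 background."""
    mask = evidence["microarray_intensity"] > background
    return set(evidence.index[mask.fillna(False)])


#: Region keys of the 3-set Venn partition, in report order.
VENN_REGIONS = (
    "rnaseq_only",
    "est_only",
    "tiling_only",
    "rnaseq_est",
    "rnaseq_tiling",
    "est_tiling",
    "all_three",
)


@dataclass
class VennPartition:
    """The 7 disjoint regions of the RNA-seq / EST / tiling Venn diagram."""

    regions: dict[str, set[str]]
    reliable_set: set[str]

    def counts(self) -> dict[str, int]:
        return {k: len(self.regions[k]) for k in VENN_REGIONS}

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())


def platform_venn(rnaseq: set[str], est: set[str], tiling: set[str]) -> VennPartition:
    """Partition genes detected by any platform into the 7 Venn regions.

    ``reliable_set`` is membership in at least two of the three platforms.
    """
    r, e, t = set(rnaseq), set(est), set(tiling)
    regions = {
        "rnaseq_only": r - e - t,
        "est_only": e - r - t,
        "tiling_only": t - r - e,
        "rnaseq_est": (r & e) - t,
        "rnaseq_tiling": (r & t) - e,
        "est_tiling": (e & t) - r,
        "all_three": r & e & t,
    }
    reliable = (
        regions["all_three"]
        | regions["rnaseq_est"]
        | regions["rnaseq_tiling"]
        | regions["est_tiling"]
    )
    return VennPartition(regions=regions, reliable_set=reliable)


@dataclass
class ReliableCount:
    """Consensus expressed-gene totals under the two conventions.

    ``any_two`` counts genes on >= 2 platforms (the general rule);
    ``rnaseq_anchored`` counts only the triple region plus the two RNA-seq
    pairwise regions — i.e. RNA-seq detection corroborated by at least one
    other platform — which is the arithmetic used for headline totals.
    """

    any_two: int
    rnaseq_anchored: int


def reliable_expressed_count(venn: VennPartition) -> ReliableCount:
    """Count reliably-expressed genes from a Venn partition."""
    c = venn.counts()
    anchored = c["all_three"] + c["rnaseq_est"] + c["rnaseq_tiling"]
    return ReliableCount(any_two=anchored + c["est_tiling"], rnaseq_anchored=anchored)
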