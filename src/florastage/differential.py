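"""Pairwise differential expression and stage-specific gene detection.

The design has one library per stage (no replicates), so differential calls
between two stages use Fisher's exact test on the 2x2 table of a gene's
counts against the remainder of each library:

    [[count_a, lib_a - count_a],
     [count_b, lib_b - count_b]]

with the conventional two-sided P (sum of probabilities of all tables, at the
observed margins, no more likely than the observed one).  A gene is a DEG at
``alpha`` (default 0.01, uncorrected) and optionally a minimum RPKM fold
change.  Stage-specific genes are those whose RPKM fold change over EVERY
other stage exceeds a threshold AND whose pairwise test against every other
stage is significant.  Fisher's exact test treats each library as a simple
binomial draw; with overdispersed counts it is anticonservative — see the
methods note for the measured behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

FOLD_LEVELS = (1, 2, 4, 8)


def fisher_deg(count_a: int, count_b: int, lib_a: int, lib_b: int) -> float:
    """Two-sided Fisher's exact P for one gene between two libraries."""
    if not (0 <= count_a <= lib_a and 0 <= count_b <= lib_b):
        raise ValidationError("counts must lie in [0, library size]")
    table = [[count_a, lib_a - count_a], [count_b, lib_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def fold_change(rpkm_a: float, rpkm_b: float, pseudocount: float = 1.0) -> float:
    """Pseudocounted RPKM ratio ``(a + pc) / (b + pc)``; finite for zeros."""
    if rpkm_a < 0 or rpkm_b < 0:
        raise ValidationError("RPKM inputs must be non-negative")
    return (rpkm_a + pseudocount) / (rpkm_b + pseudocount)


def deg_table(
    counts: CountMatrix,
    annotation: pd.DataFrame,
    pair: tuple[str, str],
    alpha: float = 0.01,
    min_fold: float = 1.0,
    pseudocount: float = 1.0,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-gene Fisher tests and RPKM fold changes for one sample pair.

    Returns a DataFrame with columns ``sample_a, sample_b, count_a, count_b,
    p_value, log2_fold_change, direction, is_deg``.  ``direction`` is
    ``up_in_a``/``up_in_b`` by the sign of the fold change, ``none`` for
    exact ties.  Swapping the pair flips directions and leaves P unchanged.
    DEG status uses the raw P by default; ``bh_correct=True`` adds a
    ``q_value`` column and gates ``is_deg`` on it instead.
    """
    from .quantify import rpkm as _rpkm

    a, b = pair
    for s in pair:
        if s not in counts.samples:
            raise ValidationError(f"sample {s!r} not in count matrix")
    ca = counts.counts[a].to_numpy()
    cb = counts.counts[b].to_numpy()
    la = int(counts.library_sizes[a])
    lb = int(counts.library_sizes[b])

    pvals = _fisher_vector(ca, cb, la, lb)

    expr = _rpkm(counts, annotation).values
    lfc = np.log2((expr[a].to_numpy() + pseudocount) / (expr[b].to_numpy() + pseudocount))
    direction = np.where(lfc > 0, "up_in_a", np.where(lfc < 0, "up_in_b", "none"))
    crit = benjamini_hochberg(pvals) if bh_correct else pvals
    is_deg = (crit < alpha) & (np.abs(lfc) >= np.log2(min_fold))

    out = pd.DataFrame(
        {
            "sample_a": a,
            "sample_b": b,
            "count_a": ca,
            "count_b": cb,
            "p_value": pvals,
            "log2_fold_change": lfc,
            "direction": direction,
            "is_deg": is_deg,
        },
        index=counts.genes,
    )
    if bh_correct:
        out.insert(5, "q_value", crit)
    return out


def _fisher_vector(ca: np.ndarray, cb: np.ndarray, la: int, lb: int) -> np.ndarray:
    """Fisher P for many genes against fixed library sizes, de-duplicated.

    Distinct (count_a, count_b) pairs are far fewer than genes, so compute
    each table once.
    """
    pairs = np.stack([ca, cb], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    pcache = np.empty(len(uniq))
    for i, (x, y) in enumerate(uniq):
        pcache[i] = stats.fisher_exact(
            [[int(x), la - int(x)], [int(y), lb - int(y)]], alternative="two-sided"
        )[1]
    return pcache[inverse]


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values; offered behind a flag, off by default."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def stage_specific(
    counts: CountMatrix,
    annotation: pd.DataFrame,
    stage: str,
    fold: float = 4.0,
    alpha: float = 0.01,
    pseudocount: float = 1.0,
    require_significance: bool = True,
) -> set[str]:
    """Genes specifically expressed in one stage over all others.

    A gene qualifies when its pseudocounted RPKM fold change over EVERY other
    stage is strictly greater than ``fold`` and (by default) its pairwise
    Fisher test against every other stage is significant at ``alpha``.
    ``require_significance=False`` gives the fold-only variant for
    sensitivity analysis.
    """
    from .quantify import rpkm as _rpkm

    if stage not in counts.samples:
        raise ValidationError(f"unknown stage {stage!r}")
    if fold < 1:
        raise ValidationError("fold must be >= 1")

    expr = _rpkm(counts, annotation).values
    target = expr[stage].to_numpy() + pseudocount
    keep = np.ones(len(counts.genes), dtype=bool)
    for other in counts.samples:
        if other == stage:
            continue
        ratio = target / (expr[other].to_numpy() + pseudocount)
        keep &= ratio > fold
        if not keep.any():
            return set()
    if require_significance:
        la = int(counts.library_sizes[stage])
        ca = counts.counts[stage].to_numpy()
        for other in counts.samples:
            if other == stage:
                continue
            idx = np.flatnonzero(keep)
            cb = counts.counts[other].to_numpy()
            lb = int(counts.library_sizes[other])
            pv = _fisher_vector(ca[idx], cb[idx], la, lb)
            keep[idx] &= pv < alpha
            if not keep.any():
                return set()
    return set(counts.genes[keep])


def stage_specific_table(
    counts: CountMatrix,
    annotation: pd.DataFrame,
    folds: tuple[float, ...] = FOLD_LEVELS,
    alpha: float = 0.01,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Stage-specific gene counts per stage at each fold level.

    Rows are fold thresholds, columns stages; entries are numbers of genes
    specific to that stage at that fold.  Columns are monotone non-increasing
    down the rows because the fold condition is nested.
    """
    records = {}
    for stage in counts.samples:
        sets = {f: stage_specific(counts, annotation, stage, f, alpha, pseudocount)
                for f in folds}
        records[stage] = {f: len(sets[f]) for f in folds}
    out = pd.DataFrame(records)
    out.index.name = "fold"
    return out


@dataclass
class MaxStageGroups:
    """Partition of genes by stage of maximal expression (the D1/D2/D3-style
    grouping), plus the genes whose maximum was tied across stages."""

    groups: dict[str, set[str]]
    ties: set[str]


def max_stage_groups(
    expr: ExpressionMatrix, genes: set[str] | None = None
) -> MaxStageGroups:
    """Assign each gene to the sample of its maximal expression.

    Exact ties go to the earliest sample in the matrix's declared column
    order; tied genes are recorded and logged.  The groups partition the
    input genes.
    """
    values = expr.values if genes is None else expr.values.loc[sorted(genes)]
    missing = set() if genes is None else set(genes) - set(expr.genes)
    if missing:
        raise ValidationError(f"genes absent from matrix: {sorted(missing)[:10]}")
    arr = values.to_numpy()
    winner = arr.argmax(axis=1)  # argmax takes the first maximum: earliest stage
    n_max = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1)
    ties = set(values.index[n_max > 1])
    if ties:
        logger.warning("max-stage ties broken by stage order for %d genes: %s%s",
                       len(ties), sorted(ties)[:5], "..." if len(ties) > 5 else "")
    groups: dict[str, set[str]] = {s: set() for s in expr.samples}
    for gene, w in zip(values.index, winner):
        groups[expr.samples[w]].add(gene)
    return MaxStageGroups(groups=groups, ties=ties)
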