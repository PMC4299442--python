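"""Gene-family detection tables, enrichment tests and tandem-array detection.

Families are Pfam-style domain labels attached to genes (a gene may carry
several; it then counts once in each family).  Detection tables report, per
family, how many annotated members fall in a gene set and the fraction of
the family that does; enrichment adds a two-sided Fisher's exact P against a
stated universe.  Tandem arrays — runs of same-family genes adjacent on a
chromosome, the signature of tandem duplication — are detected by scanning
genes in coordinate order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError, family_map


def _round_half_up(x: float, digits: int = 2) -> float:
    """Round-half-up, matching how printed fraction columns are rounded."""
    factor = 10 ** digits
    return np.floor(x * factor + 0.5) / factor


def family_detection_table(
    gene_set: set[str],
    annotation: pd.DataFrame,
    min_percent: float = 0.0,
    min_total: int = 1,
) -> pd.DataFrame:
    """Per-family membership counts and fractions within a gene set.

    Columns: ``family, total, in_set, percent`` where ``total`` is the
    family's annotated size (independent of the gene set), ``in_set`` the
    members found in the set and ``percent = round(in_set/total, 2)``
    (half-up).  Rows with ``total < min_total`` or ``percent < min_percent``
    are dropped; remaining rows sort by percent descending, then family name.
    """
    fams = family_map(annotation)
    gene_set = set(gene_set)
    rows = []
    for fam, members in fams.items():
        total = len(members)
        in_set = sum(1 for g in members if g in gene_set)
        percent = _round_half_up(in_set / total) if total else 0.0
        rows.append((fam, total, in_set, percent))
    out = pd.DataFrame(rows, columns=["family", "total", "in_set", "percent"])
    out = out[(out["total"] >= min_total) & (out["percent"] >= min_percent)]
    out = out.sort_values(["percent", "family"], ascending=[False, True])
    return out.reset_index(drop=True)


def family_enrichment(
    gene_set: set[str],
    universe: set[str],
    annotation: pd.DataFrame,
    min_total: int = 1,
) -> pd.DataFrame:
    """Fisher's exact family enrichment of a gene set within a universe.

    For each family the 2x2 table is [[members in set, non-members in set],
    [members outside set, non-members outside set]], restricted to the
    universe; P is two-sided.  The universe is an explicit parameter (e.g.
    all annotated genes) — there is no hidden default population.  Rows sort
    by P ascending.
    """
    gene_set, universe = set(gene_set), set(universe)
    if not gene_set <= universe:
        raise ValidationError("gene_set must be a subset of universe")
    fams = family_map(annotation)
    n_set = len(gene_set)
    n_uni = len(universe)
    rows = []
    for fam, members in fams.items():
        members_u = [g for g in members if g in universe]
        total = len(members_u)
        if total < min_total or total == 0:
            continue
        in_set = sum(1 for g in members_u if g in gene_set)
        table = [
            [in_set, n_set - in_set],
            [total - in_set, n_uni - n_set - (total - in_set)],
        ]
        if min(min(row) for row in table) < 0:
            raise ValidationError(f"inconsistent inputs for family {fam}: {table}")
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append((fam, total, in_set, _round_half_up(in_set / total), p))
    out = pd.DataFrame(rows, columns=["family", "total", "in_set", "percent", "p_value"])
    return out.sort_values(["p_value", "family"]).reset_index(drop=True)


def set_overlap_test(
    set_a: set[str], set_b: set[str], universe_size: int
) -> tuple[int, float]:
    """Overlap of two gene sets and its two-sided Fisher significance.

    The universe size must cover the union; the 2x2 table classifies each of
    the ``universe_size`` genes by membership in A and in B.
    """
    set_a, set_b = set(set_a), set(set_b)
    union = len(set_a | set_b)
    if universe_size < union:
        raise ValidationError(
            f"universe ({universe_size}) smaller than union ({union})"
        )
    overlap = len(set_a & set_b)
    table = [
        [overlap, len(set_a) - overlap],
        [len(set_b) - overlap, universe_size - union],
    ]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return overlap, p


@dataclass
class TandemArray:
    """A maximal run of same-family genes adjacent on one chromosome."""

    family: str
    chromosome: str
    members: list[str]
    span: tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.members)


def detect_tandem_arrays(
    annotation: pd.DataFrame,
    family: str,
    max_intervening: int = 1,
    max_distance_bp: int | None = None,
) -> list[TandemArray]:
    """Detect tandem arrays of one family by scanning each chromosome.

    Genes are sorted by start coordinate per chromosome.  Two consecutive
    family members extend the same array when at most ``max_intervening``
    non-family genes lie between them and (if ``max_distance_bp`` is set)
    their starts are within that distance.  Arrays of >= 2 members are
    reported with their genomic span; arrays are disjoint and maximal.
    """
    members = set(family_map(annotation).get(family, []))
    if not members:
        return []
    arrays: list[TandemArray] = []
    for chrom, sub in annotation.groupby("chromosome", sort=True):
        ordered = sub.sort_values("start")
        run: list[str] = []
        gap = 0
        last_start = None
        for gene_id, row in ordered.iterrows():
            if gene_id in members:
                too_far = (
                    max_distance_bp is not None
                    and last_start is not None
                    and row["start"] - last_start > max_distance_bp
                )
                if run and gap <= max_intervening and not too_far:
                    run.append(gene_id)
                else:
                    if len(run) >= 2:
                        arrays.append(_make_array(family, chrom, run, annotation))
                    run = [gene_id]
                gap = 0
                last_start = row["start"]
            else:
                gap += 1
        if len(run) >= 2:
            arrays.append(_make_array(family, chrom, run, annotation))
    return arrays


def _make_array(
    family: str, chrom: str, run: list[str], annotation: pd.DataFrame
) -> TandemArray:
    sub = annotation.loc[run]
    return TandemArray(
        family=family,
        chromosome=str(chrom),
        members=list(run),
        span=(int(sub["start"].min()), int(sub["end"].max())),
    )
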