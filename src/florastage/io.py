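"""Readers and writers for the pipeline's tab-separated artifacts.

All tables are UTF-8 TSV with a header row and no quoting; gene IDs are
opaque strings in the first column.  Count files may carry an optional
``#library_sizes`` line immediately after the header giving per-sample
totals; without it, column sums are used.  Every writer's output parses back
through its reader (round-trip property).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ANNOTATION_COLUMNS,
    EVIDENCE_COLUMNS,
    CountMatrix,
    TruthTable,
    ValidationError,
    validate_annotation,
)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV into a validated :class:`CountMatrix`.

    Raises :class:`ValidationError` naming the offending line for ragged
    rows, non-integer cells or duplicate gene IDs.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        lib_sizes = None
        rows: list[list[str]] = []
        ids: list[str] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "#library_sizes":
                lib_sizes = _parse_int_row(parts[1:], samples, lineno, path)
                continue
            if len(parts) != len(samples) + 1:
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(samples) + 1} columns, got {len(parts)}"
                )
            ids.append(parts[0])
            rows.append(_parse_int_row(parts[1:], samples, lineno, path))
    seen: set[str] = set()
    for g in ids:
        if g in seen:
            raise ValidationError(f"{path}: duplicate gene ID {g!r}")
        seen.add(g)
    counts = pd.DataFrame(rows, index=pd.Index(ids, name="gene_id"), columns=samples,
                          dtype=np.int64)
    libs = pd.Series(lib_sizes, index=samples) if lib_sizes is not None else None
    return CountMatrix(counts=counts, library_sizes=libs)


def _parse_int_row(cells: list[str], samples: list[str], lineno: int, path: Path) -> list[int]:
    out = []
    for sample, cell in zip(samples, cells):
        try:
            out.append(int(cell))
        except ValueError:
            raise ValidationError(
                f"{path}:{lineno}: non-integer value {cell!r} in column {sample!r}"
            ) from None
    return out


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(counts.samples) + "\n")
        fh.write(
            "#library_sizes\t"
            + "\t".join(str(int(counts.library_sizes[s])) for s in counts.samples)
            + "\n"
        )
        for gene, row in counts.counts.iterrows():
            fh.write(gene + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False,
                        dtype={"families": str, "tf_family": str, "chromosome": str})
    return validate_annotation(table)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index_label="gene_id")


def read_evidence(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    missing = [c for c in EVIDENCE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"evidence table missing columns: {missing}")
    table["est_supported"] = table["est_supported"].astype(bool)
    table["probe_present"] = table["probe_present"].astype(bool)
    return table


def write_evidence(evidence: pd.DataFrame, path: str | Path) -> None:
    evidence.loc[:, list(EVIDENCE_COLUMNS)].to_csv(path, sep="\t", index_label="gene_id")


def read_truth(path: str | Path) -> TruthTable:
    table = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
    stage = table["planted_specific_stage"].replace("", None)
    means = table.drop(columns=["planted_specific_stage"])
    return TruthTable(means=means, specific_stage=stage)


def write_truth(truth: TruthTable, path: str | Path) -> None:
    out = truth.means.copy()
    out["planted_specific_stage"] = truth.specific_stage.fillna("")
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_set(path: str | Path) -> set[str]:
    """Plain gene list: one ID per line, ``#`` comments and blanks ignored."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_gene_set(genes: set[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: ``name <tab> description <tab> gene...`` per line."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_matrix(values: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    values.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
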