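"""Readers and writers for the pipeline's interchange formats.

Counts travel as TSV (first column gene id, header row of sample ids) or as
MatrixMarket coordinate triplets with sidecar row/column name files;
annotation and orthology tables as TSV; signatures as GMT; DE tables and
score tables as TSV. All readers and writers are involutive on valid inputs.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    GROUP_ALIASES,
    CountMatrix,
    FormatError,
    OrthologyTable,
    SampleAnnotation,
    Signature,
    SignatureSet,
    ValidationError,
)


def _sidecar_paths(mtx_path: Path) -> tuple[Path, Path]:
    stem = mtx_path.with_suffix("")
    return Path(f"{stem}.rows.txt"), Path(f"{stem}.cols.txt")


def read_annotation(
    path: str | Path,
    aliases: Mapping[str, str] = GROUP_ALIASES,
    groups: tuple[str, ...] | None = None,
) -> SampleAnnotation:
    """Read a sample annotation TSV with ``sample_id`` and ``group`` columns."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in table.columns or "group" not in table.columns:
        raise FormatError(f"{path}: annotation needs 'sample_id' and 'group' columns")
    table = table.set_index("sample_id")
    return SampleAnnotation.from_frame(table, aliases=aliases, groups=groups)


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.table.rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def _read_counts_tsv(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.index.name = None
    frame.columns = frame.columns.astype(str)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for col in frame.columns:
            bad = pd.to_numeric(frame[col], errors="coerce").isna()
            if bad.any():
                raise FormatError(
                    f"{path}: non-numeric count at gene "
                    f"{frame.index[bad.argmax()]!r}, sample {col!r}"
                )
    return frame


def _read_counts_mtx(path: Path) -> pd.DataFrame:
    rows_path, cols_path = _sidecar_paths(path)
    for p in (rows_path, cols_path):
        if not p.exists():
            raise FormatError(f"missing MTX sidecar file {p}")
    mat = scipy.io.mmread(str(path))
    genes = rows_path.read_text().split()
    samples = cols_path.read_text().split()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    return pd.DataFrame(dense, index=genes, columns=samples)


def read_count_matrix(
    path: str | Path,
    annotation_path: str | Path,
    aliases: Mapping[str, str] = GROUP_ALIASES,
) -> CountMatrix:
    """Read counts (TSV or ``.mtx`` triplet with sidecars) plus annotation.

    Samples present in the counts but absent from the annotation raise
    :class:`ValidationError`; non-integer or negative cells raise
    :class:`FormatError` naming the offending gene/sample.
    """
    path = Path(path)
    counts = _read_counts_mtx(path) if path.suffix == ".mtx" else _read_counts_tsv(path)
    annotation = read_annotation(annotation_path, aliases=aliases)
    return CountMatrix(counts, annotation)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write counts as TSV, or MatrixMarket + sidecars if ``path`` ends in .mtx."""
    path = Path(path)
    if path.suffix == ".mtx":
        rows_path, cols_path = _sidecar_paths(path)
        sparse = scipy.sparse.coo_matrix(matrix.counts.to_numpy())
        scipy.io.mmwrite(str(path), sparse, field="integer")
        rows_path.write_text("\n".join(matrix.gene_ids) + "\n")
        cols_path.write_text("\n".join(matrix.sample_ids) + "\n")
    else:
        matrix.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_orthology_table(path: str | Path) -> OrthologyTable:
    """Read an HCOP-like orthology TSV.

    Columns: source_gene_id, human_symbol, n_databases, biotype. Blank
    symbols are normalized to "no ortholog"; n_databases outside [0, 14]
    is a validation error.
    """
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"source_gene_id": str, "human_symbol": str, "biotype": str},
        keep_default_na=False,
    )
    try:
        table["n_databases"] = table["n_databases"].astype(int)
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad n_databases column ({exc})") from exc
    return OrthologyTable(table)


def write_orthology_table(orthology: OrthologyTable, path: str | Path) -> None:
    orthology.table.to_csv(path, sep="\t", index=False)


_GMT_NAME = re.compile(r"^(?P<group>.+)_top(?P<k>\d+)$")


def write_signatures_gmt(signatures: SignatureSet, path: str | Path) -> None:
    """Write one GMT line per signature: name, description, genes (tab-separated)."""
    if len(signatures) == 0:
        raise ValidationError("no signatures to write")
    lines = []
    for sig in signatures:
        if len(sig.genes) == 0:
            raise ValidationError(f"signature {sig.name} has an empty gene list")
        for gene in sig.genes:
            if "\t" in gene or "\n" in gene:
                raise FormatError(f"gene name {gene!r} cannot be encoded in GMT")
        desc = f"minimax-p signature, group={sig.group}, k={sig.k}"
        lines.append("\t".join([sig.name, desc] + list(sig.genes)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_signatures_gmt(path: str | Path) -> SignatureSet:
    """Read a GMT file back into a :class:`SignatureSet`.

    Selection p-values are not stored in GMT; they are restored as NaN.
    """
    out = SignatureSet()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, _desc, genes = fields[0], fields[1], fields[2:]
        match = _GMT_NAME.match(name)
        group = match["group"] if match else name
        k = int(match["k"]) if match else len(genes)
        out.add(
            Signature(
                group=group,
                genes=list(genes),
                selection_p=np.full(len(genes), np.nan),
                k=k,
            )
        )
    if len(out) == 0:
        raise FormatError(f"{path}: empty GMT file")
    return out


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DE table TSV (gene, log2fc, pvalue, padj, base_mean)."""
    table.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "pvalue", "padj", "base_mean"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: DE table missing columns {sorted(missing)}")
    return table


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a score table TSV (sample, ft_score, o_score, ft_minus_o, ...)."""
    scores.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a real-valued gene/symbol x sample expression TSV."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return frame.astype(float)


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    expr.rename_axis("gene_id").to_csv(path, sep="\t")
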