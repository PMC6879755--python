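"""Core domain types for the cell-of-origin pipeline.

The pipeline compares four sample groups — normal fallopian-tube epithelium
(N-FT), normal ovarian surface epithelium (N-O), and tumors derived from each
(T-FT, T-O) — and produces group-specific gene signatures and per-sample
cell-of-origin scores. Types here are thin, validated wrappers around pandas
containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical group labels of the four-group mouse design.
CANONICAL_GROUPS: tuple[str, ...] = ("N-FT", "N-O", "T-FT", "T-O")

#: Label aliases applied on read; "N-0" (zero) is a mislabeling of "N-O"
#: seen in source annotations.
GROUP_ALIASES: Mapping[str, str] = {"N-0": "N-O"}


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicates, missing labels...)."""


class FormatError(ValueError):
    """A file cell or field cannot be parsed as required (e.g. non-integer count)."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    if len(ids) != len(set(ids)):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what}: {dup!r}")


@dataclass
class SampleAnnotation:
    """Per-sample labels: group (required), optional subtype and batch.

    ``table`` is indexed by sample id with at least a ``group`` column.
    """

    table: pd.DataFrame
    groups: tuple[str, ...] | None = None  # declared finite label set, if any

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValidationError("annotation requires a 'group' column")
        _check_unique(self.table.index, "sample id")
        if self.table["group"].isna().any():
            bad = self.table.index[self.table["group"].isna()][0]
            raise ValidationError(f"sample {bad!r} has no group label")
        if self.groups is not None:
            unknown = set(self.table["group"]) - set(self.groups)
            if unknown:
                raise ValidationError(
                    f"group labels {sorted(unknown)} not in declared set {self.groups}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "group"])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        aliases: Mapping[str, str] = GROUP_ALIASES,
        groups: tuple[str, ...] | None = None,
    ) -> "SampleAnnotation":
        table = frame.copy()
        table["group"] = table["group"].replace(dict(aliases))
        return cls(table, groups=groups)


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with group-labeled samples."""

    counts: pd.DataFrame
    annotation: SampleAnnotation

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene id")
        _check_unique(self.counts.columns, "sample id")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            frac = values != np.floor(values)
            if np.isnan(values).any() or frac.any():
                g, s = np.argwhere(np.isnan(values) | frac)[0]
                raise FormatError(
                    f"non-integer count at gene {self.counts.index[g]!r}, "
                    f"sample {self.counts.columns[s]!r}: {values[g, s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}: {values[g, s]}"
            )
        missing = [s for s in self.counts.columns if s not in self.annotation.table.index]
        if missing:
            raise ValidationError(f"samples missing from annotation: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def groups(self) -> pd.Series:
        """Group label per sample, in matrix column order."""
        return self.annotation.table.loc[self.sample_ids, "group"]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.annotation.group_of(s) == group]


@dataclass
class OrthologyTable:
    """Mouse-to-human orthology predictions (HCOP-like).

    Columns: ``source_gene_id``, ``human_symbol``, ``n_databases`` (0-14
    supporting databases), ``biotype``. A blank symbol is normalized to
    ``"no ortholog"`` with zero supporting databases.
    """

    NO_ORTHOLOG = "no ortholog"

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["source_gene_id", "human_symbol", "n_databases", "biotype"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"orthology table missing columns: {missing}")
        tab = self.table.copy()
        sym = tab["human_symbol"].astype("string")
        blank = sym.isna() | (sym.str.strip() == "")
        tab["human_symbol"] = sym.mask(blank, self.NO_ORTHOLOG).astype(str)
        tab["n_databases"] = tab["n_databases"].astype(int)
        if ((tab["n_databases"] < 0) | (tab["n_databases"] > 14)).any():
            bad = tab.loc[(tab["n_databases"] < 0) | (tab["n_databases"] > 14)].iloc[0]
            raise ValidationError(
                f"n_databases {bad['n_databases']} for {bad['source_gene_id']!r} "
                "outside [0, 14]"
            )
        tab.loc[tab["human_symbol"] == self.NO_ORTHOLOG, "n_databases"] = 0
        self.table = tab.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def mapped(self) -> pd.DataFrame:
        """Rows that carry a real human symbol."""
        return self.table[self.table["human_symbol"] != self.NO_ORTHOLOG]


@dataclass
class CohortData:
    """External-cohort inputs: expression, subtype labels, optional IPL matrix.

    ``expression`` is symbols x samples on a log scale (already normalized);
    ``ipl`` is pathway features x samples.
    """

    expression: pd.DataFrame
    subtype: pd.Series
    ipl: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        samples = list(self.expression.columns)
        if len(set(samples)) != len(samples):
            raise ValidationError("duplicate cohort sample ids")
        if self.expression.index.duplicated().any():
            raise ValidationError("duplicate cohort feature names")
        if set(self.subtype.index) != set(samples):
            raise ValidationError("subtype labels do not match expression samples")
        if self.ipl is not None:
            if set(self.ipl.columns) != set(samples):
                raise ValidationError("IPL samples do not match expression samples")
            if self.ipl.index.duplicated().any():
                raise ValidationError("duplicate IPL feature names")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)


@dataclass
class Signature:
    """An ordered gene list for one group, ranked by minimax selection p.

    ``selection_p[i]`` is the largest (least significant) of gene i's three
    "target vs other group" p-values; the list is sorted ascending on it.
    """

    group: str
    genes: list[str]
    selection_p: np.ndarray
    k: int
    truncated: bool = False  # fewer eligible genes than requested

    def __post_init__(self) -> None:
        self.selection_p = np.asarray(self.selection_p, dtype=float)
        _check_unique(self.genes, f"gene in {self.group} signature")
        if len(self.genes) != len(self.selection_p):
            raise ValidationError("genes and selection_p length mismatch")
        if np.any(np.diff(self.selection_p) < 0):
            raise ValidationError("selection_p must be non-decreasing along the list")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def name(self) -> str:
        return f"{self.group}_top{self.k}"


@dataclass
class SignatureSet:
    """Signatures keyed by (group, size); GMT-serializable."""

    signatures: dict[tuple[str, int], Signature] = field(default_factory=dict)

    def add(self, sig: Signature) -> None:
        self.signatures[(sig.group, sig.k)] = sig

    def get(self, group: str, k: int) -> Signature:
        return self.signatures[(group, k)]

    @property
    def groups(self) -> list[str]:
        return sorted({g for g, _ in self.signatures})

    @property
    def sizes(self) -> list[int]:
        return sorted({k for _, k in self.signatures})

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures.values())
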