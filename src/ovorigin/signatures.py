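"""Minimax-p signature construction and DEG overlap summaries.

A group's signature is built from its three pairwise comparisons: a gene is
eligible if it is upregulated (log2fc > 0, no significance floor) versus
every other group; its selection p-value is the largest (least significant)
of the three raw p-values; genes are ranked ascending on that minimax p and
the top k are kept. Selection uses raw p-values — adjusted values would tie
heavily and significance enters only through the ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import OrthologyTable, Signature, SignatureSet, ValidationError
from .diffexpr import PairwiseDESet

logger = logging.getLogger(__name__)

DEFAULT_SIZES: tuple[int, ...] = (50, 100, 250, 500)


def filter_gene_universe(
    genes: Iterable[str], orthology: OrthologyTable
) -> list[str]:
    """Protein-coding genes with a human ortholog in at least one database.

    Genes absent from the orthology table are treated as orphans and
    excluded. Input order is preserved.
    """
    tab = orthology.table
    eligible = set(
        tab.loc[
            (tab["biotype"] == "protein_coding") & (tab["n_databases"] >= 1),
            "source_gene_id",
        ]
    )
    kept = [g for g in genes if g in eligible]
    if not kept:
        raise ValidationError("gene universe is empty after the ortholog/biotype filter")
    return kept


def build_signature(
    pairwise: PairwiseDESet,
    target_group: str,
    k: int,
    universe: Sequence[str] | None = None,
) -> Signature:
    """Top-k genes upregulated in ``target_group`` versus all three others.

    Ranking is ascending in the minimax selection p; ties are broken by the
    larger minimum |log2fc| across the three comparisons, then by gene id.
    Fewer than k eligible genes returns them all with a truncation flag.
    """
    if k < 1:
        raise ValidationError(f"signature size must be >= 1, got {k}")
    tables = pairwise.comparisons_for(target_group)
    if len(tables) < 3:
        raise ValidationError(
            f"{target_group!r} needs three pairwise comparisons, found {len(tables)}"
        )

    merged: pd.DataFrame | None = None
    for i, (other, tab) in enumerate(sorted(tables.items())):
        part = tab.set_index("gene")[["log2fc", "pvalue"]].add_suffix(f"_{i}")
        merged = part if merged is None else merged.join(part, how="inner")
    assert merged is not None
    if universe is not None:
        merged = merged.loc[merged.index.intersection(list(universe))]

    n = len(tables)
    fc = merged[[f"log2fc_{i}" for i in range(n)]].to_numpy()
    pv = merged[[f"pvalue_{i}" for i in range(n)]].to_numpy()
    eligible = (fc > 0).all(axis=1) & ~np.isnan(pv).any(axis=1)
    if not eligible.any():
        raise ValidationError(f"no gene is upregulated in {target_group!r} vs all others")

    sel_p = pv[eligible].max(axis=1)
    min_abs_fc = np.abs(fc[eligible]).min(axis=1)
    # sort by gene id first; the stable sort on (p, |fc|) then leaves
    # lexicographic order as the final tie level
    ranked = (
        pd.DataFrame(
            {"selection_p": sel_p, "min_abs_fc": min_abs_fc},
            index=merged.index[eligible],
        )
        .sort_index(kind="mergesort")
        .sort_values(["selection_p", "min_abs_fc"], ascending=[True, False], kind="mergesort")
    )

    truncated = len(ranked) < k
    if truncated:
        logger.warning(
            "group %s: only %d eligible genes for requested size %d",
            target_group,
            len(ranked),
            k,
        )
    top = ranked.head(k)
    return Signature(
        group=target_group,
        genes=list(top.index),
        selection_p=top["selection_p"].to_numpy(),
        k=k,
        truncated=truncated,
    )


def build_signature_set(
    pairwise: PairwiseDESet,
    groups: Sequence[str] = ("T-FT", "T-O"),
    sizes: Sequence[int] = DEFAULT_SIZES,
    universe: Sequence[str] | None = None,
) -> SignatureSet:
    """Signatures for each group at each size; smaller sizes are prefixes of larger."""
    out = SignatureSet()
    for group in groups:
        biggest = build_signature(pairwise, group, max(sizes), universe=universe)
        for k in sorted(sizes):
            out.add(
                Signature(
                    group=group,
                    genes=biggest.genes[:k],
                    selection_p=biggest.selection_p[:k],
                    k=k,
                    truncated=len(biggest.genes) < k,
                )
            )
    return out


@dataclass
class VennSummary:
    """DEG counts per comparison and their intersections at one alpha.

    ``sets`` maps a comparison label (e.g. ``"T-O vs T-FT"``) to its DEG
    set; counts and intersections are derived views.
    """

    alpha: float
    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sets.items()}

    def intersection(self, *names: str) -> frozenset[str]:
        result: frozenset[str] | None = None
        for name in names:
            s = self.sets[name]
            result = s if result is None else result & s
        return result if result is not None else frozenset()

    def intersection_counts(self, order: int = 2) -> dict[tuple[str, ...], int]:
        """Counts of all intersections of the given order."""
        return {
            combo: len(self.intersection(*combo))
            for combo in combinations(sorted(self.sets), order)
        }

    def overlap_pct(self, reference: str, other: str) -> int:
        """Percentage of ``reference``'s DEGs also DE in ``other`` (nearest int)."""
        ref = self.sets[reference]
        if not ref:
            return 0
        return int(round(100.0 * len(ref & self.sets[other]) / len(ref)))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"comparison": name, "n_deg": len(s)} for name, s in sorted(self.sets.items())
        ]
        return pd.DataFrame(rows)


def venn_summary(pairwise: PairwiseDESet, alpha: float = 0.05) -> VennSummary:
    """DEG sets (padj < alpha) per comparison with intersection bookkeeping."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    out = VennSummary(alpha=alpha)
    for (b, a), tab in pairwise.tables.items():
        degs = frozenset(tab.loc[tab["padj"] < alpha, "gene"])
        out.sets[f"{b} vs {a}"] = degs
    return out


@dataclass
class MappingReport:
    """Bookkeeping from mouse-to-human signature mapping."""

    dropped: list[str]  # signature genes without a usable human symbol
    collapsed: list[str]  # genes removed because their symbol was already taken


def map_signature_to_human(
    signature: Signature, orthology: OrthologyTable
) -> tuple[Signature, MappingReport]:
    """Replace mouse gene ids by human symbols.

    One-to-many mappings resolve to the symbol with the most supporting
    databases (ties by symbol name); genes without an ortholog are dropped;
    if two mouse genes map to the same symbol the better-ranked gene keeps
    it. More than half the signature unmappable is an error.
    """
    mapped = orthology.mapped().sort_values(
        ["source_gene_id", "n_databases", "human_symbol"],
        ascending=[True, False, True],
    )
    best = mapped.drop_duplicates("source_gene_id").set_index("source_gene_id")[
        "human_symbol"
    ]
    genes, ps, dropped, collapsed = [], [], [], []
    seen: set[str] = set()
    for gene, p in zip(signature.genes, signature.selection_p):
        symbol = best.get(gene)
        if symbol is None:
            dropped.append(gene)
            continue
        if symbol in seen:
            collapsed.append(gene)
            continue
        seen.add(symbol)
        genes.append(symbol)
        ps.append(p)
    if len(dropped) > len(signature.genes) / 2:
        raise ValidationError(
            f"{len(dropped)}/{len(signature.genes)} signature genes have no "
            "human ortholog"
        )
    human = Signature(
        group=signature.group,
        genes=genes,
        selection_p=np.asarray(ps),
        k=signature.k,
        truncated=signature.truncated or bool(dropped) or bool(collapsed),
    )
    return human, MappingReport(dropped=dropped, collapsed=collapsed)
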