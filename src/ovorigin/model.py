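"""The cell-of-origin model: four-group counts in, signatures and scores out.

:class:`CellOfOriginModel` is built from a validated count matrix (plus an
optional orthology table defining the cross-species gene universe); ``fit``
runs normalization, all six pairwise NB comparisons, minimax-p signature
construction and per-sample scoring, returning a :class:`CellOfOriginResults`
that carries the estimates and diagnostics and knows how to apply itself to
an external cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import diffexpr, scoring, signatures
from .datatypes import (
    CANONICAL_GROUPS,
    CohortData,
    CountMatrix,
    OrthologyTable,
    SampleAnnotation,
    SignatureSet,
    ValidationError,
)

DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("mesenchymal-like", "proliferative-like"),
)


class CellOfOriginModel:
    """Cell-of-origin signature model for the four-group design.

    Parameters
    ----------
    data :
        Gene x sample integer counts with group-labeled samples (the four
        canonical groups N-FT, N-O, T-FT, T-O must be present to fit).
    orthology :
        Optional orthology/biotype table; when given, signature construction
        is restricted to protein-coding genes with a human ortholog, and
        fitted signatures can be mapped onto a human cohort.
    ft_group, o_group :
        The two tumor groups whose signatures define the combined score.
    prior_count :
        Pseudo-count used for logCPM (and, on the normalized-count scale,
        inside the NB fold-change estimate).
    """

    def __init__(
        self,
        data: CountMatrix,
        orthology: OrthologyTable | None = None,
        ft_group: str = "T-FT",
        o_group: str = "T-O",
        prior_count: float = 0.5,
    ) -> None:
        self.data = data
        self.orthology = orthology
        self.ft_group = ft_group
        self.o_group = o_group
        self.prior_count = prior_count

    @classmethod
    def from_dataframes(
        cls,
        counts: pd.DataFrame,
        annotation: pd.DataFrame,
        orthology: pd.DataFrame | None = None,
        **kwargs,
    ) -> "CellOfOriginModel":
        """Build from plain pandas frames (annotation indexed by sample id)."""
        data = CountMatrix(counts, SampleAnnotation.from_frame(annotation))
        orth = OrthologyTable(orthology) if orthology is not None else None
        return cls(data, orthology=orth, **kwargs)

    def fit(
        self,
        sizes: Sequence[int] = signatures.DEFAULT_SIZES,
        alpha: float = 0.05,
        groups: Sequence[str] = CANONICAL_GROUPS,
    ) -> "CellOfOriginResults":
        """Run normalization, pairwise DE, signature selection, and scoring."""
        if not 0 < alpha < 1:
            raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
        used = [
            s for s in self.data.sample_ids
            if self.data.annotation.group_of(s) in groups
        ]
        size_factors = diffexpr.estimate_size_factors(self.data.counts[used])
        logcpm = diffexpr.compute_logcpm(
            self.data.counts[used], prior=self.prior_count
        )
        pairwise = diffexpr.run_all_pairs(
            self.data, groups=tuple(groups), size_factors=size_factors
        )
        universe: list[str] | None = None
        if self.orthology is not None:
            universe = signatures.filter_gene_universe(
                self.data.gene_ids, self.orthology
            )
        sig_set = signatures.build_signature_set(
            pairwise,
            groups=(self.ft_group, self.o_group),
            sizes=sizes,
            universe=universe,
        )
        venn = signatures.venn_summary(pairwise, alpha=alpha)
        scores = {
            k: scoring.score_samples(
                logcpm, sig_set, k, ft_group=self.ft_group, o_group=self.o_group
            )
            for k in sorted(sizes)
        }
        return CellOfOriginResults(
            model=self,
            size_factors=size_factors,
            logcpm=logcpm,
            pairwise=pairwise,
            universe=universe,
            signatures=sig_set,
            venn=venn,
            scores=scores,
            alpha=alpha,
            sizes=tuple(sorted(sizes)),
        )


@dataclass
class CellOfOriginResults:
    """Fitted signatures, scores, and diagnostics for the mouse experiment."""

    model: CellOfOriginModel
    size_factors: pd.Series
    logcpm: pd.DataFrame
    pairwise: diffexpr.PairwiseDESet
    universe: list[str] | None
    signatures: SignatureSet
    venn: signatures.VennSummary
    scores: dict[int, pd.DataFrame]
    alpha: float
    sizes: tuple[int, ...]

    def de(self, group_b: str, group_a: str) -> pd.DataFrame:
        """DE table oriented ``group_b vs group_a``."""
        return self.pairwise.get(group_b, group_a)

    def signature(self, group: str, k: int):
        return self.signatures.get(group, k)

    def score_table(self, k: int | None = None) -> pd.DataFrame:
        """Per-sample score table at signature size k (smallest by default)."""
        return self.scores[k if k is not None else self.sizes[0]]

    def cluster_samples(self, linkage: str = "complete") -> cohort_mod.ClusteringResult:
        """Euclidean sample-distance hierarchical clustering of the logCPM matrix."""
        return cohort_mod.sample_distance_clustering(self.logcpm, linkage=linkage)

    def apply_to_cohort(
        self,
        cohort: CohortData,
        k: int | None = None,
        contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
        top_n: int = 50,
    ) -> "CohortResults":
        """Score an external cohort with the human-mapped signatures.

        The two tumor signatures at size ``k`` are mapped to human symbols,
        the cohort matrix is z-scored within itself, each sample gets FT, O
        and combined FT-O scores, subtype contrasts are tested by rank sum,
        and IPL features (if present) are ranked by |Pearson r| with the
        combined score.
        """
        if self.model.orthology is None:
            raise ValidationError("cohort application requires an orthology table")
        k = k if k is not None else self.sizes[0]
        ft_h, ft_report = signatures.map_signature_to_human(
            self.signatures.get(self.model.ft_group, k), self.model.orthology
        )
        o_h, o_report = signatures.map_signature_to_human(
            self.signatures.get(self.model.o_group, k), self.model.orthology
        )
        human_sigs = SignatureSet()
        human_sigs.add(ft_h)
        human_sigs.add(o_h)
        score_table = scoring.score_samples(
            cohort.expression,
            human_sigs,
            k,
            ft_group=self.model.ft_group,
            o_group=self.model.o_group,
        )
        combined = pd.Series(
            score_table["ft_minus_o"].to_numpy(), index=score_table["sample"]
        )
        subtype_tests = cohort_mod.compare_subtypes(
            combined, cohort.subtype, contrasts
        )
        ipl_table = (
            cohort_mod.correlate_ipl(cohort.ipl, combined, top_n=top_n)
            if cohort.ipl is not None
            else None
        )
        return CohortResults(
            parent=self,
            k=k,
            scores=score_table,
            subtype=cohort.subtype,
            subtype_tests=subtype_tests,
            ipl_table=ipl_table,
            mapping_reports={
                self.model.ft_group: ft_report,
                self.model.o_group: o_report,
            },
        )

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lines = [
            "Cell-of-origin model fit",
            "=" * 60,
            f"genes: {self.model.data.n_genes}   samples: {len(self.logcpm.columns)}",
            f"gene universe: "
            + (f"{len(self.universe)} (ortholog/biotype filtered)"
               if self.universe is not None else "all genes (no orthology table)"),
            f"adjusted-p threshold: {self.alpha}",
            "",
            f"{'comparison':<20}{'DEGs (padj < alpha)':>20}",
        ]
        for name, count in sorted(self.venn.counts.items()):
            lines.append(f"{name:<20}{count:>20}")
        lines.append("")
        lines.append(f"{'signature':<20}{'size':>8}{'max selection p':>20}")
        for sig in self.signatures:
            sel = sig.selection_p
            top = f"{sel[-1]:.3g}" if len(sel) else "-"
            lines.append(f"{sig.name:<20}{len(sig):>8}{top:>20}")
        table = self.score_table()
        lines += [
            "",
            f"scores at k={self.sizes[0]} (mouse samples):",
            f"  ft_minus_o range: [{table['ft_minus_o'].min():.3f}, "
            f"{table['ft_minus_o'].max():.3f}]",
        ]
        return "\n".join(lines)

    def plot_scores(self, k: int | None = None, ax=None):
        """Strip plot of the combined FT-O score by sample group."""
        import matplotlib.pyplot as plt

        table = self.score_table(k)
        groups = self.model.data.groups().loc[table["sample"]].to_numpy()
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        order = sorted(set(groups))
        for i, grp in enumerate(order):
            vals = table.loc[groups == grp, "ft_minus_o"]
            ax.scatter(np.full(len(vals), i), vals, alpha=0.8)
        ax.set_xticks(range(len(order)), order)
        ax.set_ylabel("FT − O score")
        ax.set_xlabel("group")
        return ax


@dataclass
class CohortResults:
    """Cohort application: scores, subtype tests, and IPL correlations."""

    parent: CellOfOriginResults
    k: int
    scores: pd.DataFrame
    subtype: pd.Series
    subtype_tests: pd.DataFrame
    ipl_table: pd.DataFrame | None
    mapping_reports: dict[str, signatures.MappingReport] = field(default_factory=dict)

    @property
    def combined(self) -> pd.Series:
        return pd.Series(
            self.scores["ft_minus_o"].to_numpy(), index=self.scores["sample"]
        )

    def summary(self) -> str:
        lines = [
            f"Cohort application (signature size k={self.k})",
            "=" * 60,
            f"samples scored: {len(self.scores)}",
            f"signature coverage: FT {self.scores['coverage_ft'].iat[0]:.2f}, "
            f"O {self.scores['coverage_o'].iat[0]:.2f}",
            "",
            "subtype contrasts (rank sum on FT-O score):",
        ]
        for _, row in self.subtype_tests.iterrows():
            arrow = ">" if row["direction"] > 0 else ("<" if row["direction"] < 0 else "=")
            lines.append(
                f"  {row['group_high']} {arrow} {row['group_low']}: "
                f"U={row['U']:.1f}, p={row['pvalue']:.3g} "
                f"(n={row['n_high']}/{row['n_low']})"
            )
        if self.ipl_table is not None:
            lines.append("")
            lines.append("top IPL features by |Pearson r| with the FT-O score:")
            for _, row in self.ipl_table.head(5).iterrows():
                lines.append(
                    f"  {row['rank']:>3}. {row['feature']}  r={row['pearson_r']:+.3f}"
                )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Strip plot of the combined score by cohort subtype."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        combined = self.combined
        labels = self.subtype.loc[combined.index]
        order = sorted(labels.unique())
        for i, grp in enumerate(order):
            vals = combined[labels == grp]
            ax.scatter(np.full(len(vals), i), vals, alpha=0.6)
        ax.set_xticks(range(len(order)), order, rotation=20)
        ax.set_ylabel("FT − O score")
        ax.set_xlabel("subtype")
        return ax
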