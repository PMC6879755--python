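"""Minimax-p signature construction, universe filter, Venn summary, mapping."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ovorigin.datatypes import OrthologyTable, Signature, ValidationError
from ovorigin.diffexpr import PairwiseDESet
from ovorigin.signatures import (
    build_signature,
    build_signature_set,
    filter_gene_universe,
    map_signature_to_human,
    venn_summary,
)

GROUPS = ("N-FT", "N-O", "T-FT", "T-O")


def make_pairwise(
    genes: list[str],
    log2fc: dict[tuple[str, str], np.ndarray],
    pvalue: dict[tuple[str, str], np.ndarray],
    padj: dict[tuple[str, str], np.ndarray] | None = None,
) -> PairwiseDESet:
    out = PairwiseDESet()
    for pair in log2fc:
        out.add(
            *pair,
            pd.DataFrame(
                {
                    "gene": genes,
                    "log2fc": log2fc[pair],
                    "pvalue": pvalue[pair],
                    "padj": (padj or pvalue)[pair],
                    "base_mean": 100.0,
                }
            ),
        )
    return out


def random_pairwise(rng, genes):
    """Random DE triples for all six pairs, canonical orientation."""
    from itertools import combinations

    log2fc, pvalue = {}, {}
    for a, b in combinations(GROUPS, 2):
        pair = (b, a)
        log2fc[pair] = rng.normal(0, 2, len(genes))
        pvalue[pair] = rng.uniform(size=len(genes))
    return make_pairwise(genes, log2fc, pvalue)


def brute_force_signature(pairwise, target, k):
    """Exhaustive re-application of the minimax rule, gene by gene."""
    tables = {o: t.set_index("gene") for o, t in pairwise.comparisons_for(target).items()}
    genes = list(next(iter(tables.values())).index)
    rows = []
    for g in genes:
        fcs = [t.loc[g, "log2fc"] for t in tables.values()]
        ps = [t.loc[g, "pvalue"] for t in tables.values()]
        if all(f > 0 for f in fcs) and not any(np.isnan(ps)):
            rows.append((g, max(ps), min(abs(f) for f in fcs)))
    rows.sort(key=lambda r: (r[1], -r[2], r[0]))
    return [r[0] for r in rows[:k]]


class TestUniverseFilter:
    def _orth(self, rows):
        return OrthologyTable(
            pd.DataFrame(
                rows,
                columns=["source_gene_id", "human_symbol", "n_databases", "biotype"],
            )
        )

    def test_fully_coding_orthologous_table_is_identity(self):
        orth = self._orth([("a", "A", 3, "protein_coding"), ("b", "B", 1, "protein_coding")])
        assert filter_gene_universe(["a", "b"], orth) == ["a", "b"]

    def test_orphan_and_noncoding_excluded(self):
        orth = self._orth(
            [
                ("a", "A", 3, "protein_coding"),
                ("b", "", 0, "protein_coding"),  # no ortholog
                ("c", "C", 5, "lncRNA"),  # not protein-coding
            ]
        )
        assert filter_gene_universe(["a", "b", "c", "d"], orth) == ["a"]

    def test_retained_count_matches_simulated_truth(self):
        from ovorigin.simulate import SimulationConfig, generate_orthology_table

        cfg = SimulationConfig(
            seed=21, n_genes=500, n_ft_marker=0, n_o_marker=0,
            n_shared_tumor=0, n_ft_tumor=0, n_o_tumor=0,
        )
        orth = generate_orthology_table(cfg)
        tab = orth.table
        expected = set(
            tab.loc[
                (tab["biotype"] == "protein_coding")
                & (tab["human_symbol"] != orth.NO_ORTHOLOG),
                "source_gene_id",
            ]
        )
        genes = sorted(tab["source_gene_id"].unique())
        assert set(filter_gene_universe(genes, orth)) == expected

    def test_empty_universe_is_an_error(self):
        orth = self._orth([("a", "", 0, "lncRNA")])
        with pytest.raises(ValidationError, match="empty"):
            filter_gene_universe(["a"], orth)


class TestBuildSignature:
    def test_minimax_ranking_hand_case(self):
        # g1 has p-triple (.001, .002, .003) -> selection_p .003; g3 has
        # (.001, .2, .01) -> selection_p .2; so g1 ranks above g3
        genes = ["g1", "g2", "g3", "g4"]
        pairs = [("T-FT", "N-FT"), ("T-FT", "N-O"), ("T-FT", "T-O")]
        pvals = {
            pairs[0]: np.array([0.001, 0.5, 0.001, 0.9]),
            pairs[1]: np.array([0.002, 0.5, 0.2, 0.9]),
            pairs[2]: np.array([0.003, 0.5, 0.01, 0.9]),
        }
        fcs = {p: np.ones(4) for p in pairs}
        fcs[pairs[2]] = np.array([1.0, 1.0, 1.0, -1.0])  # g4 down vs T-O
        pw = make_pairwise(genes, fcs, pvals)
        sig = build_signature(pw, "T-FT", k=4)
        assert sig.genes[0] == "g1"
        assert sig.genes.index("g1") < sig.genes.index("g3")
        assert "g4" not in sig.genes  # downregulated vs one group -> excluded
        assert sig.selection_p[0] == pytest.approx(0.003)

    def test_downregulation_vs_any_group_excludes_regardless_of_p(self):
        genes = ["g1"]
        pairs = [("T-FT", "N-FT"), ("T-FT", "N-O"), ("T-FT", "T-O")]
        pw = make_pairwise(
            genes,
            {pairs[0]: np.array([5.0]), pairs[1]: np.array([5.0]), pairs[2]: np.array([-0.01])},
            {p: np.array([1e-10]) for p in pairs},
        )
        with pytest.raises(ValidationError, match="upregulated"):
            build_signature(pw, "T-FT", k=1)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            genes = [f"g{i:02d}" for i in range(n)]
            pw = random_pairwise(rng, genes)
            k = int(rng.integers(1, n + 1))
            try:
                sig = build_signature(pw, "T-FT", k=k)
            except ValidationError:
                assert brute_force_signature(pw, "T-FT", k) == []
                continue
            assert sig.genes == brute_force_signature(pw, "T-FT", k)

    def test_invariant_to_gene_input_order(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i:02d}" for i in range(30)]
        pw = random_pairwise(rng, genes)
        shuffled = PairwiseDESet()
        perm = rng.permutation(30)
        for pair, tab in pw.tables.items():
            shuffled.add(*pair, tab.iloc[perm].reset_index(drop=True))
        a = build_signature(pw, "T-FT", k=10)
        b = build_signature(shuffled, "T-FT", k=10)
        assert a.genes == b.genes

    def test_selection_p_nondecreasing_invariant(self, fitted):
        for sig in fitted.signatures:
            assert (np.diff(sig.selection_p) >= 0).all()


class TestSignatureSet:
    def test_sizes_are_nested_prefixes(self, fitted):
        for group in ("T-FT", "T-O"):
            sigs = [fitted.signature(group, k).genes for k in (50, 100, 250, 500)]
            for small, large in zip(sigs, sigs[1:]):
                assert large[: len(small)] == small

    def test_tumor_signatures_disjoint_for_disjoint_programs(self, fitted):
        ft = set(fitted.signature("T-FT", 50).genes)
        o = set(fitted.signature("T-O", 50).genes)
        assert not (ft & o)

    def test_oversized_request_saturates_with_warning_flag(self, fitted):
        sig = build_signature(fitted.pairwise, "T-FT", k=10**6, universe=fitted.universe)
        assert sig.truncated
        assert len(sig.genes) < 10**6

    def test_members_upregulated_versus_all_other_groups(self, fitted):
        for group in ("T-FT", "T-O"):
            sig = fitted.signature(group, 50)
            for other, tab in fitted.pairwise.comparisons_for(group).items():
                fc = tab.set_index("gene").loc[sig.genes, "log2fc"]
                assert (fc > 0).all()


class TestVennSummary:
    def test_printed_set_sizes_give_42_percent(self):
        # 8623 tumor-vs-tumor DEGs of which 3641 are also DE between the
        # normal tissues -> 42% overlap
        tumor = [f"g{i}" for i in range(8623)]
        normal = tumor[:3641] + [f"x{i}" for i in range(2000)]
        genes = sorted(set(tumor) | set(normal))
        member_t = np.isin(genes, tumor)
        member_n = np.isin(genes, normal)
        pw = make_pairwise(
            genes,
            {("T-O", "T-FT"): np.ones(len(genes)), ("N-O", "N-FT"): np.ones(len(genes))},
            {("T-O", "T-FT"): np.zeros(len(genes)), ("N-O", "N-FT"): np.zeros(len(genes))},
            padj={
                ("T-O", "T-FT"): np.where(member_t, 0.01, 0.5),
                ("N-O", "N-FT"): np.where(member_n, 0.01, 0.5),
            },
        )
        venn = venn_summary(pw, alpha=0.05)
        assert venn.counts["T-O vs T-FT"] == 8623
        assert len(venn.intersection("T-O vs T-FT", "N-O vs N-FT")) == 3641
        assert venn.overlap_pct("T-O vs T-FT", "N-O vs N-FT") == 42

    def test_disjoint_sets_have_zero_intersections(self):
        genes = [f"g{i}" for i in range(20)]
        half = np.arange(20) < 10
        pw = make_pairwise(
            genes,
            {("T-O", "T-FT"): np.ones(20), ("N-O", "N-FT"): np.ones(20)},
            {("T-O", "T-FT"): np.zeros(20), ("N-O", "N-FT"): np.zeros(20)},
            padj={
                ("T-O", "T-FT"): np.where(half, 0.01, 0.5),
                ("N-O", "N-FT"): np.where(half, 0.5, 0.01),
            },
        )
        venn = venn_summary(pw)
        for combo, n in venn.intersection_counts(order=2).items():
            assert n == 0

    def test_counts_match_literal_set_algebra_on_random_sets(self):
        rng = np.random.default_rng(55)
        genes = [f"g{i}" for i in range(200)]
        padj = {
            ("T-O", "T-FT"): rng.uniform(size=200),
            ("N-O", "N-FT"): rng.uniform(size=200),
            ("T-FT", "N-FT"): rng.uniform(size=200),
        }
        pw = make_pairwise(
            genes,
            {p: np.ones(200) for p in padj},
            {p: np.zeros(200) for p in padj},
            padj=padj,
        )
        venn = venn_summary(pw, alpha=0.3)
        literal = {
            name: {g for g, q in zip(genes, padj[pair]) if q < 0.3}
            for pair, name in zip(padj, ["T-O vs T-FT", "N-O vs N-FT", "T-FT vs N-FT"])
        }
        for name, expected in literal.items():
            assert venn.sets[name] == frozenset(expected)
        a, b = "N-O vs N-FT", "T-O vs T-FT"
        assert venn.intersection(a, b) == frozenset(literal[a] & literal[b])

    def test_alpha_outside_unit_interval_rejected(self, fitted):
        with pytest.raises(ValidationError, match="alpha"):
            venn_summary(fitted.pairwise, alpha=1.5)


class TestHumanMapping:
    def _orth(self, rows):
        return OrthologyTable(
            pd.DataFrame(
                rows,
                columns=["source_gene_id", "human_symbol", "n_databases", "biotype"],
            )
        )

    def _sig(self, genes):
        return Signature(
            group="T-FT",
            genes=genes,
            selection_p=np.linspace(0.001, 0.01, len(genes)),
            k=len(genes),
        )

    def test_injective_mapping_preserves_length(self):
        orth = self._orth(
            [("a", "A", 5, "protein_coding"), ("b", "B", 5, "protein_coding")]
        )
        human, report = map_signature_to_human(self._sig(["a", "b"]), orth)
        assert human.genes == ["A", "B"] and not report.dropped

    def test_one_to_many_resolved_by_database_support(self):
        orth = self._orth(
            [
                ("a", "A1", 3, "protein_coding"),
                ("a", "A2", 11, "protein_coding"),
            ]
        )
        human, _ = map_signature_to_human(self._sig(["a"]), orth)
        assert human.genes == ["A2"]

    def test_majority_unmappable_is_an_error(self):
        orth = self._orth(
            [
                ("a", "A", 5, "protein_coding"),
                ("b", "", 0, "protein_coding"),
                ("c", "", 0, "protein_coding"),
            ]
        )
        with pytest.raises(ValidationError, match="ortholog"):
            map_signature_to_human(self._sig(["a", "b", "c"]), orth)

    def test_simulated_truth_mapping_recovered(self, fitted, orthology):
        sig = fitted.signature("T-FT", 50)
        human, report = map_signature_to_human(sig, orthology)
        # default simulated table maps GeneNNNN -> GENENNNN injectively
        assert human.genes == [g.upper() for g in sig.genes]
        assert not report.dropped and not report.collapsed
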