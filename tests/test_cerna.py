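"""ceRNA screening: immune intersection, co-expression, pair admission,
stringency tiers, network assembly — each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import immucerna as ic
from conftest import pooled_pearson


def random_expr(rng, genes, n_samples=12):
    values = pd.DataFrame(
        rng.normal(size=(len(genes), n_samples)),
        index=genes,
        columns=[f"s{i}" for i in range(n_samples)],
    )
    # some genes strongly co-expressed so pairs can clear the threshold
    for i in range(0, len(genes) - 1, 3):
        values.iloc[i + 1] = values.iloc[i] + 0.1 * rng.normal(size=n_samples)
    groups = {f"s{i}": ("control" if i < n_samples // 2 else "case")
              for i in range(n_samples)}
    return ic.ExpressionMatrix(values=values, groups=groups, scale="log2")


class TestImmuneIntersect:
    def test_worked_example(self, toy_catalog):
        immune, lncs = ic.immune_intersect(["RABEP1", "JPX", "ACTB"], toy_catalog)
        assert immune == ["RABEP1"]   # mRNA and in the immune list
        assert lncs == ["JPX"]        # lncRNAs need no immune flag

    def test_no_immune_genes(self):
        catalog = ic.GeneCatalog(
            table=pd.DataFrame({"biotype": ["mRNA"], "is_immune": [False]},
                               index=["ACTB"])
        )
        immune, _ = ic.immune_intersect(["ACTB"], catalog)
        assert immune == []

    def test_empty_deg_list_warns(self, toy_catalog, caplog):
        with caplog.at_level("WARNING"):
            immune, lncs = ic.immune_intersect([], toy_catalog)
        assert immune == [] and lncs == []

    def test_uncovered_genes_dropped_with_warning(self, toy_catalog, caplog):
        with caplog.at_level("WARNING"):
            immune, lncs = ic.immune_intersect(["RABEP1", "UNKNOWN"], toy_catalog)
        assert "UNKNOWN" in caplog.text
        assert immune == ["RABEP1"]

    def test_matches_set_algebra_oracle(self, default_sim):
        """On 50 random DEG symbols the output equals brute-force set
        intersection with the catalog."""
        rng = np.random.default_rng(7)
        cat = default_sim.catalog
        degs = list(rng.choice(cat.gene_ids, size=50, replace=False))
        immune, lncs = ic.immune_intersect(degs, cat)
        t = cat.table
        oracle_immune = [g for g in degs
                         if t.at[g, "biotype"] == "mRNA" and t.at[g, "is_immune"]]
        oracle_lnc = [g for g in degs if t.at[g, "biotype"] == "lncRNA"]
        assert immune == oracle_immune
        assert lncs == oracle_lnc


class TestPairwiseCorrelation:
    def test_identity_and_antisymmetry(self):
        x = [1.0, 2, 3, 4, 5, 6]
        values = pd.DataFrame(
            {"s%d" % i: [x[i], x[i], -x[i]] for i in range(6)},
            index=["a", "b", "c"],
        )
        expr = ic.ExpressionMatrix(values=values, groups=None, scale="log2")
        recs = {(r.lncrna, r.mrna): r
                for r in ic.pairwise_correlation(expr, ["a"], ["b", "c"])}
        assert recs[("a", "b")].r == pytest.approx(1.0, abs=1e-12)
        assert recs[("a", "c")].r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_vector_pair(self):
        x = [1.0, 2, 3, 4, 5]
        y = [2.0, 1, 4, 3, 6]
        values = pd.DataFrame([x, y], index=["gx", "gy"],
                              columns=[f"s{i}" for i in range(5)])
        expr = ic.ExpressionMatrix(values=values, groups=None, scale="log2")
        rec = ic.pairwise_correlation(expr, ["gx"], ["gy"])[0]
        assert rec.r == pytest.approx(pooled_pearson(x, y), abs=1e-12)
        # p from the t distribution with n-2 df, against scipy's reference
        from scipy.stats import pearsonr
        assert rec.p_corr == pytest.approx(pearsonr(x, y).pvalue, rel=1e-9)

    def test_matches_formula_on_random_matrix_to_1e12(self, default_sim):
        rng = np.random.default_rng(3)
        genes = list(rng.choice(default_sim.expr.gene_ids, 12, replace=False))
        recs = ic.pairwise_correlation(default_sim.expr, genes[:6], genes[6:])
        log2 = default_sim.expr.values
        for rec in recs:
            oracle = pooled_pearson(log2.loc[rec.lncrna], log2.loc[rec.mrna])
            assert rec.r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_gene_flagged_degenerate(self):
        values = pd.DataFrame(
            [[1.0, 2, 3, 4], [5.0, 5, 5, 5]], index=["v", "flat"],
            columns=list("wxyz"),
        )
        expr = ic.ExpressionMatrix(values=values, groups=None, scale="log2")
        rec = ic.pairwise_correlation(expr, ["v"], ["flat"])[0]
        assert rec.degenerate and rec.r == 0.0

    def test_missing_gene_raises(self, tiny_expr):
        with pytest.raises(KeyError, match="nope"):
            ic.pairwise_correlation(tiny_expr, ["gA"], ["nope"])

    def test_per_group_option(self, default_sim):
        rec_all = ic.pairwise_correlation(
            default_sim.expr, ["LNC0001"], ["G0001"]
        )[0]
        rec_ctrl = ic.pairwise_correlation(
            default_sim.expr, ["LNC0001"], ["G0001"], group="control"
        )[0]
        log2 = default_sim.expr.values[default_sim.expr.samples_in_group("control")]
        assert rec_ctrl.r == pytest.approx(
            pooled_pearson(log2.loc["LNC0001"], log2.loc["G0001"]), abs=1e-12
        )
        assert rec_ctrl.r != rec_all.r


def brute_force_pairs(correlations, interactions, r_threshold):
    """Independent double-loop enumeration of the admission criteria."""
    admitted = []
    for rec in correlations:
        if rec.degenerate:
            continue
        shared = {
            m for (m, g) in interactions.edges if g == rec.lncrna
        } & {m for (m, g) in interactions.edges if g == rec.mrna}
        if shared and rec.r > r_threshold:
            admitted.append((rec.lncrna, rec.mrna, frozenset(shared), rec.r))
    admitted.sort(key=lambda t: (-t[3], t[0], t[1]))
    return admitted


class TestBuildCernaPairs:
    def test_published_style_pair_admitted(self):
        recs = [ic.CorrelationRecord("JPX", "RABEP1", 0.952570119, 1e-8)]
        inter = ic.InteractionTable.from_pairs(
            [("miR-145", "JPX"), ("miR-145", "RABEP1"), ("miR-24", "JPX"),
             ("miR-24", "RABEP1")]
        )
        pairs = ic.build_cerna_pairs(recs, inter)
        assert len(pairs) == 1
        assert pairs[0].shared_mirnas == frozenset({"miR-145", "miR-24"})
        assert pairs[0].r == pytest.approx(0.952570119)

    def test_no_shared_mirna_rejected(self):
        recs = [ic.CorrelationRecord("L", "M", 0.95, 1e-8)]
        inter = ic.InteractionTable.from_pairs([("miR-1", "L"), ("miR-2", "M")])
        assert ic.build_cerna_pairs(recs, inter) == []

    def test_negative_correlation_rejected_despite_magnitude(self):
        # mirrors the published negative rows absent from the final network
        recs = [ic.CorrelationRecord("SND1-IT1", "RXRB", -0.943270822, 1e-8)]
        inter = ic.InteractionTable.from_pairs(
            [("miR-9", "SND1-IT1"), ("miR-9", "RXRB")]
        )
        assert ic.build_cerna_pairs(recs, inter) == []

    def test_degenerate_records_excluded(self):
        recs = [ic.CorrelationRecord("L", "M", 0.0, 1.0, degenerate=True)]
        inter = ic.InteractionTable.from_pairs([("miR-1", "L"), ("miR-1", "M")])
        assert ic.build_cerna_pairs(recs, inter) == []

    def test_corr_alpha_option(self):
        recs = [ic.CorrelationRecord("L", "M", 0.9, 0.2)]
        inter = ic.InteractionTable.from_pairs([("miR-1", "L"), ("miR-1", "M")])
        assert ic.build_cerna_pairs(recs, inter) != []
        assert ic.build_cerna_pairs(recs, inter, corr_alpha=0.05) == []

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match="r_threshold"):
            ic.build_cerna_pairs([], ic.InteractionTable.from_pairs([]),
                                 r_threshold=1.5)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_exhaustive_enumeration(self, seed):
        """Admission equals the brute-force double loop on random instances
        of up to 20 genes."""
        rng = np.random.default_rng(seed)
        n_lnc, n_mrna = 8, 12
        lncs = [f"L{i}" for i in range(n_lnc)]
        mrnas = [f"M{i}" for i in range(n_mrna)]
        expr = random_expr(rng, lncs + mrnas)
        mirs = [f"mir{i}" for i in range(6)]
        edges = {
            (m, g)
            for m in mirs
            for g in lncs + mrnas
            if rng.random() < 0.25
        }
        inter = ic.InteractionTable(edges=frozenset(edges))
        recs = ic.pairwise_correlation(expr, lncs, mrnas)
        pairs = ic.build_cerna_pairs(recs, inter, r_threshold=0.8)
        got = [(p.lncrna, p.mrna, p.shared_mirnas, p.r) for p in pairs]
        assert got == brute_force_pairs(recs, inter, 0.8)


class TestStringencyFilter:
    @pytest.fixture()
    def published_pairs(self):
        df = ic.load_published_pah_pairs()
        return [
            ic.CeRNAPair(row.lncrna, row.mrna, frozenset({"mir"}), row.r, 1e-6)
            for row in df.itertuples()
        ]

    def test_published_top_pair_retained(self, published_pairs):
        kept = ic.stringency_filter(published_pairs, cutoff=0.91)
        assert len(kept) == 18  # every published row clears |r| > 0.91
        assert all(p.tier == "high_stringency" for p in kept)
        assert kept[0].r == pytest.approx(0.952570119)

    def test_below_cutoff_dropped(self):
        pairs = [ic.CeRNAPair("L", "M", frozenset({"m"}), 0.905, 1e-6)]
        assert ic.stringency_filter(pairs, cutoff=0.91) == []

    def test_filter_composition_is_monotone(self, published_pairs):
        via_08 = ic.stringency_filter(
            ic.stringency_filter(published_pairs, cutoff=0.8), cutoff=0.91
        )
        direct = ic.stringency_filter(published_pairs, cutoff=0.91)
        assert [(p.lncrna, p.mrna) for p in via_08] == \
               [(p.lncrna, p.mrna) for p in direct]

    def test_output_subset_of_input(self, published_pairs):
        kept = ic.stringency_filter(published_pairs, cutoff=0.93)
        keys = {(p.lncrna, p.mrna) for p in published_pairs}
        assert {(p.lncrna, p.mrna) for p in kept} <= keys


class TestAssembleNetwork:
    def test_single_pair_three_nodes_two_edges(self):
        pairs = [ic.CeRNAPair("JPX", "RABEP1", frozenset({"miR-145"}), 0.95, 1e-8)]
        net = ic.assemble_network(pairs)
        assert len(net.node_types) == 3
        assert len(net.edges) == 2
        net.validate()

    def test_published_six_pair_network_shape(self):
        """The validated network: 2 lncRNAs and 6 mRNAs joined by miRNAs."""
        six = [("JPX", "RABEP1"), ("JPX", "IREB2"), ("MALAT1", "CHUK"),
               ("MALAT1", "TANK"), ("MALAT1", "ECD"), ("MALAT1", "TBK1")]
        pairs = [
            ic.CeRNAPair(l, m, frozenset({f"miR-{i}"}), 0.92, 1e-6)
            for i, (l, m) in enumerate(six)
        ]
        net = ic.assemble_network(pairs)
        assert len(net.nodes_of_type("lncRNA")) == 2
        assert len(net.nodes_of_type("mRNA")) == 6

    def test_every_mirna_bridges_both_sides(self, default_sim):
        deg = ic.differential_expression(default_sim.expr)
        immune, lncs = ic.immune_intersect(deg.deg_genes(), default_sim.catalog)
        recs = ic.pairwise_correlation(default_sim.expr, lncs, immune)
        pairs = ic.build_cerna_pairs(recs, default_sim.interactions)
        net = ic.assemble_network(pairs)
        net.validate()  # every miRNA node links >= 1 lncRNA and >= 1 mRNA
        for mir in net.nodes_of_type("miRNA"):
            assert net.degree(mir) >= 2

    def test_deterministic_ordering(self, default_sim):
        deg = ic.differential_expression(default_sim.expr)
        immune, lncs = ic.immune_intersect(deg.deg_genes(), default_sim.catalog)
        recs = ic.pairwise_correlation(default_sim.expr, lncs, immune)
        a = ic.build_cerna_pairs(recs, default_sim.interactions)
        b = ic.build_cerna_pairs(recs, default_sim.interactions)
        assert a == b
        rs = [p.r for p in a]
        assert rs == sorted(rs, reverse=True)
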