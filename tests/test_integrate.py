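"""FDR adjustment, cross-method consensus and the reporting tables."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from gwasea.genemap import SnpGeneMap
from gwasea.genesets import GeneSet
from gwasea.integrate import (
    bh_adjust,
    consensus,
    contributing_genes,
    enriched_gene_table,
    leave_one_out,
    set_size_summary,
)


class TestBhAdjust:
    def test_single_test_is_identity(self):
        assert bh_adjust([0.01], m_total=1)[0] == pytest.approx(0.01)

    def test_matches_statsmodels_when_full_list(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.0001, 1, 50)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1, 30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_monotone_in_rank_and_capped(self):
        p = np.array([0.9, 0.5, 0.2, 0.95])
        adj = bh_adjust(p, m_total=100)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj <= 1.0)

    def test_m_total_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m_total=1)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestConsensus:
    def _frame(self, sets, ps, fdrs, sizes=None):
        df = pd.DataFrame({"set": sets, "raw_p": ps, "fdr": fdrs})
        if sizes is not None:
            df["size"] = sizes
        return df

    def test_single_method_top_k(self):
        df = self._frame(["A", "B", "C", "D"], [0.001, 0.002, 0.003, 0.5],
                         [0.01, 0.02, 0.04, 0.9], sizes=[10, 20, 30, 40])
        rep = consensus({"m1": df})
        assert rep.K == 3
        assert list(rep.top_lists["m1"]["set"]) == ["A", "B", "C"]
        assert rep.median_set_size["m1"] == 20

    def test_identical_methods_full_multiplicity(self):
        df = self._frame(["A", "B"], [0.001, 0.002], [0.01, 0.02])
        rep = consensus({m: df for m in ["m1", "m2", "m3", "m4"]})
        assert (rep.union["multiplicity"] == 4).all()

    def test_k_floor_of_one(self):
        df = self._frame(["A", "B"], [0.2, 0.3], [0.8, 0.9])
        rep = consensus({"m1": df})
        assert rep.K == 1 and len(rep.top_lists["m1"]) == 1

    def test_tie_break_by_set_name(self):
        df = self._frame(["B", "A", "C"], [0.01, 0.01, 0.5], [0.03, 0.03, 0.9])
        rep = consensus({"m1": df})
        assert list(rep.top_lists["m1"]["set"]) == ["A", "B"]


class TestContributingGenes:
    def _world(self):
        pairs = [("s1", "A"), ("s2", "A"), ("s3", "A"), ("s4", "B"), ("s5", "B")]
        m = SnpGeneMap(pairs=pd.DataFrame(pairs, columns=["snp_id", "gene_id"]))
        assoc = pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(1, 6)],
             "P": [0.01, 0.5, 0.6, 0.5, 0.7]}
        )
        return assoc, m

    def test_toy_set(self):
        assoc, m = self._world()
        genes, ratio = contributing_genes(GeneSet("S", "d", ["A", "B"]), assoc, m)
        assert genes == ["A"]
        assert ratio == pytest.approx(1 / 5)

    def test_no_signal_empty(self):
        assoc, m = self._world()
        assoc["P"] = 0.5
        genes, ratio = contributing_genes(GeneSet("S", "d", ["A", "B"]), assoc, m)
        assert genes == [] and ratio == 0.0


class TestSetSizeSummary:
    def test_even_and_odd_medians(self):
        out = set_size_summary({"a": [10, 14, 122, 68, 49, 51, 12, 43, 16], "b": [7]})
        assert out["a"] == 43 and out["b"] == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            set_size_summary({"a": []})


class TestLeaveOneOut:
    def test_gene_without_snps_leaves_srt_unchanged(self, power_run):
        m = power_run["map"]
        assoc = power_run["assoc"]
        perm = power_run["permutation"]
        base = power_run["collection"][power_run["collection"].names[0]]
        # a member gene absent from the annotation maps to no SNPs
        gs = GeneSet(base.name, base.description, list(base.genes) + ["UNMAPPED_GENE"])
        reduced = leave_one_out("srt", gs, "UNMAPPED_GENE", assoc, m, permutation=perm)
        from gwasea.genesets import GeneSetCollection
        from gwasea.srt import srt_test

        single = GeneSetCollection()
        single.add(gs)
        orig = srt_test(assoc, perm, m, single)
        assert reduced["ratio"].iloc[0] == pytest.approx(orig["ratio"].iloc[0])
        assert reduced["raw_p"].iloc[0] == pytest.approx(orig["raw_p"].iloc[0])

    def test_removing_strongest_causal_gene_lowers_mixedmodel_intercept(self, power_run):
        truth = power_run["truth"]
        gs = power_run["collection"][truth.causal_set_names[0]]
        m = power_run["map"]
        assoc = power_run["assoc"]
        from gwasea.mixedmodel import fit_set_mixed_model, p_to_chisq

        p_of = assoc.set_index("snp_id")["P"]
        strongest = max(
            truth.causal_genes,
            key=lambda g: float(np.mean(p_to_chisq(p_of.loc[m.snps_of(g)].to_numpy()))),
        )
        original = fit_set_mixed_model(assoc, m, gs)
        reduced = leave_one_out("mixedmodel", gs, strongest, assoc, m)
        assert reduced["beta0"].iloc[0] < original["beta0"]

    def test_remove_and_readd_round_trip(self, power_run):
        truth = power_run["truth"]
        gs = power_run["collection"][truth.causal_set_names[0]]
        m = power_run["map"]
        assoc = power_run["assoc"]
        from gwasea.mixedmodel import fit_set_mixed_model

        before = fit_set_mixed_model(assoc, m, gs)
        leave_one_out("mixedmodel", gs, truth.causal_genes[0], assoc, m)
        after = fit_set_mixed_model(assoc, m, gs)
        assert before["beta0"] == after["beta0"] and before["p"] == after["p"]

    def test_non_member_rejected(self, power_run):
        truth = power_run["truth"]
        gs = power_run["collection"][truth.causal_set_names[0]]
        with pytest.raises(ValueError):
            leave_one_out("mixedmodel", gs, "NOT_A_MEMBER",
                          power_run["assoc"], power_run["map"])


class TestEnrichedGeneTable:
    def _world(self):
        # gene G in 5 of 6 top sets, 2 of 7 SNPs significant
        pairs = [(f"g_s{j}", "G") for j in range(7)]
        pairs += [("x_s1", "X"), ("y_s1", "Y")]
        m = SnpGeneMap(pairs=pd.DataFrame(pairs, columns=["snp_id", "gene_id"]))
        p = {f"g_s{j}": 0.5 for j in range(7)}
        p["g_s2"], p["g_s5"] = 0.01, 0.03
        p["x_s1"], p["y_s1"] = 0.02, 0.6
        assoc = pd.DataFrame({"snp_id": list(p), "P": list(p.values())})
        tops = [GeneSet(f"T{i}", "d", ["G", "X"] if i < 5 else ["X", "Y"]) for i in range(6)]
        return assoc, m, tops

    def test_counts_and_best_snp(self):
        assoc, m, tops = self._world()
        table = enriched_gene_table(tops, assoc, m, min_terms=4)
        row = table.set_index("gene_id").loc["G"]
        assert row["n_terms"] == 5
        assert (row["n_sig_snps"], row["n_snps"]) == (2, 7)
        assert row["best_snp"] == "g_s2"

    def test_min_terms_boundary_excludes(self):
        assoc, m, tops = self._world()
        table = enriched_gene_table(tops[:4], assoc, m, min_terms=4)
        # X is in only 4 of these sets' membership lists -> boundary included
        assert "X" in set(table["gene_id"])
        table5 = enriched_gene_table(tops[:4], assoc, m, min_terms=5)
        assert "X" not in set(table5["gene_id"])

    def test_min_terms_one_lists_every_contributing_gene(self):
        assoc, m, tops = self._world()
        table = enriched_gene_table(tops, assoc, m, min_terms=1)
        assert set(table["gene_id"]) == {"G", "X"}   # Y has no significant SNP
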