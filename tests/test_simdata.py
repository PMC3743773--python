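"""Generator behavior: determinism, layout guarantees, disease-model
calibration and effect recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from gwasea import simdata
from gwasea.core import TruthSpec
from gwasea.gwas_assoc import fit_snp_logistic


class TestAnnotation:
    def test_fixed_length_degenerate_case(self):
        ann = simdata.simulate_annotation(
            1, n_chroms=1, gene_length_range=(10_000, 10_000),
            gap_range=(50_000, 50_000), seed=1,
        )
        assert len(ann) == 1
        assert int(ann["end"][0] - ann["start"][0] + 1) == 10_000

    def test_seed_determinism_and_sensitivity(self):
        a = simdata.simulate_annotation(100, n_chroms=3, seed=7)
        b = simdata.simulate_annotation(100, n_chroms=3, seed=7)
        c = simdata.simulate_annotation(100, n_chroms=3, seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert not a[["start", "end"]].equals(c[["start", "end"]])

    def test_invariants(self):
        ann = simdata.simulate_annotation(50, n_chroms=2, seed=3)
        assert (ann["start"] <= ann["end"]).all()
        assert ann["gene_id"].is_unique

    @pytest.mark.parametrize("bad", [(0, 10), (10, 5), (-5, 5)])
    def test_bad_ranges_rejected(self, bad):
        with pytest.raises(ValueError):
            simdata.simulate_annotation(5, gene_length_range=bad, seed=1)


class TestVariants:
    def test_coverage_guarantee(self, toy_annotation):
        one_gene = toy_annotation.iloc[[0]]
        var = simdata.simulate_variants(one_gene, snps_per_gene_mean=5, seed=2)
        inside = (
            (var["pos"] >= one_gene["start"].iloc[0] - 20_000)
            & (var["pos"] <= one_gene["end"].iloc[0] + 20_000)
        )
        assert inside.any()

    def test_degenerate_maf_range(self, toy_annotation):
        var = simdata.simulate_variants(
            toy_annotation, maf_range=(0.3, 0.3), seed=2
        )
        assert np.allclose(var["maf"], 0.3)

    def test_seed_determinism(self, toy_annotation):
        a = simdata.simulate_variants(toy_annotation, seed=4)
        b = simdata.simulate_variants(toy_annotation, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_sorted_within_chromosome(self, toy_annotation):
        var = simdata.simulate_variants(toy_annotation, seed=4)
        for _, grp in var.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            simdata.simulate_variants(pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]))


class TestGeneSets:
    @pytest.fixture
    def annotation(self):
        return simdata.simulate_annotation(120, n_chroms=2, seed=9)

    def test_null_scenario_has_no_causal_genes(self, annotation):
        _, truth = simdata.simulate_gene_sets(annotation, n_sets=10, n_causal_sets=0, seed=1)
        assert truth.causal_genes == [] and truth.is_null

    def test_zero_overlap_gives_disjoint_sets(self, annotation):
        coll, _ = simdata.simulate_gene_sets(
            annotation, n_sets=8, size_range=(5, 10), overlap_fraction=0.0, seed=1
        )
        names = coll.names
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not set(coll[a].genes) & set(coll[b].genes)

    def test_sizes_within_bounds(self, annotation):
        coll, _ = simdata.simulate_gene_sets(
            annotation, n_sets=50, size_range=(5, 25), seed=2
        )
        assert all(5 <= s.size <= 25 for s in coll)

    def test_causal_genes_subset_of_causal_sets(self, annotation):
        coll, truth = simdata.simulate_gene_sets(
            annotation, n_sets=10, n_causal_sets=2, n_causal_genes_per_set=3, seed=3
        )
        causal_members = set()
        for name in truth.causal_set_names:
            causal_members.update(coll[name].genes)
        assert set(truth.causal_genes) <= causal_members

    def test_infeasible_size_range_rejected(self, annotation):
        with pytest.raises(ValueError):
            simdata.simulate_gene_sets(annotation, n_sets=5, size_range=(5, 500), seed=1)


class TestCohort:
    def test_reference_shape(self):
        ann = simdata.simulate_annotation(5, seed=1)
        var = simdata.simulate_variants(ann, snps_per_gene_mean=3, seed=1)
        cohort = simdata.simulate_cohort(var, TruthSpec(), 537, 605, seed=1)
        assert cohort.n_individuals == 1142
        assert cohort.n_cases == 537 and cohort.n_controls == 605

    def test_seed_determinism(self):
        ann = simdata.simulate_annotation(5, seed=1)
        var = simdata.simulate_variants(ann, snps_per_gene_mean=3, seed=1)
        a = simdata.simulate_cohort(var, TruthSpec(), 50, 50, seed=9)
        b = simdata.simulate_cohort(var, TruthSpec(), 50, 50, seed=9)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.phenotype, b.phenotype)

    def test_missing_rate_injection(self):
        ann = simdata.simulate_annotation(5, seed=1)
        var = simdata.simulate_variants(ann, snps_per_gene_mean=5, seed=1)
        cohort = simdata.simulate_cohort(
            var, TruthSpec(), 200, 200, seed=2, missing_rate=0.05
        )
        frac = (cohort.genotypes == -1).mean()
        assert 0.03 < frac < 0.07

    def test_unattainable_counts_error(self):
        ann = simdata.simulate_annotation(2, seed=1)
        var = simdata.simulate_variants(ann, snps_per_gene_mean=2, seed=1)
        truth = TruthSpec(alpha=-30.0)   # cases essentially impossible
        with pytest.raises(RuntimeError):
            simdata.simulate_cohort(var, truth, 50, 50, seed=1, max_batches=5)

    def test_null_pvalues_calibrated(self, null_run):
        """No effects: per-SNP p-values are ~uniform and the 0.05 rejection
        rate sits inside the binomial 99% CI."""
        assoc = null_run["assoc"]
        ok = assoc[assoc["flag"] == "ok"]
        n = len(ok)
        assert n >= 2000
        frac = (ok["P"] < 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert 0.05 - half <= frac <= 0.05 + half
        assert kstest(ok["P"], "uniform").pvalue > 0.01

    def test_single_snp_odds_ratio_recovery(self):
        """One causal SNP at OR 2, maf 0.3, 2000+2000: the fitted odds
        ratio lands in [1.7, 2.4]."""
        var = pd.DataFrame(
            {"snp_id": ["s1"], "chrom": ["chr1"], "pos": [1000], "maf": [0.3]}
        )
        truth = TruthSpec(beta={"s1": float(np.log(2))})
        truth.alpha = simdata.calibrate_alpha(truth, var)
        cohort = simdata.simulate_cohort(var, truth, 2000, 2000, seed=3)
        rec = fit_snp_logistic(cohort, 0)
        assert 1.7 <= np.exp(rec.beta) <= 2.4

    def test_effect_recovery_within_3_se(self, power_run):
        from gwasea.gwas_assoc import minor_allele_flips

        assoc = power_run["assoc"].set_index("snp_id")
        truth = power_run["truth"]
        cohort = power_run["cohort"]
        flips = dict(zip(cohort.snp_ids, minor_allele_flips(cohort)))
        for snp, beta in truth.beta.items():
            expected = -beta if flips[snp] else beta
            row = assoc.loc[snp]
            assert abs(row["beta"] - expected) < 3 * row["se"]
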