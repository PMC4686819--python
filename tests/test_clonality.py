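"""CCF inversion, clone counting and gene-level clonality mapping."""

import numpy as np
import pandas as pd
import pytest

from brcaness.clonality import (TumorContext, cluster_genes, count_clones,
                                estimate_ccf, expected_vaf,
                                fit_scna_fraction, gene_clonality_map,
                                scna_clonality)


class TestEstimateCcf:
    def test_heterozygous_clonal(self):
        est = estimate_ccf(0.5, TumorContext("t", purity=1.0, cn_total=2))
        assert (est.multiplicity, est.ccf) == (1, pytest.approx(1.0))
        assert est.clonal

    def test_half_purity_algebra(self):
        est = estimate_ccf(0.25, TumorContext("t", purity=0.5, cn_total=2))
        assert est.multiplicity == 1
        assert est.ccf == pytest.approx(1.0)

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError, match="purity"):
            TumorContext("t", purity=0.0)

    def test_round_trip_identity_with_known_multiplicity(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            purity = rng.uniform(0.2, 1.0)
            cn = int(rng.integers(1, 6))
            m = int(rng.integers(1, cn + 1))
            ccf = rng.uniform(0.05, 1.0)
            vaf = expected_vaf(purity, ccf, m, cn)
            est = estimate_ccf(vaf, TumorContext("t", purity, cn),
                               multiplicity=m)
            assert est.ccf == pytest.approx(ccf, abs=1e-12)

    def test_noisefree_inversion_recovers_unit_ccf(self):
        # at CCF 1 the chosen multiplicity reproduces the VAF exactly
        for purity, cn, m in [(1.0, 2, 1), (0.8, 3, 2), (0.5, 4, 1)]:
            vaf = expected_vaf(purity, 1.0, m, cn)
            est = estimate_ccf(vaf, TumorContext("t", purity, cn))
            assert est.ccf == pytest.approx(1.0)

    def test_recovery_from_read_noise(self):
        """Two-clone tumor (CCFs 1.0 / 0.4) at depth 150: after clustering,
        >= 90% of variants get a cluster-center CCF within 0.1 of truth."""
        rng = np.random.default_rng(1)
        ctx = TumorContext("t", purity=1.0, cn_total=2)
        truths = np.repeat([1.0, 0.4], 500)
        raw = []
        for ccf in truths:
            depth = rng.poisson(150)
            vaf = rng.binomial(depth, expected_vaf(1.0, ccf, 1, 2)) / depth
            raw.append(estimate_ccf(min(vaf, 1.0), ctx, multiplicity=1).ccf)
        res = count_clones(raw)
        refined = res["centers"][res["labels"]]
        assert (np.abs(refined - truths) <= 0.1).mean() >= 0.9


class TestCountClones:
    def test_uniform_ccfs_are_one_clone(self):
        res = count_clones([1.0] * 20)
        assert res["n_clones"] == 1
        assert res["clonal"].all()

    def test_single_variant_is_one_clone(self):
        res = count_clones([0.7])
        assert res["n_clones"] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            count_clones([])

    def test_two_separated_clones_recovered(self):
        rng = np.random.default_rng(2)
        ccfs = np.concatenate([rng.normal(1.0, 0.05, 50),
                               rng.normal(0.3, 0.05, 50)])
        res = count_clones(ccfs)
        assert res["n_clones"] == 2
        assert abs(res["centers"][0] - 1.0) <= 0.1
        assert abs(res["centers"][1] - 0.3) <= 0.1
        # clonal flag marks exactly the high cluster
        assert res["clonal"].sum() == 50

    def test_subclonal_only_tumor_has_no_clonal_cluster(self):
        res = count_clones([0.4, 0.42, 0.38])
        assert res["n_clones"] == 1
        assert not res["clonal"].any()


class TestScnaClonality:
    @pytest.mark.parametrize("fraction,label", [
        (1.0, "clonal"), (0.9, "clonal"), (0.3, "subclonal"),
        (float("nan"), "unknown"), (None, "unknown"),
    ])
    def test_labels(self, fraction, label):
        assert scna_clonality(fraction) == label

    def test_fraction_fit_recovers_truth_on_noiseless_logratio(self):
        for purity, cn, f in [(1.0, 3, 0.8), (0.7, 1, 0.5), (0.9, 5, 0.25)]:
            mix = f * cn + (1 - f) * 2
            logr = np.log2((purity * mix + 2 * (1 - purity)) / 2)
            assert fit_scna_fraction(logr, purity, cn) == pytest.approx(
                f, abs=0.01)

    def test_planted_clonal_fraction_within_binomial_ci(self):
        from scipy import stats
        rng = np.random.default_rng(3)
        n = 200
        fractions = np.where(rng.random(n) < 0.6,
                             rng.uniform(0.9, 1.0, n),
                             rng.uniform(0.1, 0.8, n))
        labels = [scna_clonality(f) for f in fractions]
        clonal = labels.count("clonal")
        assert stats.binom.ppf(0.025, n, 0.6) <= clonal \
            <= stats.binom.ppf(0.975, n, 0.6)


def events_for(gene_hits):
    """gene_hits: list of (sample, chrom, start, end, clonality)."""
    return pd.DataFrame(gene_hits, columns=["sample", "chrom", "start",
                                            "end", "clonality"])


GENES = pd.DataFrame([
    dict(gene="BRCA2", chrom="chr1", start=1000, end=2000),
    dict(gene="TP53", chrom="chr2", start=1000, end=2000),
])


class TestGeneClonalityMap:
    def test_unhit_gene_is_origin(self):
        prof = gene_clonality_map(events_for([]), GENES, cohort_size=10)
        assert (prof[["clonal_freq", "subclonal_freq", "product"]] == 0) \
            .all().all()

    def test_pure_clonal_gene_has_zero_product(self):
        ev = events_for([(f"S{i}", "chr1", 0, 5000, "clonal")
                         for i in range(10)])
        prof = gene_clonality_map(ev, GENES, cohort_size=10)
        brca2 = prof.set_index("gene").loc["BRCA2"]
        assert brca2["clonal_freq"] == 1.0
        assert brca2["subclonal_freq"] == 0.0
        assert brca2["product"] == 0.0

    def test_product_arithmetic(self):
        ev = events_for(
            [(f"S{i}", "chr1", 0, 5000, "clonal") for i in range(5)]
            + [(f"S{i}", "chr1", 0, 5000, "subclonal") for i in range(5, 9)])
        prof = gene_clonality_map(ev, GENES, cohort_size=10)
        brca2 = prof.set_index("gene").loc["BRCA2"]
        assert brca2["product"] == pytest.approx(0.5 * 0.4)

    def test_frequency_invariant_to_event_splitting(self):
        whole = events_for([("S1", "chr1", 0, 5000, "clonal")])
        split = events_for([("S1", "chr1", 0, 1500, "clonal"),
                            ("S1", "chr1", 1500, 5000, "clonal")])
        a = gene_clonality_map(whole, GENES, 4)
        b = gene_clonality_map(split, GENES, 4)
        pd.testing.assert_frame_equal(a, b)

    def test_gene_without_interval_rejected(self):
        genes = pd.DataFrame([dict(gene="LOST", chrom=None, start=None,
                                   end=None)])
        with pytest.raises(ValueError, match="LOST"):
            gene_clonality_map(events_for([]), genes, 5)


class TestClusterGenes:
    def _profiles(self):
        rows = [dict(gene=f"G{i}", clonal_freq=0.0, subclonal_freq=0.0,
                     product=0.0) for i in range(67)]
        rows += [dict(gene="TP53", clonal_freq=0.9, subclonal_freq=0.5,
                      product=0.45),
                 dict(gene="RB1", clonal_freq=0.85, subclonal_freq=0.45,
                      product=0.3825)]
        return pd.DataFrame(rows)

    def test_two_identical_profiles_one_cluster(self):
        prof = pd.DataFrame([
            dict(gene="A", clonal_freq=0.5, subclonal_freq=0.5, product=0.25),
            dict(gene="B", clonal_freq=0.5, subclonal_freq=0.5, product=0.25),
        ])
        out = cluster_genes(prof, distance_cutoff=0.1)
        assert out["cluster"].nunique() == 1

    def test_outlying_genes_cluster_together_and_top_ranking(self):
        out = cluster_genes(self._profiles(), distance_cutoff=0.2)
        by_gene = out.set_index("gene")
        assert by_gene.loc["TP53", "cluster"] == by_gene.loc["RB1", "cluster"]
        assert by_gene.loc["G0", "cluster"] != by_gene.loc["TP53", "cluster"]
        assert set(out.nsmallest(2, "outlier_rank")["gene"]) \
            == {"TP53", "RB1"}

    def test_permutation_invariance_up_to_relabeling(self):
        prof = self._profiles()
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(prof))
        a = cluster_genes(prof, distance_cutoff=0.2).set_index("gene")
        b = cluster_genes(prof.iloc[perm].reset_index(drop=True),
                          distance_cutoff=0.2).set_index("gene")
        # partition identical: same co-membership for every gene pair
        genes = list(a.index)
        for i in range(0, len(genes), 7):
            for j in range(i + 1, len(genes), 11):
                same_a = a.loc[genes[i], "cluster"] == a.loc[genes[j], "cluster"]
                same_b = b.loc[genes[i], "cluster"] == b.loc[genes[j], "cluster"]
                assert same_a == same_b
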