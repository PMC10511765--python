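import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cassacore as cc
from cassacore.io_formats import PipelineError, SelectionMatrix
from cassacore.phenotype_consensus import ConsensusPhenotype

from oracles import diversity_oracle


class TestGeneticDiversity:
    def test_hand_worked_locus(self):
        """{AA, Aa, aa, Aa}: Ho=0.5, Hs=0.58333, Fis=0.142857."""
        dos = np.array([[2], [1], [0], [1]])
        g = cc.GenotypeMatrix(("a", "b", "c", "d"), ("l",), dos)
        s = cc.genetic_diversity_stats(g)
        assert s.per_locus["Ho"].iloc[0] == pytest.approx(0.5)
        assert s.per_locus["Hs"].iloc[0] == pytest.approx(0.58333, abs=1e-5)
        assert s.per_locus["Fis"].iloc[0] == pytest.approx(0.142857, abs=1e-6)

    def test_all_heterozygous_locus_gives_fis_minus_one(self):
        dos = np.ones((4, 1), dtype=np.int8)
        g = cc.GenotypeMatrix(("a", "b", "c", "d"), ("l",), dos)
        s = cc.genetic_diversity_stats(g)
        assert s.per_locus["Ho"].iloc[0] == 1.0
        assert s.per_locus["Hs"].iloc[0] == pytest.approx(0.5)
        assert s.per_locus["Fis"].iloc[0] == pytest.approx(-1.0)

    def test_monomorphic_locus_excluded_and_counted(self):
        dos = np.array([[2, 1], [2, 0], [2, 1]])
        g = cc.GenotypeMatrix(("a", "b", "c"), ("fixed", "poly"), dos)
        s = cc.genetic_diversity_stats(g)
        assert s.n_monomorphic == 1
        assert np.isnan(s.per_locus.loc["fixed", "Fis"])

    def test_matches_brute_force_oracle(self, random_genotypes):
        g = random_genotypes(50, 100, seed=7)
        s = cc.genetic_diversity_stats(g)
        for l, (ho, hs, fis) in enumerate(diversity_oracle(g.dosages)):
            row = s.per_locus.iloc[l]
            assert row["Ho"] == pytest.approx(ho, abs=1e-10)
            assert row["Hs"] == pytest.approx(hs, abs=1e-10)
            if not np.isnan(fis):
                assert row["Fis"] == pytest.approx(fis, abs=1e-10)

    def test_summary_fis_is_mean_of_per_locus_fis(self, random_genotypes):
        """Summaries average per-locus Fis, not 1 - mean(Ho)/mean(Hs)."""
        g = random_genotypes(30, 60, seed=8)
        s = cc.genetic_diversity_stats(g)
        per_locus = s.per_locus["Fis"].dropna()
        assert s.mean_fis == pytest.approx(per_locus.mean(), abs=1e-12)
        ratio_form = 1 - s.mean_ho / s.mean_hs
        assert s.mean_fis != pytest.approx(ratio_form, abs=1e-6)

    def test_subset_of_one_rejected(self, random_genotypes):
        g = random_genotypes(5, 10)
        with pytest.raises(PipelineError):
            cc.genetic_diversity_stats(g, [0])


class TestAlleleRetention:
    def test_full_subset_retains_everything(self, random_genotypes):
        g = random_genotypes(10, 20, seed=9)
        _, _, frac = cc.allele_retention(g, range(10))
        assert frac == 1.0

    def test_fixed_locus_in_subset_drops_one_allele(self):
        # complete: both alleles at each of 10 loci; subset fixes locus 0
        dos = np.array(
            [[0] + [1] * 9, [0] + [1] * 9, [2] + [1] * 9], dtype=np.int8
        )
        g = cc.GenotypeMatrix(("a", "b", "c"), tuple(f"l{i}" for i in range(10)), dos)
        in_sub, total, frac = cc.allele_retention(g, [0, 1])
        assert (in_sub, total) == (19, 20)
        assert frac == pytest.approx(0.95)

    def test_single_heterozygous_accession_keeps_both_alleles(self):
        dos = np.array([[1, 1], [0, 2]], dtype=np.int8)
        g = cc.GenotypeMatrix(("het", "hom"), ("l1", "l2"), dos)
        in_sub, _, _ = cc.allele_retention(g, [0])
        assert in_sub == 4

    def test_monotone_in_subset_growth(self, random_genotypes):
        g = random_genotypes(20, 40, seed=10)
        rng = np.random.default_rng(0)
        order = rng.permutation(20)
        prev = 0
        for k in range(2, 21):
            _, _, frac = cc.allele_retention(g, order[:k])
            assert frac >= prev - 1e-12
            prev = frac
        assert prev == 1.0


class TestShannonWeaver:
    def test_uniform_distribution_is_one(self):
        assert cc.shannon_weaver(
            [1, 2, 3, 1, 2, 3], "qualitative", classes=(1, 2, 3)
        ) == pytest.approx(1.0)

    def test_monomorphic_is_zero(self):
        assert cc.shannon_weaver(
            [2, 2, 2], "qualitative", classes=(1, 2, 3)
        ) == 0.0

    def test_hand_example(self):
        vals = [1, 1, 2, 3]  # frequencies (0.5, 0.25, 0.25)
        assert cc.shannon_weaver(
            vals, "qualitative", classes=(1, 2, 3)
        ) == pytest.approx(0.94639, abs=1e-5)

    def test_quantitative_six_bin_normalization(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 6, size=6000)
        val = cc.shannon_weaver(x, "quantitative", complete_range=(0, 6))
        assert val == pytest.approx(1.0, abs=0.01)
        assert cc.shannon_weaver(
            np.full(10, 3.0), "quantitative", complete_range=(0.0, 6.0)
        ) == 0.0

    def test_out_of_range_values_clamp_to_edge_bins(self):
        val = cc.shannon_weaver(
            [-5.0, 11.0], "quantitative", complete_range=(0.0, 10.0)
        )
        assert 0 < val <= 1

    def test_single_class_rejected(self):
        with pytest.raises(PipelineError):
            cc.shannon_weaver([1, 1], "qualitative", classes=(1,))

    def test_invariant_to_observation_order(self):
        vals = [3, 1, 2, 2, 3, 3]
        a = cc.shannon_weaver(vals, "qualitative", classes=(1, 2, 3))
        b = cc.shannon_weaver(vals[::-1], "qualitative", classes=(1, 2, 3))
        assert a == b


class TestKappa:
    def test_closed_forms(self):
        assert cc.kappa([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0
        assert cc.kappa([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)
        assert cc.kappa([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(-1.0)
        assert cc.kappa([0, 0, 0], [0, 0, 0]) == 1.0  # p_e = 1 degenerate case

    def test_symmetry_and_joint_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, size=50)
        b = rng.integers(0, 2, size=50)
        assert cc.kappa(a, b) == pytest.approx(cc.kappa(b, a))
        assert cc.kappa(1 - a, 1 - b) == pytest.approx(cc.kappa(a, b))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 60))
    def test_against_sklearn_oracle(self, seed, n):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, size=n)
        b = rng.integers(0, 2, size=n)
        if np.array_equal(a, b) or len(np.unique(np.r_[a, b])) < 2:
            return
        expected = cohen_kappa_score(a, b)
        if np.isnan(expected):
            return
        assert cc.kappa(a, b) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(PipelineError):
            cc.kappa([1, 0], [1, 0, 0])

    def test_kappa_matrix_structure(self):
        sel = SelectionMatrix(
            accession_ids=("a", "b", "c", "d"),
            method_names=("m1", "m2"),
            membership=np.array([[1, 1], [1, 0], [0, 1], [0, 0]]),
        )
        km = cc.kappa_matrix(sel)
        assert np.allclose(np.diag(km), 1.0)
        assert km.loc["m1", "m2"] == km.loc["m2", "m1"]


def _consensus_and_selection(n=30, seed=0):
    rng = np.random.default_rng(seed)
    catalog = cc.TraitCatalog(
        (
            cc.TraitSpec("q", "quantitative"),
            cc.TraitSpec("c", "qualitative", (1, 2, 3)),
        )
    )
    data = pd.DataFrame(
        {
            "q": rng.normal(10, 2, size=n),
            "c": rng.integers(1, 4, size=n),
        },
        index=[f"A{i}" for i in range(n)],
    )
    cp = ConsensusPhenotype(data=data, catalog=catalog)
    member = np.zeros((n, 2), dtype=int)
    member[: n // 3, 0] = 1
    member[n // 3 : 2 * n // 3, 1] = 1
    sel = SelectionMatrix(
        accession_ids=tuple(data.index),
        method_names=("m1", "m2"),
        membership=member,
    )
    return cp, sel


class TestCompareDistributions:
    def test_core_equal_to_complete_has_no_flags(self):
        cp, _ = _consensus_and_selection()
        n = len(cp.data)
        sel = SelectionMatrix(
            accession_ids=tuple(cp.data.index),
            method_names=("all",),
            membership=np.ones((n, 1), dtype=int),
        )
        rep = cc.compare_distributions(cp, sel)
        quant = rep[rep["kind"] == "quantitative"]
        assert (quant["rel_mean_diff"].abs() < 1e-12).all()
        assert not quant["mean_flag"].any() and not quant["var_flag"].any()
        qual = rep[rep["kind"] == "qualitative"]
        assert (qual["class_coverage"] == 1.0).all()

    def test_variance_inflation_flagged_beyond_fifty_percent(self):
        """A core variance of 135 against 79.31 (+70%) must be flagged."""
        catalog = cc.TraitCatalog((cc.TraitSpec("q", "quantitative"),))
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, size=200)
        core_idx = np.argsort(np.abs(base))[-40:]  # extreme tails: inflated var
        data = pd.DataFrame({"q": base * np.sqrt(79.31)}, index=[f"A{i}" for i in range(200)])
        member = np.zeros((200, 1), dtype=int)
        member[core_idx] = 1
        sel = SelectionMatrix(tuple(data.index), ("tails",), member)
        rep = cc.compare_distributions(
            ConsensusPhenotype(data=data, catalog=catalog), sel
        )
        row = rep.iloc[0]
        assert row["rel_var_diff"] > 0.5
        assert row["var_flag"]

    def test_missing_class_reduces_coverage(self):
        cp, sel = _consensus_and_selection(seed=1)
        # restrict method 1 to accessions of class 1 only
        classes = cp.data["c"].to_numpy()
        member = np.zeros((len(classes), 1), dtype=int)
        member[np.flatnonzero(classes == 1)[:5]] = 1
        sel = SelectionMatrix(tuple(cp.data.index), ("only1",), member)
        rep = cc.compare_distributions(cp, sel)
        cov = rep[rep["kind"] == "qualitative"]["class_coverage"].iloc[0]
        assert cov < 1.0

    def test_empty_collection_rejected(self):
        cp, _ = _consensus_and_selection()
        sel = SelectionMatrix(
            tuple(cp.data.index), ("empty",), np.zeros((len(cp.data), 1), dtype=int)
        )
        with pytest.raises(PipelineError, match="empty"):
            cc.compare_distributions(cp, sel)


class TestPca:
    def test_rank_one_data_loads_on_first_component(self):
        n = 20
        t = np.linspace(-1, 1, n)
        dos = np.clip(np.round(t[:, None] * np.ones(5) + 1), 0, 2).astype(np.int8)
        g = cc.GenotypeMatrix(
            tuple(f"A{i}" for i in range(n)), tuple(f"l{j}" for j in range(5)), dos
        )
        sel = SelectionMatrix(
            g.accession_ids, ("m",), np.ones((n, 1), dtype=int)
        )
        res = cc.pca_validate(None, g, sel)["genotype"]
        assert res.variance_explained[0] == pytest.approx(100.0, abs=1e-6)

    def test_symmetric_cloud_has_uniform_quadrants(self):
        rng = np.random.default_rng(4)
        n = 2000
        data = pd.DataFrame(
            rng.normal(size=(n, 2)), columns=["q1", "q2"],
            index=[f"A{i}" for i in range(n)],
        )
        catalog = cc.TraitCatalog(
            (cc.TraitSpec("q1", "quantitative"), cc.TraitSpec("q2", "quantitative"))
        )
        sel = SelectionMatrix(
            tuple(data.index), ("m",), np.ones((n, 1), dtype=int)
        )
        res = cc.pca_validate(
            ConsensusPhenotype(data=data, catalog=catalog), None, sel
        )["phenotype"]
        shares = res.quadrant_shares.loc["complete"].to_numpy()
        assert shares.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(shares, 0.25, atol=0.05)

    def test_variance_explained_is_nonincreasing_and_bounded(self, random_genotypes):
        g = random_genotypes(25, 40, seed=11)
        sel = SelectionMatrix(
            g.accession_ids, ("m",), np.ones((25, 1), dtype=int)
        )
        res = cc.pca_validate(None, g, sel)["genotype"]
        ve = res.variance_explained
        assert ve.sum() <= 100 + 1e-9
        assert (np.diff(ve) <= 1e-9).all()

    def test_zero_variance_features_rejected(self):
        data = pd.DataFrame(
            {"q": [1.0, 1.0, 1.0]}, index=["a", "b", "c"]
        )
        catalog = cc.TraitCatalog((cc.TraitSpec("q", "quantitative"),))
        sel = SelectionMatrix(("a", "b", "c"), ("m",), np.ones((3, 1), dtype=int))
        with pytest.raises(PipelineError):
            cc.pca_validate(
                ConsensusPhenotype(data=data, catalog=catalog), None, sel
            )


class TestIswReport:
    def test_report_covers_all_traits_and_collections(self):
        cp, sel = _consensus_and_selection(seed=5)
        rep = cc.isw_report(cp, sel)
        assert set(rep["trait_id"]) == {"q", "c"}
        assert set(rep["collection"]) == {"m1", "m2"}
        assert ((rep["isw"] >= 0) & (rep["isw"] <= 1)).all()

    def test_flag_threshold(self):
        cp, sel = _consensus_and_selection(seed=6)
        rep = cc.isw_report(cp, sel, flag_threshold=0.0)
        changed = rep["delta"].abs() > 0
        assert (rep.loc[changed, "flagged"]).all()
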