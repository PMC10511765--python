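import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cassacore as cc
from cassacore.io_formats import PipelineError
from cassacore.phenotype_consensus import ConsensusPhenotype

from oracles import czekanowski_pair, modified_rogers_pair


def _consensus(data: dict, catalog: cc.TraitCatalog) -> ConsensusPhenotype:
    return ConsensusPhenotype(data=pd.DataFrame(data), catalog=catalog)


MIXED_CATALOG = cc.TraitCatalog(
    (
        cc.TraitSpec("size", "quantitative"),
        cc.TraitSpec("color", "qualitative", (1, 2, 3)),
    )
)


class TestGower:
    def test_hand_example(self):
        """Quantitative |d|/R = 0.5 plus qualitative mismatch: (0.5+1)/2."""
        cp = _consensus(
            {"size": [0.0, 5.0, 10.0], "color": [1, 2, 1]}, MIXED_CATALOG
        )
        d = cc.gower_distance(cp)
        assert d.values[0, 1] == pytest.approx(0.75)
        assert d.values[0, 2] == pytest.approx(0.5)  # same color, half range

    def test_missing_value_reweights_pair(self):
        cp = _consensus(
            {"size": [0.0, 5.0, 10.0], "color": [pd.NA, 2, 1]}, MIXED_CATALOG
        )
        d = cc.gower_distance(cp)
        assert d.values[0, 1] == pytest.approx(0.5)  # only quantitative term

    def test_identical_profiles_have_zero_distance(self):
        cp = _consensus({"size": [1.0, 1.0, 3.0], "color": [2, 2, 1]}, MIXED_CATALOG)
        assert cc.gower_distance(cp).values[0, 1] == 0.0

    def test_constant_trait_dropped_with_warning(self):
        cp = _consensus({"size": [2.0, 2.0], "color": [1, 2]}, MIXED_CATALOG)
        with pytest.warns(UserWarning, match="constant"):
            d = cc.gower_distance(cp)
        assert d.values[0, 1] == 1.0  # only the qualitative mismatch remains

    def test_pair_without_shared_traits_errors(self):
        cp = _consensus(
            {"size": [1.0, np.nan, 2.0], "color": [pd.NA, 1, 1]}, MIXED_CATALOG
        )
        with pytest.raises(PipelineError, match="share no"):
            cc.gower_distance(cp)

    def test_frozen_ranges_keep_subset_distances_comparable(self):
        cp = _consensus(
            {"size": [0.0, 5.0, 10.0], "color": [1, 1, 1]}, MIXED_CATALOG
        )
        ranges = cc.complete_ranges(cp)
        sub = ConsensusPhenotype(data=cp.data.iloc[:2], catalog=MIXED_CATALOG)
        d = cc.gower_distance(sub, ranges=ranges)
        assert d.values[0, 1] == pytest.approx((5.0 / 10.0 + 0.0) / 2)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        cp = _consensus(
            {
                "size": rng.normal(size=6),
                "color": rng.integers(1, 4, size=6),
            },
            MIXED_CATALOG,
        )
        d = cc.gower_distance(cp).values
        perm = rng.permutation(6)
        cp2 = ConsensusPhenotype(data=cp.data.iloc[perm], catalog=MIXED_CATALOG)
        d2 = cc.gower_distance(cp2).values
        np.testing.assert_allclose(d2, d[np.ix_(perm, perm)], atol=1e-12)


class TestSnpDistances:
    def test_identical_rows_give_zero(self, random_genotypes):
        g = random_genotypes(2, 10, seed=1)
        dos = np.vstack([g.dosages[0], g.dosages[0]])
        g2 = cc.GenotypeMatrix(("a", "b"), g.locus_ids, dos)
        assert cc.modified_rogers(g2).values[0, 1] == 0.0
        assert cc.czekanowski_manhattan(g2).values[0, 1] == 0.0

    def test_opposite_homozygotes_give_one(self):
        l = 7
        dos = np.array([[2] * l, [0] * l], dtype=np.int8)
        g = cc.GenotypeMatrix(("a", "b"), tuple(f"l{i}" for i in range(l)), dos)
        assert cc.modified_rogers(g).values[0, 1] == pytest.approx(1.0)
        assert cc.czekanowski_manhattan(g).values[0, 1] == pytest.approx(1.0)

    def test_single_locus_het_vs_hom_is_half(self):
        g = cc.GenotypeMatrix(("a", "b"), ("l",), np.array([[1], [0]]))
        assert cc.modified_rogers(g).values[0, 1] == pytest.approx(0.5)
        assert cc.czekanowski_manhattan(g).values[0, 1] == pytest.approx(0.5)

    def test_fast_path_equals_explicit_allele_sum(self, random_genotypes):
        g = random_genotypes(8, 25, seed=2)
        fast = cc.modified_rogers(g).values
        explicit = cc.modified_rogers(g, explicit=True).values
        np.testing.assert_allclose(fast, explicit, atol=1e-12)

    def test_against_straight_from_formula_oracle(self, random_genotypes):
        g = random_genotypes(10, 20, seed=3)
        mr = cc.modified_rogers(g).values
        cz = cc.czekanowski_manhattan(g).values
        for i in range(10):
            for j in range(10):
                assert mr[i, j] == pytest.approx(
                    modified_rogers_pair(g.dosages[i], g.dosages[j]), abs=1e-12
                )
                assert cz[i, j] == pytest.approx(
                    czekanowski_pair(g.dosages[i], g.dosages[j]), abs=1e-12
                )

    def test_missing_dosages_rejected(self):
        dos = np.array([[1, cc.MISSING], [0, 2]], dtype=np.int8)
        g = cc.GenotypeMatrix(("a", "b"), ("l1", "l2"), dos)
        with pytest.raises(PipelineError, match="impute"):
            cc.modified_rogers(g)
        with pytest.raises(PipelineError, match="impute"):
            cc.czekanowski_manhattan(g)


class TestBlend:
    def test_identity_arithmetic_and_convexity(self, random_genotypes):
        g = random_genotypes(5, 12, seed=4)
        d1 = cc.modified_rogers(g)
        d2 = cc.czekanowski_manhattan(g)
        np.testing.assert_allclose(
            cc.blend_distances(d1, d2, 1.0).values, d1.values, atol=1e-15
        )
        mixed = cc.blend_distances(d1, d2, 0.5).values
        np.testing.assert_allclose(mixed, 0.5 * d1.values + 0.5 * d2.values)
        assert mixed.min() >= 0 and mixed.max() <= 1

    def test_mismatched_registries_error(self, random_genotypes):
        g = random_genotypes(4, 6, seed=5)
        d1 = cc.modified_rogers(g)
        g2 = cc.GenotypeMatrix(
            tuple(f"B{i}" for i in range(4)), g.locus_ids, g.dosages
        )
        with pytest.raises(PipelineError, match="registries"):
            cc.blend_distances(d1, cc.czekanowski_manhattan(g2))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(3, 12),
    l=st.integers(2, 30),
)
def test_metric_axioms_hold_on_random_genotypes(seed, n, l):
    """Zero diagonal, symmetry and [0,1] range for the SNP distances."""
    rng = np.random.default_rng(seed)
    dos = rng.integers(0, 3, size=(n, l)).astype(np.int8)
    g = cc.GenotypeMatrix(
        tuple(f"A{i}" for i in range(n)), tuple(f"l{j}" for j in range(l)), dos
    )
    for d in (cc.modified_rogers(g), cc.czekanowski_manhattan(g)):
        v = d.values
        assert np.abs(np.diag(v)).max() == 0.0
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        assert v.min() >= 0.0 and v.max() <= 1.0
        # Manhattan mean never exceeds the quadratic-mean form
        if d.kind == "czekanowski":
            np.testing.assert_array_less(
                v, cc.modified_rogers(g).values + 1e-9
            )
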