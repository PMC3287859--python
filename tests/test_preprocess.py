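"""MAF arithmetic, filtering, duplicate collapsing, standardization, LD."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from snplasso.core_data import ValidationError
from snplasso.preprocess import (
    collapse_duplicates,
    compute_maf,
    compute_mafs,
    filter_by_maf,
    ld_screen,
    pairwise_r2,
    standardize,
    standardize_arrays,
)
from snplasso.simulate import SimConfig, simulate_genotypes

from conftest import make_genotypes, make_phenotypes


class TestComputeMaf:
    @pytest.mark.parametrize(
        "col,expected",
        [
            ([0, 0, 0, 0], 0.0),
            ([2, 2, 2, 2], 0.0),  # folded
            ([0, 1, 2, 1], 0.5),  # 4/8 by hand
            ([1, 0, 0, 0, 0], 0.1),
        ],
    )
    def test_examples(self, col, expected):
        assert compute_maf(np.array(col)) == pytest.approx(expected)

    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=60))
    def test_flip_invariance(self, col):
        a = np.array(col)
        assert compute_maf(a) == pytest.approx(compute_maf(2 - a))
        assert 0.0 <= compute_maf(a) <= 0.5

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            compute_maf(np.array([], dtype=int))


class TestFilterByMaf:
    def test_boundary_is_inclusive(self):
        # 50 individuals: one heterozygote -> f = 1/100 = 0.01 exactly
        dos = np.zeros((50, 2), dtype=np.int8)
        dos[0, 0] = 1  # maf 0.01: retained
        g = make_genotypes(np.random.default_rng(0), 50, [0.3])
        g.dosages = np.column_stack([dos[:, 0], dos[:, 1], g.dosages[:, 0]]).astype(
            np.int8
        )
        from snplasso.core_data import SnpInfo

        g.snps = [SnpInfo("at_boundary"), SnpInfo("mono"), SnpInfo("common")]
        out = filter_by_maf(g, 0.01)
        assert out.snp_ids == ["at_boundary", "common"]

    def test_constructed_counts_and_idempotence(self, rng):
        mafs = [0.005, 0.3, 0.008, 0.2, 0.009, 0.4, 0.1, 0.15, 0.25, 0.35]
        n = 4000  # large n so realized MAFs stay on their side of 0.01
        g = make_genotypes(rng, n, mafs)
        out = filter_by_maf(g, 0.01)
        assert out.n_snps == 7
        again = filter_by_maf(out, 0.01)
        assert again.snp_ids == out.snp_ids

    def test_retained_count_monotone_in_threshold(self, rng):
        g = make_genotypes(rng, 500, list(np.linspace(0.02, 0.45, 20)))
        counts = [filter_by_maf(g, t).n_snps for t in (0.0, 0.05, 0.1, 0.3)]
        assert counts == sorted(counts, reverse=True)

    def test_table1_mafs_all_pass_default_filter(self):
        from snplasso.simulate import TABLE1_CAUSAL_SNPS

        assert all(s.maf >= 0.01 for s in TABLE1_CAUSAL_SNPS)


class TestCollapseDuplicates:
    def test_pairs_collapse_to_representatives(self, rng):
        g = make_genotypes(rng, 30, [0.2 + 0.008 * j for j in range(35)])
        # duplicate 5 columns to build 5 pairs -> 40 columns total
        dup = g.dosages[:, :5]
        from snplasso.core_data import GenotypeMatrix, SnpInfo

        dosages = np.column_stack([g.dosages, dup]).astype(np.int8)
        snps = g.snps + [SnpInfo(f"dup{j}") for j in range(5)]
        g40 = GenotypeMatrix(g.samples, snps, dosages)
        out, groups = collapse_duplicates(g40)
        assert g40.n_snps == 35 + 5
        assert out.n_snps == 35
        # first-in-input-order member is the representative
        assert set(groups) <= set(g.snp_ids[:5])
        # re-expansion recovers every original id
        expanded = set(out.snp_ids)
        for rep, members in groups.items():
            expanded |= set(members)
        assert expanded == set(g40.snp_ids)

    def test_no_duplicates_is_identity(self, rng):
        g = make_genotypes(rng, 50, [0.1, 0.2, 0.3])
        out, groups = collapse_duplicates(g)
        assert out.snp_ids == g.snp_ids and groups == {}


class TestStandardize:
    def test_two_point_column(self):
        d = standardize_arrays(
            np.array([[0.0], [2.0]]),
            np.empty((2, 0)),
            np.array([1.0, 3.0]),
            ["a"],
            [],
        )
        np.testing.assert_allclose(d.X[:, 0], [-1.0, 1.0])
        np.testing.assert_allclose(d.y, [-1.0, 1.0])

    def test_columns_centered_unit_variance(self, rng):
        g = make_genotypes(rng, 80, [0.2, 0.35, 0.5])
        p = make_phenotypes(rng, list(g.samples), {"r": rng.standard_normal(80)})
        d = standardize(g, p, "r")
        assert np.abs(d.X.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(d.X.var(axis=0), 1.0, atol=1e-8)
        np.testing.assert_allclose(d.Z.var(axis=0), 1.0, atol=1e-8)
        assert abs(d.y.mean()) < 1e-10

    def test_idempotent(self, rng):
        d = standardize_arrays(
            rng.standard_normal((30, 4)),
            rng.standard_normal((30, 2)),
            rng.standard_normal(30),
            list("abcd"),
            ["u", "v"],
        )
        d2 = standardize_arrays(d.X, d.Z, d.y, d.snp_ids, d.covariate_names)
        np.testing.assert_allclose(d2.X, d.X, atol=1e-12)
        np.testing.assert_allclose(d2.Z, d.Z, atol=1e-12)
        np.testing.assert_allclose(d2.y, d.y, atol=1e-12)

    def test_zero_variance_column_rejected_by_name(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 5.0
        with pytest.raises(ValidationError, match="col_b"):
            standardize_arrays(
                X, np.empty((20, 0)), rng.standard_normal(20),
                ["col_a", "col_b", "col_c"], [],
            )

    def test_back_transformed_ols_matches_raw_scale_ols(self, rng):
        # standardized-scale coefficients map back to the raw-scale OLS fit
        X = rng.standard_normal((20, 3)) * [1.0, 4.0, 0.5] + [2.0, -1.0, 0.0]
        y = X @ [0.5, -0.25, 1.5] + rng.standard_normal(20) * 0.3
        d = standardize_arrays(X, np.empty((20, 0)), y, list("abc"), [])
        coef_std = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        raw_slopes = coef_std / d.x_scale
        raw_intercept = d.y_mean - float(raw_slopes @ d.x_mean)
        oracle = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(raw_intercept, oracle.params[0], atol=1e-8)
        np.testing.assert_allclose(raw_slopes, oracle.params[1:], atol=1e-8)


class TestPairwiseR2:
    def test_identity_and_flip(self, rng):
        a = rng.binomial(2, 0.3, 100)
        a[0] = 1  # ensure non-constant
        assert pairwise_r2(a, a) == pytest.approx(1.0)
        assert pairwise_r2(a, 2 - a) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        a = rng.binomial(2, 0.3, 10_000)
        b = rng.binomial(2, 0.3, 10_000)
        assert pairwise_r2(a, b) < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pairwise_r2(np.zeros(10), np.arange(10) % 3)


class TestLdScreen:
    def test_duplicate_partner_found(self, rng):
        g = make_genotypes(rng, 60, [0.3, 0.4, 0.25])
        from snplasso.core_data import GenotypeMatrix, SnpInfo

        g2 = GenotypeMatrix(
            g.samples,
            g.snps + [SnpInfo("copy_of_0")],
            np.column_stack([g.dosages, g.dosages[:, 0]]).astype(np.int8),
        )
        tab = ld_screen(g2, ["snp0"])
        row = tab.iloc[0]
        assert row.best_partner == "copy_of_0"
        assert row.best_r2 == pytest.approx(1.0)
        assert row.above_threshold

    def test_independent_panel_below_threshold(self, rng):
        g = make_genotypes(rng, 5000, [0.3] * 8)
        tab = ld_screen(g, g.snp_ids, threshold=0.1)
        assert (tab.best_r2 < 0.1).all()

    def test_generator_ld_block_partner_detected(self):
        cfg = SimConfig(
            n_individuals=2000, n_null_snps=10, ld_blocks=((2, 0.7),),
            causal_table=(), seed=8,
        )
        g = simulate_genotypes(cfg)
        tab = ld_screen(g, [g.snp_ids[0]])
        assert tab.iloc[0].best_partner == g.snp_ids[1]
        assert tab.iloc[0].best_r2 > 0.1


def test_realized_maf_vector_matches_declared(rng):
    mafs = [0.05, 0.2, 0.45]
    g = make_genotypes(rng, 20_000, mafs)
    np.testing.assert_allclose(compute_mafs(g), mafs, atol=0.01)
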