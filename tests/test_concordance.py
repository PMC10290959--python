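import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gmconcord.concordance import (
    PairCounts,
    StratifiedPairSample,
    bh_adjust,
    concordance_from_counts,
    concordance_test,
    null_variance,
    pair_counts_stratified,
    run_meta_screen,
    scale_concordance,
    z_pvalue,
)
from gmconcord.datamodel import AnalysisConfig, GmcError


def enumerate_pairs(x, y, stratum, weight):
    """Independent O(n^2) oracle: explicit loop over all index pairs."""
    out = PairCounts()
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if stratum[i] != stratum[j]:
                continue
            w = weight[i] * weight[j]
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                out.T_xy += w
            elif dx == 0:
                out.T_x += w
                out.n_comparable += 1
            elif dy == 0:
                out.T_y += w
            elif dx == dy:
                out.C += w
                out.n_comparable += 1
            else:
                out.D += w
                out.n_comparable += 1
    return out


class TestPairCounts:
    def test_monotone_sequences(self):
        pc = pair_counts_stratified(
            StratifiedPairSample([1, 2, 3], [1, 2, 3], [0] * 3, [1.0] * 3)
        )
        assert (pc.C, pc.D) == (3.0, 0.0)
        assert pc.T_x == pc.T_y == pc.T_xy == 0.0

    def test_reversal(self):
        pc = pair_counts_stratified(
            StratifiedPairSample([1, 2, 3], [3, 2, 1], [0] * 3, [1.0] * 3)
        )
        assert (pc.C, pc.D) == (0.0, 3.0)

    def test_tied_example_all_six_pairs(self):
        pc = pair_counts_stratified(
            StratifiedPairSample(
                [1, 2, 2, 4], [1, 3, 2, 2], [0] * 4, [1.0] * 4
            )
        )
        assert (pc.C, pc.D, pc.T_x, pc.T_y, pc.T_xy) == (3, 1, 1, 1, 0)

    def test_cross_stratum_pairs_excluded(self):
        pc = pair_counts_stratified(
            StratifiedPairSample(
                [1, 2, 5, 6], [1, 2, 1, 0], ["a", "a", "b", "b"], [1.0] * 4
            )
        )
        assert (pc.C, pc.D) == (1.0, 1.0)

    def test_all_small_strata_rejected(self):
        with pytest.raises(GmcError, match="no comparable pairs"):
            pair_counts_stratified(
                StratifiedPairSample([1, 2], [1, 2], ["a", "b"])
            )

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            n = rng.integers(3, 40)
            k = rng.integers(1, 5)
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            strat = rng.integers(0, k, size=n)
            sample = StratifiedPairSample(x, y, strat)
            got = pair_counts_stratified(sample)
            want = enumerate_pairs(x, y, strat, sample.weight)
            for f in ("C", "D", "T_x", "T_y", "T_xy"):
                assert getattr(got, f) == pytest.approx(getattr(want, f))
            assert got.n_comparable == want.n_comparable

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 8), st.integers(0, 8), st.integers(0, 2)
            ),
            min_size=3,
            max_size=25,
        ),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_monotone_transform_invariance(self, rows, transform):
        x = np.array([r[0] for r in rows], dtype=float)
        y = np.array([r[1] for r in rows], dtype=float)
        strat = np.array([r[2] for r in rows])
        f = {
            "exp": np.exp,
            "cube": lambda v: v**3,
            "affine": lambda v: 2.5 * v + 7,
        }[transform]
        try:
            base = pair_counts_stratified(StratifiedPairSample(x, y, strat))
        except GmcError:
            return
        trans = pair_counts_stratified(
            StratifiedPairSample(f(x), f(y), strat)
        )
        for fld in ("C", "D", "T_x", "T_y", "T_xy"):
            assert getattr(base, fld) == pytest.approx(getattr(trans, fld))

    def test_antisymmetry_under_y_negation(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        a = pair_counts_stratified(StratifiedPairSample(x, y, [0] * 30))
        b = pair_counts_stratified(StratifiedPairSample(x, -y, [0] * 30))
        assert a.C == pytest.approx(b.D) and a.D == pytest.approx(b.C)
        ca = concordance_from_counts(a)
        cb = concordance_from_counts(b)
        assert scale_concordance(ca) == pytest.approx(-scale_concordance(cb))

    def test_stratum_pair_mass_is_size_balanced(self, rng):
        # with w = 1/n_d the total pair mass of a stratum is (n_d-1)/(2 n_d)
        for n in (3, 10, 57):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            pc = pair_counts_stratified(
                StratifiedPairSample(x, y, [0] * n)
            )
            assert pc.mass_total == pytest.approx((n - 1) / (2 * n))


class TestConcordanceFraction:
    def test_perfect(self):
        pc = PairCounts(C=3)
        assert concordance_from_counts(pc, "half_tie") == 1.0
        assert concordance_from_counts(pc, "full_tie") == 1.0

    def test_tie_policies_differ_as_defined(self):
        pc = PairCounts(C=1, D=1, T_x=2)
        assert concordance_from_counts(pc, "full_tie") == pytest.approx(0.75)
        assert concordance_from_counts(pc, "half_tie") == pytest.approx(0.5)

    def test_symmetry_point(self):
        pc = PairCounts(C=5, D=5)
        assert concordance_from_counts(pc) == 0.5

    def test_zero_denominator_flagged_not_raised(self):
        assert np.isnan(concordance_from_counts(PairCounts(T_y=4.0)))

    def test_scaling(self):
        assert scale_concordance(0.5) == 0.0
        assert scale_concordance(1.0) == 1.0
        assert scale_concordance(0.0) == -1.0


class TestNullVariance:
    def test_analytic_close_to_permutation(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        s = StratifiedPairSample(x, y, np.zeros(50))
        va = null_variance(s, "analytic")
        vp = null_variance(s, "permutation", n_perm=10000, seed=0)
        assert va == pytest.approx(vp, rel=0.10)

    def test_analytic_close_to_permutation_with_ties_and_strata(self, rng):
        x = rng.integers(0, 5, size=60).astype(float)
        y = rng.integers(0, 4, size=60).astype(float)
        strat = rng.integers(0, 3, size=60)
        s = StratifiedPairSample(x, y, strat)
        va = null_variance(s, "analytic")
        vp = null_variance(s, "permutation", n_perm=10000, seed=1)
        assert va == pytest.approx(vp, rel=0.10)

    def test_weight_scaling_leaves_z_invariant(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            strat = rng.integers(0, 2, size=n)
            base = concordance_test(x, y, strat)
            w2 = StratifiedPairSample(x, y, strat).weight * 2.0
            doubled = concordance_test(x, y, strat, weight=w2)
            assert doubled.z == pytest.approx(base.z)

    def test_degenerate_constant_y_flagged(self):
        res = concordance_test([1, 2, 3, 4], [5, 5, 5, 5])
        assert np.isnan(res.c) and np.isnan(res.p)

    def test_small_permutation_count_rejected(self, rng):
        s = StratifiedPairSample(rng.normal(size=10), rng.normal(size=10),
                                 np.zeros(10))
        with pytest.raises(GmcError, match="100"):
            null_variance(s, "permutation", n_perm=50)


class TestZAndBH:
    def test_null_point(self):
        z, p = z_pvalue(0.5, 0.01)
        assert z == 0.0 and p == 1.0

    def test_normal_quantile(self):
        v = 0.004
        z, p = z_pvalue(0.5 + 1.959964 * np.sqrt(v), v)
        assert p == pytest.approx(0.05, rel=1e-4)

    def test_z_sign_matches_scaled_concordance(self, rng):
        for _ in range(20):
            c = rng.uniform(0.0, 1.0)
            z, _ = z_pvalue(c, 0.01)
            assert np.sign(z) == np.sign(scale_concordance(c))

    def test_nonpositive_variance_flagged(self):
        z, p = z_pvalue(0.7, 0.0)
        assert np.isnan(z) and np.isnan(p)

    def test_bh_single_and_step_up(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_bh_monotone_in_rank(self, rng):
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestKendallEquivalence:
    def test_c_scaled_equals_tau_a_without_ties(self, rng):
        for n in (10, 25, 60):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = concordance_test(x, y)
            tau = stats.kendalltau(x, y).statistic
            assert res.c_scaled == pytest.approx(tau, abs=1e-12)


class TestMetaScreen:
    def _matrices(self, rng, n_ds=3, n_x=4, n_y=5, n=12):
        xs, ys = {}, {}
        for d in range(n_ds):
            cols = [f"D{d}_S{i}" for i in range(n)]
            import pandas as pd

            xs[f"D{d}"] = pd.DataFrame(
                rng.normal(size=(n_x, n)),
                index=[f"M{i}" for i in range(n_x)], columns=cols,
            )
            ys[f"D{d}"] = pd.DataFrame(
                rng.normal(size=(n_y, n)),
                index=[f"G{i}" for i in range(n_y)], columns=cols,
            )
        return xs, ys

    def test_grid_is_full_cross_product(self, rng):
        xs, ys = self._matrices(rng)
        t = run_meta_screen(xs, ys, [f"M{i}" for i in range(4)],
                            [f"G{i}" for i in range(5)])
        assert len(t) == 20
        assert list(t.columns[:2]) == ["x_id", "y_id"]

    def test_uncovered_pair_reported_but_untested(self, rng):
        xs, ys = self._matrices(rng, n_ds=2)
        t = run_meta_screen(xs, ys, ["M0", "ABSENT"], ["G0"])
        row = t[t.x_id == "ABSENT"].iloc[0]
        assert row.n_datasets == 0 and np.isnan(row.p) and np.isnan(row.q)
        assert not row.significant

    def test_pair_in_single_dataset_excluded_from_bh(self, rng):
        xs, ys = self._matrices(rng, n_ds=2)
        xs["D1"] = xs["D1"].drop(index="M0")
        t = run_meta_screen(xs, ys, ["M0"], ["G0"]).iloc[0]
        assert t.n_datasets == 1
        assert np.isfinite(t.p) and np.isnan(t.q)

    def test_significant_set_monotone_in_fdr(self, rng):
        xs, ys = self._matrices(rng, n_ds=3, n_x=5, n_y=5, n=20)
        sizes = []
        for alpha in (0.01, 0.05, 0.2, 0.8):
            t = run_meta_screen(xs, ys, list(xs["D0"].index),
                                list(ys["D0"].index), fdr=alpha)
            sizes.append(int(t.significant.sum()))
        assert sizes == sorted(sizes)
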