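"""SAM statistic, fudge factor, pooled permutation null, BH adjustment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from netmark.containers import PhenotypeLabels
from netmark.errors import DegenerateInputError, ParameterError
from netmark.sam import (
    SamConfig,
    bh_adjust,
    call_degs,
    estimate_s0,
    permutation_pvalues,
    sam_statistic,
)
from netmark.synthetic import generate_expression
from netmark.preprocess import log2_transform, normalize_global

from conftest import make_em, make_labels


class TestSamStatistic:
    def test_zero_within_group_variance(self):
        em = make_em([[3, 3, 1, 1]])
        d, s = sam_statistic(em, make_labels(2, 2), s0=0.5)
        assert s[0] == 0.0
        assert d[0] == pytest.approx(2 / 0.5)

    def test_identical_groups_give_zero(self):
        em = make_em([[1, 5, 1, 5]])
        d, _ = sam_statistic(em, make_labels(2, 2), s0=0.1)
        assert d[0] == pytest.approx(0.0)

    def test_equals_two_sample_t_when_s0_is_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 10))
        em = make_em(x)
        d, _ = sam_statistic(em, make_labels(5, 5), s0=0.0)
        t_ref = stats.ttest_ind(x[:, :5], x[:, 5:], axis=1, equal_var=True).statistic
        np.testing.assert_allclose(d, t_ref, atol=1e-10)

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(1)
        em = make_em(rng.normal(size=(20, 8)))
        fwd = make_labels(4, 4)
        swapped = PhenotypeLabels(
            {s: ("case" if g == "control" else "control") for s, g in fwd.groups.items()}
        )
        d1, _ = sam_statistic(em, fwd, s0=0.2)
        d2, _ = sam_statistic(em, swapped, s0=0.2)
        np.testing.assert_allclose(d1, -d2, atol=1e-12)

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 50))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance_and_joint_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(15, 8))
        labels = make_labels(4, 4)
        d0, _ = sam_statistic(make_em(x), labels, s0=0.3)
        d_shift, _ = sam_statistic(make_em(x + shift), labels, s0=0.3)
        np.testing.assert_allclose(d_shift, d0, atol=1e-8)
        # scaling values by c with s0 scaled by c leaves d unchanged
        d_scale, _ = sam_statistic(make_em(x * scale), labels, s0=0.3 * scale)
        np.testing.assert_allclose(d_scale, d0, atol=1e-8)

    def test_degenerate_variance_with_zero_s0_names_gene(self):
        em = make_em([[1.0, 1.0, 1.0, 1.0]], gene_ids=["flatgene"])
        with pytest.raises(DegenerateInputError, match="flatgene"):
            sam_statistic(em, make_labels(2, 2), s0=0.0)


class TestEstimateS0:
    def test_fixed_mode_passthrough(self):
        s = np.linspace(0.1, 1, 20)
        cfg = SamConfig(s0_mode="fixed", s0_value=0.0)
        assert estimate_s0(s, s.copy(), cfg) == 0.0

    def test_constant_s_returns_that_value_with_warning(self):
        s = np.ones(20)
        with pytest.warns(UserWarning):
            assert estimate_s0(s, np.arange(20.0), SamConfig()) == 1.0

    def test_cv_minimizer_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(400, 10))
        em = make_em(x)
        labels = make_labels(5, 5)
        num = x[:, :5].mean(axis=1) - x[:, 5:].mean(axis=1)
        _, s = sam_statistic(em, labels, s0=0.0)
        got = estimate_s0(s, num, SamConfig())

        # independent exhaustive search over the same percentile grid
        order = np.argsort(s, kind="stable")
        bins = np.array_split(order, min(100, max(2, s.size // 10)))
        best, best_cv = 0.0, np.inf
        for pct in range(0, 101, 5):
            cand = float(np.percentile(s, pct))
            d = num / (s + cand)
            vs = []
            for b in bins:
                db = d[b]
                vs.append(1.4826 * np.median(np.abs(db - np.median(db))))
            vs = np.array(vs)
            if vs.mean() == 0:
                continue
            cv = vs.std(ddof=1) / vs.mean()
            if cv < best_cv:
                best_cv, best = cv, cand
        assert got == pytest.approx(best)


class TestPermutationPvalues:
    def test_extreme_gene_hits_add_one_floor(self):
        # Monte-Carlo mode (C(12,6)=924 > n_perm) with a labeling sample
        # that contains neither the identity nor its complement, so the
        # extreme gene's |d| exceeds every pooled null value
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 12)) * 0.01
        x[0, :6] += 100.0
        em = make_em(x)
        p = permutation_pvalues(em, make_labels(6, 6), s0=0.5, n_perm=50, seed=0)
        assert p[0] == pytest.approx(1.0 / (1.0 + 50 * 10))

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 6))
        em = make_em(x)
        labels = make_labels(3, 3)
        s0 = 0.2
        p = permutation_pvalues(em, labels, s0, n_perm=100, seed=0)

        # brute force: every C(6,3)=20 labeling, plain python statistics
        def d_for(case_idx):
            out = []
            for gene in x:
                a = [gene[i] for i in case_idx]
                b = [gene[i] for i in range(6) if i not in case_idx]
                ma, mb = sum(a) / 3, sum(b) / 3
                ss = sum((v - ma) ** 2 for v in a) + sum((v - mb) ** 2 for v in b)
                s = ((1 / 3 + 1 / 3) * ss / 4) ** 0.5
                out.append((ma - mb) / (s + s0))
            return out

        pooled = []
        for case_idx in itertools.combinations(range(6), 3):
            pooled.extend(abs(v) for v in d_for(case_idx))
        d_obs = d_for((0, 1, 2))
        expected = [
            (1 + sum(1 for v in pooled if v >= abs(d))) / (1 + len(pooled))
            for d in d_obs
        ]
        np.testing.assert_allclose(p, expected, rtol=1e-12)

    def test_exhaustive_mode_is_seed_independent(self):
        rng = np.random.default_rng(6)
        em = make_em(rng.normal(size=(5, 6)))
        labels = make_labels(3, 3)
        p1 = permutation_pvalues(em, labels, 0.1, n_perm=30, seed=1)
        p2 = permutation_pvalues(em, labels, 0.1, n_perm=30, seed=999)
        np.testing.assert_array_equal(p1, p2)

    def test_monte_carlo_mode_is_seeded_and_deterministic(self):
        rng = np.random.default_rng(7)
        em = make_em(rng.normal(size=(20, 12)))
        labels = make_labels(6, 6)
        p1 = permutation_pvalues(em, labels, 0.1, n_perm=50, seed=3)
        p2 = permutation_pvalues(em, labels, 0.1, n_perm=50, seed=3)
        np.testing.assert_array_equal(p1, p2)


class TestBHAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged_and_ones_stay_ones(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust(np.ones(5)), np.ones(5))

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_gene_order_permutation_gives_identical_q_per_gene(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.001, 1, size=100)
        perm = rng.permutation(100)
        q = bh_adjust(p)
        q_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(q[perm], q_perm, atol=1e-15)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust(np.array([0.0, 0.5]))
        with pytest.raises(ParameterError):
            bh_adjust(np.array([0.5, 1.5]))


@pytest.fixture(scope="module")
def deg_table():
    em, labels, truth = generate_expression(500, 10, 50, 2.0, 0.5, seed=17)
    em = log2_transform(normalize_global(em))
    return call_degs(em, labels, SamConfig(seed=17)), truth


class TestCallDegs:

    def test_up_down_partition_significant_calls(self, deg_table):
        t, _ = deg_table
        sig = t[t["significant"]]
        assert len(sig) == (sig["direction"] == "up").sum() + (
            sig["direction"] == "down"
        ).sum()

    def test_direction_matches_planted_truth(self, deg_table):
        t, truth = deg_table
        sig = t[t["significant"]]
        recovered = set(sig.index) & truth.de_gene_ids
        assert len(recovered) >= 0.9 * len(truth.de_gene_ids)
        for g in recovered:
            assert sig.loc[g, "direction"] == truth.de_direction[g]

    def test_sorted_by_q_then_abs_d(self, deg_table):
        t, _ = deg_table
        assert t["q"].is_monotonic_increasing
        for _, grp in t.groupby("q", sort=False):
            assert grp["d"].abs().is_monotonic_decreasing

    def test_sam_native_fdr_cross_check_is_small_for_strong_calls(self):
        em, labels, _ = generate_expression(200, 6, 30, 2.5, 0.4, seed=19)
        em = log2_transform(normalize_global(em))
        t = call_degs(em, labels, SamConfig(n_perm=200, seed=19), sam_fdr=True)
        strong = t[t["q"] < 0.001]
        assert (strong["fdr_sam"] <= 0.10).all()
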