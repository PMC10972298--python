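import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urinmr.io import FeatureMatrix
from urinmr.univariate import (
    holm_adjust,
    paired_t,
    run_univariate,
    shapiro_wilk_gate,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(d):
    """Brute-force exact two-sided p over all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    n = len(d)
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if min(w_plus, total - w_plus) <= w_obs + 1e-9:
            count += 1
    return count / 2**n


class TestShapiroGate:
    def test_constant_vector_routes_nonparametric(self):
        with pytest.warns(UserWarning):
            assert shapiro_wilk_gate(np.zeros(10)) == "nonparametric"

    def test_bimodal_mixture_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            d = np.concatenate([rng.normal(-4, 0.3, 25), rng.normal(4, 0.3, 25)])
            hits += shapiro_wilk_gate(d) == "nonparametric"
        assert hits >= 48

    def test_size_bounds(self):
        with pytest.raises(ValueError):
            shapiro_wilk_gate(np.array([1.0, 2.0]))


class TestPairedT:
    def test_known_small_example(self):
        t, p = paired_t([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(0.0742, abs=1e-4)

    def test_swapping_phases_negates_t_keeps_p(self):
        rng = np.random.default_rng(1)
        a, c = rng.normal(size=9), rng.normal(size=9)
        t1, p1 = paired_t(a, c)
        t2, p2 = paired_t(c, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_vanishing_noise_drives_p_to_zero(self):
        a = np.zeros(5)
        p_prev = 1.0
        for sd in [0.5, 0.05, 0.005]:
            rng = np.random.default_rng(2)
            c = 1.0 + rng.normal(0, sd, 5)
            _, p = paired_t(a, c)
            assert p < p_prev
            p_prev = p

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])


class TestWilcoxon:
    def test_enumerated_small_example(self):
        w, p = wilcoxon_signed_rank([0] * 5, [1, -2, 3, 4, 5])
        assert w == 2.0
        assert p == pytest.approx(6 / 32)

    def test_all_positive_differences(self):
        w, p = wilcoxon_signed_rank([0] * 5, [1, 2, 3, 4, 5])
        assert w == 0.0
        assert p == pytest.approx(2 / 32)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(3)
        d = rng.normal(size=8)
        w1, p1 = wilcoxon_signed_rank(np.zeros(8), d)
        w2, p2 = wilcoxon_signed_rank(np.zeros(8), -d)
        assert w1 == w2
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    def test_exact_p_matches_enumeration_with_ties(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            d = rng.integers(-4, 5, size=n).astype(float)  # integer data forces ties
            if (d == 0).all():
                continue
            _, p = wilcoxon_signed_rank(np.zeros(n), d)
            assert p == pytest.approx(wilcoxon_enumeration_oracle(d), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            d = rng.normal(size=10)
            _, p = wilcoxon_signed_rank(np.zeros(10), d)
            ref = stats.wilcoxon(d, mode="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_normal_approx_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.4, 1.0, size=25)
        _, p_exact = wilcoxon_signed_rank(np.zeros(25), d, mode="exact")
        _, p_norm = wilcoxon_signed_rank(np.zeros(25), d, mode="normal-approx")
        assert p_norm == pytest.approx(p_exact, abs=0.02)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestHolm:
    def test_step_down_hand_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_dominates_raw_and_bounded_by_bonferroni(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=25)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= np.minimum(1.0, p * len(p)) + 1e-15).all()


def _paired_matrix(diff_per_bin, n_subjects, noise_sd, seed):
    """FeatureMatrix + metadata with planted chronic-minus-acute differences."""
    rng = np.random.default_rng(seed)
    p = len(diff_per_bin)
    ids, rows, meta_rows = [], [], []
    for s in range(n_subjects):
        base = rng.normal(size=p)
        for phase, sign in (("acute", -0.5), ("chronic", 0.5)):
            ids.append(f"S{s}_{phase}")
            rows.append(base + sign * np.asarray(diff_per_bin)
                        + rng.normal(0, noise_sd, p))
            meta_rows.append({"subject_id": f"S{s}", "phase": phase})
    bins = pd.DataFrame(
        {"left": np.arange(p, 0, -1) + 0.5, "right": np.arange(p, 0, -1) - 0.5,
         "center": np.arange(p, 0, -1.0), "excluded": [False] * p, "label": [None] * p}
    )
    fm = FeatureMatrix(
        values=pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                            columns=bins.index),
        bins=bins,
    )
    meta = pd.DataFrame(meta_rows, index=fm.values.index)
    return fm, meta


class TestRunUnivariate:
    def test_planted_down_regulation_detected(self):
        hits = 0
        for seed in range(20):
            fm, meta = _paired_matrix([-1.5, 0.0, 0.0], 10, 0.4, seed)
            res = run_univariate(fm, meta)
            row = res.iloc[0]
            hits += row["regulation"] == "down" and row["p_raw"] < 0.05
        assert hits >= 18

    def test_single_bin_holm_equals_raw(self):
        fm, meta = _paired_matrix([1.0], 6, 0.3, 0)
        res = run_univariate(fm, meta)
        assert len(res) == 1
        assert res["p_holm"].iloc[0] == res["p_raw"].iloc[0]

    def test_unpaired_subject_rejected_with_ids(self):
        fm, meta = _paired_matrix([0.0, 0.0], 5, 0.3, 1)
        fm = FeatureMatrix(values=fm.values.iloc[:-1], bins=fm.bins)
        meta = meta.iloc[:-1]
        with pytest.raises(ValueError, match="S4"):
            run_univariate(fm, meta)

    def test_invariant_to_subject_ordering(self):
        fm, meta = _paired_matrix([0.8, -0.4, 0.0, 0.2], 8, 0.5, 2)
        res1 = run_univariate(fm, meta)
        perm = np.random.default_rng(0).permutation(len(fm.values))
        fm2 = FeatureMatrix(values=fm.values.iloc[perm], bins=fm.bins)
        res2 = run_univariate(fm2, meta.iloc[perm])
        pd.testing.assert_frame_equal(res1, res2)
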