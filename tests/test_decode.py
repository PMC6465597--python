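import numpy as np
import pytest

from memdecode.containers import PseudoTrialSet, RDMSeries, ValidationError
from memdecode.decode import (
    DecodeParams,
    build_rdm_series,
    condition_mean_tempgen,
    condition_mean_timecourses,
    fit_linear_svm,
    pair_decode_timecourse,
    rdm_one_repetition,
    repetition_seeds,
    subaverage,
    temporal_generalization,
)

from conftest import make_epochs


def _pseudo(data, times=None):
    data = np.asarray(data, dtype=float)
    if times is None:
        times = np.arange(data.shape[2], dtype=float)
    return PseudoTrialSet(data=data, times=times, image_id=0, group_size=1,
                          members=np.arange(data.shape[0])[:, None])


class TestSubaverage:
    def test_thirty_trials_in_groups_of_five_give_six(self):
        ep = make_epochs(n_trials=30, n_images=1)
        ps = subaverage(ep, 1, 5, np.random.default_rng(0))
        assert ps.n_pseudo == 6
        assert ps.members.shape == (6, 5)

    def test_group_of_one_is_permutation(self):
        ep = make_epochs(n_trials=6, n_images=1)
        ps = subaverage(ep, 1, 1, np.random.default_rng(1))
        order = ps.members[:, 0]
        assert sorted(order.tolist()) == list(range(6))
        assert np.allclose(ps.data, ep.data[order])

    def test_remainder_discarded_at_random(self):
        ep = make_epochs(n_trials=32, n_images=1)
        ps = subaverage(ep, 1, 5, np.random.default_rng(2))
        assert ps.n_pseudo == 6
        used = ps.members.ravel()
        assert used.size == 30 and np.unique(used).size == 30
        # across seeds, different trials end up discarded
        discarded = set()
        for s in range(20):
            m = subaverage(ep, 1, 5, np.random.default_rng(s)).members.ravel()
            discarded |= set(range(32)) - set(m.tolist())
        assert len(discarded) > 2

    def test_pseudo_trials_are_group_means(self):
        ep = make_epochs(n_trials=10, n_images=1)
        ps = subaverage(ep, 1, 5, np.random.default_rng(3))
        for k in range(ps.n_pseudo):
            assert np.allclose(ps.data[k], ep.data[ps.members[k]].mean(axis=0))

    def test_too_few_trials_rejected(self):
        ep = make_epochs(n_trials=4, n_images=1)
        with pytest.raises(ValidationError, match="fewer than group size"):
            subaverage(ep, 1, 5, np.random.default_rng(0))


def _qp_max_margin(X, y, C=1.0):
    """Independent soft-margin SVM oracle: solve the dual QP with SLSQP."""
    from scipy.optimize import minimize

    ys = np.where(y == 0.0, 1.0, -1.0)       # class A (label 0) = +1 side
    K = (X @ X.T) * np.outer(ys, ys)
    n = len(ys)

    def neg_dual(a):
        return 0.5 * a @ K @ a - a.sum()

    res = minimize(neg_dual, np.full(n, 0.1), jac=lambda a: K @ a - np.ones(n),
                   bounds=[(0, C)] * n,
                   constraints=[{"type": "eq", "fun": lambda a: a @ ys,
                                 "jac": lambda a: ys}],
                   method="SLSQP", options={"maxiter": 500, "ftol": 1e-12})
    a = res.x
    w = (a * ys) @ X
    sv = (a > 1e-6) & (a < C - 1e-6)
    if not sv.any():
        return None
    b = float(np.mean(ys[sv] - X[sv] @ w))
    return w, b


class TestLinearSVM:
    def test_matches_sklearn_svc(self):
        from sklearn.svm import SVC

        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            X = rng.standard_normal((2 * n, int(rng.integers(1, 20))))
            y = np.asarray([0.0] * n + [1.0] * n)
            Xt = rng.standard_normal((5, X.shape[1]))
            w, b = fit_linear_svm(X, y)
            ours = Xt @ w + b
            ref = SVC(kernel="linear", C=1.0).fit(X, y).decision_function(Xt)
            # SVC orients decision > 0 toward classes_[1] (= label 1 = B)
            assert np.allclose(ours, -ref, atol=1e-8)

    def test_matches_qp_oracle(self):
        rng = np.random.default_rng(7)
        n_checked = 0
        while n_checked < 10:
            n = int(rng.integers(3, 6))
            X = rng.standard_normal((2 * n, 2)) + np.r_[[[2, 0]] * n, [[-2, 0]] * n]
            y = np.asarray([0.0] * n + [1.0] * n)
            oracle = _qp_max_margin(X, y)
            if oracle is None:
                continue
            w_o, b_o = oracle
            w, b = fit_linear_svm(X, y)
            Xt = rng.standard_normal((20, 2))
            d_ours, d_oracle = Xt @ w + b, Xt @ w_o + b_o
            keep = np.abs(d_oracle) > 1e-3
            assert np.array_equal(np.sign(d_ours[keep]), np.sign(d_oracle[keep]))
            n_checked += 1


class TestPairDecoding:
    def test_perfectly_separable_toy(self):
        A = _pseudo(np.full((3, 1, 4), +1.0))
        B = _pseudo(np.full((3, 1, 4), -1.0))
        acc = pair_decode_timecourse(A, B)
        assert np.allclose(acc, 100.0)

    def test_fold_schedule_against_oracle(self):
        # N=3 pseudo-trials, 2 channels, 1 time point: replay the paired
        # leave-one-out schedule with the independent QP oracle.
        rng = np.random.default_rng(42)
        A = rng.standard_normal((3, 2, 1)) + [[1.0], [0.2]]
        B = rng.standard_normal((3, 2, 1)) - [[1.0], [0.2]]
        pa, pb = _pseudo(A), _pseudo(B)
        acc = pair_decode_timecourse(pa, pb)[0]
        correct = 0
        for k in range(3):
            keep = [i for i in range(3) if i != k]
            Xtr = np.vstack([A[keep, :, 0], B[keep, :, 0]])
            y = np.asarray([0.0, 0.0, 1.0, 1.0])
            w, b = _qp_max_margin(Xtr, y) or fit_linear_svm(Xtr, y)
            correct += int(A[k, :, 0] @ w + b >= 0)
            correct += int(B[k, :, 0] @ w + b < 0)
        assert acc == pytest.approx(100.0 * correct / 6)

    def test_signal_free_accuracy_near_chance(self):
        rng = np.random.default_rng(3)
        accs = []
        for _ in range(30):
            A = _pseudo(rng.standard_normal((4, 6, 8)))
            B = _pseudo(rng.standard_normal((4, 6, 8)))
            accs.append(pair_decode_timecourse(A, B).mean())
        assert np.mean(accs) == pytest.approx(50.0, abs=3.0)

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(5)
        A = _pseudo(rng.standard_normal((4, 3, 6)))
        B = _pseudo(rng.standard_normal((4, 3, 6)))
        assert np.array_equal(pair_decode_timecourse(A, B),
                              pair_decode_timecourse(B, A))

    def test_mismatched_counts_rejected(self):
        A = _pseudo(np.zeros((3, 2, 4)))
        B = _pseudo(np.zeros((4, 2, 4)))
        with pytest.raises(ValidationError, match="same pseudo-trial count"):
            pair_decode_timecourse(A, B)

    def test_accuracy_monotone_in_separation(self):
        # expected accuracy never decreases over a 3-point separation grid
        rng = np.random.default_rng(11)
        grid_means = []
        for sep in (0.0, 0.6, 1.6):
            accs = []
            for _ in range(25):
                A = _pseudo(rng.standard_normal((4, 6, 3)) + sep / 2)
                B = _pseudo(rng.standard_normal((4, 6, 3)) - sep / 2)
                accs.append(pair_decode_timecourse(A, B).mean())
            grid_means.append((np.mean(accs), np.std(accs) / np.sqrt(len(accs))))
        (m0, s0), (m1, s1), (m2, s2) = grid_means
        assert m1 >= m0 - 3 * (s0 + s1)
        assert m2 >= m1 - 3 * (s1 + s2)
        assert m2 > m0 + 3 * (s0 + s2)


class TestTemporalGeneralization:
    def test_time_constant_patterns_generalize(self):
        rng = np.random.default_rng(0)
        base_a = rng.standard_normal((3, 2, 1)) + [[2.0], [0.0]]
        base_b = rng.standard_normal((3, 2, 1)) - [[2.0], [0.0]]
        A = _pseudo(np.repeat(base_a, 5, axis=2))
        B = _pseudo(np.repeat(base_b, 5, axis=2))
        tg = temporal_generalization(A, B)
        for row in tg.accuracy:
            assert np.allclose(row, row[0])

    def test_diagonal_equals_timecourse_bit_exact(self):
        rng = np.random.default_rng(1)
        A = _pseudo(rng.standard_normal((4, 3, 7)))
        B = _pseudo(rng.standard_normal((4, 3, 7)))
        tg = temporal_generalization(A, B)
        tc = pair_decode_timecourse(A, B)
        assert np.array_equal(np.diag(tg.accuracy), tc)

    def test_sign_flip_produces_below_chance_generalization(self):
        # patterns swap between A and B halfway through the epoch
        a_pat = np.asarray([1.5, -0.5])
        A = np.empty((3, 2, 6))
        B = np.empty((3, 2, 6))
        rng = np.random.default_rng(2)
        jit_a = 0.1 * rng.standard_normal((3, 2))
        jit_b = 0.1 * rng.standard_normal((3, 2))
        for t in range(6):
            sign = 1.0 if t < 3 else -1.0
            A[:, :, t] = sign * a_pat + jit_a
            B[:, :, t] = -sign * a_pat + jit_b
        tg = temporal_generalization(_pseudo(A), _pseudo(B)).accuracy
        assert np.all(np.diag(tg) == 100.0)
        assert np.all(tg[:3, 3:] == 0.0)   # trained pre-flip, tested post-flip
        assert np.all(tg[3:, :3] == 0.0)


class TestRDMSeries:
    def _epochs(self, seed=0, n_images=3, n_trials_per=10):
        return make_epochs(n_trials=n_images * n_trials_per, n_channels=4,
                           n_times=5, seed=seed, n_images=n_images)

    def test_symmetric_zero_diagonal(self):
        rdm = build_rdm_series(self._epochs(),
                               DecodeParams(group_size=5, n_repetitions=2, seed=0))
        rdm.validate()
        assert rdm.n_images == 3

    def test_deterministic(self):
        p = DecodeParams(group_size=5, n_repetitions=2, seed=9)
        r1 = build_rdm_series(self._epochs(), p)
        r2 = build_rdm_series(self._epochs(), p)
        assert np.array_equal(r1.values, r2.values)

    def test_repetition_average_linearity(self):
        ep = self._epochs(seed=4)
        p2 = DecodeParams(group_size=5, n_repetitions=2, seed=33)
        full = build_rdm_series(ep, p2)
        seeds = repetition_seeds(33, 2)
        parts = [rdm_one_repetition(ep, p2, s) for s in seeds]
        assert np.allclose(full.values, np.mean(parts, axis=0), atol=1e-12)

    def test_channel_group_subset(self):
        ep = self._epochs(seed=6)
        p = DecodeParams(group_size=5, n_repetitions=1, seed=1, channel_group="frontal")
        rdm = build_rdm_series(ep, p)
        rdm.validate()


class TestConditionMeans:
    def _rdm_from_values(self, values, conds):
        K = values.shape[1]
        return RDMSeries(values=values, times=np.arange(values.shape[0], dtype=float),
                         image_ids=np.arange(1, K + 1),
                         condition_of={i + 1: c for i, c in enumerate(conds)})

    def test_printed_four_by_four_toy(self):
        v = np.zeros((1, 4, 4))
        #  pairs: (1,2)=60 within-high, (3,4)=52 within-low, between 70,72,74,76
        v[0, 0, 1] = 60
        v[0, 2, 3] = 52
        v[0, 0, 2], v[0, 0, 3], v[0, 1, 2], v[0, 1, 3] = 70, 72, 74, 76
        v[0] += v[0].T
        out = condition_mean_timecourses(
            self._rdm_from_values(v, ["high", "high", "low", "low"]))
        assert out["high"].accuracy[0] == pytest.approx(60.0)
        assert out["low"].accuracy[0] == pytest.approx(52.0)
        assert out["difference"].accuracy[0] == pytest.approx(8.0)

    def test_constant_rdm(self):
        v = np.full((2, 4, 4), 55.0)
        for t in range(2):
            np.fill_diagonal(v[t], 0.0)
        out = condition_mean_timecourses(
            self._rdm_from_values(v, ["high", "high", "low", "low"]))
        assert np.allclose(out["high"].accuracy, 55.0)
        assert np.allclose(out["low"].accuracy, 55.0)
        assert np.allclose(out["difference"].accuracy, 0.0)

    def test_fifteen_fifteen_pair_counts(self):
        conds = ["high"] * 15 + ["low"] * 15
        rdm = self._rdm_from_values(np.zeros((1, 30, 30)), conds)
        assert len(rdm.pair_indices("high")) == 105
        assert len(rdm.pair_indices("low")) == 105
        n_total = len(rdm.pair_indices())
        assert n_total - 2 * 105 == 225   # between pairs unused

    def test_single_image_condition_rejected(self):
        v = np.zeros((1, 3, 3))
        with pytest.raises(ValidationError, match="at least 2 images"):
            condition_mean_timecourses(
                self._rdm_from_values(v, ["high", "low", "low"]))


class TestConditionMeanTempgen:
    def _mat(self, value, pair, subject="s1"):
        from memdecode.containers import TempGenMatrix
        return TempGenMatrix(accuracy=np.full((3, 3), float(value)),
                             times=np.arange(3, dtype=float),
                             subject_id=subject, image_pair=pair)

    def test_elementwise_mean_over_subjects_and_pairs(self):
        cond = {1: "high", 2: "high", 3: "low", 4: "low"}
        mats = [self._mat(60, (1, 2), "s1"), self._mat(80, (1, 2), "s2"),
                self._mat(40, (3, 4), "s1"), self._mat(50, (3, 4), "s2"),
                self._mat(99, (1, 3), "s1")]   # between pair: excluded
        out = condition_mean_tempgen(mats, cond)
        assert np.allclose(out["high"].accuracy, 70.0)
        assert np.allclose(out["low"].accuracy, 45.0)

    def test_identical_matrices_average_to_same(self):
        cond = {1: "high", 2: "high", 3: "low", 4: "low"}
        mats = [self._mat(57, (1, 2), s) for s in ("a", "b", "c")]
        mats += [self._mat(57, (3, 4), s) for s in ("a", "b", "c")]
        out = condition_mean_tempgen(mats, cond)
        assert np.allclose(out["high"].accuracy, 57.0)
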