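"""Stage-1 prototype selection, the k rule, KNN labeling and the full run."""

import numpy as np
import pandas as pd
import pytest

from twospamh import (
    MISSING,
    NON_MISSING,
    UNLABELED,
    DailyPanel,
    FeatureSpace,
    InvalidKError,
    PrototypeError,
    PrototypeSet,
    Thresholds,
    TwoSpamH,
    empirical_quantile,
    knn_classify,
    run_2spamh,
    run_2spamh_all,
    select_prototypes,
    validate_k,
)
from conftest import make_panel


def fs_from_points(points):
    points = np.asarray(points, dtype=float)
    return FeatureSpace(
        points=points,
        included_rows=np.arange(len(points)),
        days=pd.date_range("2021-01-01", periods=len(points), freq="D"),
        orientation_sign_z=1,
        orientation_sign_w=1,
    )


class TestQuantile:
    def test_interpolation_example(self):
        assert empirical_quantile(np.arange(1, 11), 0.3) == pytest.approx(3.7)

    def test_boundaries(self):
        v = np.array([4.0, 1.0, 9.0])
        assert empirical_quantile(v, 0.0) == 1.0
        assert empirical_quantile(v, 1.0) == 9.0

    def test_constant_vector(self):
        assert empirical_quantile(np.full(7, 2.5), 0.4) == 2.5

    def test_errors(self):
        with pytest.raises(ValueError):
            empirical_quantile(np.array([]), 0.5)
        with pytest.raises(ValueError):
            empirical_quantile(np.array([1.0]), 1.5)


class TestSelectPrototypes:
    def test_diagonal_example(self):
        # both coordinates 0..9: quantiles 2.7 and 6.3 on each axis
        v = np.arange(10, dtype=float)
        proto = select_prototypes(fs_from_points(np.column_stack([v, v])))
        assert set(proto.missing_idx) == {0, 1, 2}
        assert set(proto.non_missing_idx) == {7, 8, 9}
        assert len(proto.unlabeled_idx) == 4

    def test_quadrant_logic(self):
        pts = [(-3, -3), (3, 3), (-3, 3), (3, -3)] + [(0, 0)] * 8
        proto = select_prototypes(fs_from_points(pts))
        assert list(proto.missing_idx) == [0]       # low/low
        assert list(proto.non_missing_idx) == [1]   # high/high
        assert {2, 3}.issubset(set(proto.unlabeled_idx))  # mixed quadrants

    def test_identical_points_give_empty_classes(self):
        proto = select_prototypes(fs_from_points([(1.0, 1.0)] * 12))
        assert proto.n_missing == 0 and proto.n_non_missing == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_defining_inequalities_hold_exactly(self, seed):
        rng = np.random.default_rng(seed)
        f = fs_from_points(rng.normal(size=(60, 2)))
        th = Thresholds(0.3, 0.7)
        proto = select_prototypes(f, th)
        qlz, quz = np.quantile(f.c_z, [0.3, 0.7])
        qlw, quw = np.quantile(f.c_w, [0.3, 0.7])
        for t in proto.missing_idx:
            assert f.c_z[t] < qlz and f.c_w[t] < qlw
        for t in proto.non_missing_idx:
            assert f.c_z[t] > quz and f.c_w[t] > quw
        assert (
            set(proto.missing_idx) | set(proto.non_missing_idx)
            | set(proto.unlabeled_idx)
        ) == set(range(60))

    @pytest.mark.parametrize("seed", range(5))
    def test_shrinking_band_never_adds_prototypes(self, seed):
        rng = np.random.default_rng(seed + 100)
        f = fs_from_points(rng.normal(size=(80, 2)))
        wide = select_prototypes(f, Thresholds(0.3, 0.7))
        narrow = select_prototypes(f, Thresholds(0.2, 0.8))
        assert set(narrow.missing_idx) <= set(wide.missing_idx)
        assert set(narrow.non_missing_idx) <= set(wide.non_missing_idx)


class TestValidateK:
    def test_worked_example_rejects_k18(self):
        proto = PrototypeSet(np.arange(4), np.arange(4, 20), np.array([], int))
        check = validate_k(18, proto)
        assert not check.ok
        assert check.half_k == 9
        assert "9" in check.reason and check.n_missing == 4

    def test_k1_ok_with_both_classes(self):
        proto = PrototypeSet(np.array([0]), np.array([1]), np.array([], int))
        assert validate_k(1, proto).ok

    def test_boundary_of_half_rule(self):
        proto = PrototypeSet(np.arange(4), np.arange(4, 20), np.array([], int))
        assert validate_k(8, proto).ok        # 8/2 = 4 <= 4
        assert not validate_k(9, proto).ok    # 9/2 = 4.5 > 4

    def test_k_exceeding_total(self):
        proto = PrototypeSet(np.arange(3), np.arange(3, 6), np.array([], int))
        assert not validate_k(7, proto).ok


def brute_force_knn(points, proto, k):
    """Independent oracle: exhaustive sort + vote with the documented ties."""
    labeled = sorted(
        [(int(i), MISSING) for i in proto.missing_idx]
        + [(int(i), NON_MISSING) for i in proto.non_missing_idx]
    )
    out = []
    for t in proto.unlabeled_idx:
        scored = sorted(
            (float(np.sqrt(((points[i] - points[t]) ** 2).sum())), i, lab)
            for i, lab in labeled
        )
        top = scored[:k]
        n_miss = sum(1 for _, _, lab in top if lab == MISSING)
        if 2 * n_miss > k:
            out.append(MISSING)
        elif 2 * n_miss < k:
            out.append(NON_MISSING)
        else:
            d0 = top[0][0]
            at_min = {lab for d, _, lab in top if d == d0}
            out.append(MISSING if len(at_min) == 2 else top[0][2])
    return np.array(out, dtype=object)


class TestKnn:
    def test_nearest_neighbor(self):
        f = fs_from_points([(0, 0), (1, 1), (0.1, 0.1)])
        proto = PrototypeSet(np.array([0]), np.array([1]), np.array([2]))
        assert knn_classify(f, proto, 1)[0] == MISSING

    def test_even_k_tie_goes_to_nearest(self):
        f = fs_from_points([(0, 0), (1, 0), (0.2, 0.0)])
        proto = PrototypeSet(np.array([0]), np.array([1]), np.array([2]))
        assert knn_classify(f, proto, 2)[0] == MISSING  # (0,0) is nearer

    def test_exact_distance_tie_goes_to_missing(self):
        f = fs_from_points([(0, 0), (1, 0), (0.5, 0.0)])
        proto = PrototypeSet(np.array([0]), np.array([1]), np.array([2]))
        assert knn_classify(f, proto, 2)[0] == MISSING

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 200))
        pts = np.round(rng.normal(size=(n, 2)), 1)  # rounding provokes ties
        idx = rng.permutation(n)
        n_m = int(rng.integers(2, max(3, n // 4)))
        n_n = int(rng.integers(2, max(3, n // 4)))
        proto = PrototypeSet(
            missing_idx=np.sort(idx[:n_m]),
            non_missing_idx=np.sort(idx[n_m:n_m + n_n]),
            unlabeled_idx=np.sort(idx[n_m + n_n:]),
        )
        k = int(rng.integers(1, 2 * min(n_m, n_n) + 1))
        f = fs_from_points(pts)
        got = knn_classify(f, proto, k)
        want = brute_force_knn(pts, proto, k)
        assert np.array_equal(got, want)

    def test_invalid_k_raises(self):
        f = fs_from_points([(0, 0), (1, 1), (0.5, 0.5)])
        proto = PrototypeSet(np.array([0]), np.array([1]), np.array([2]))
        with pytest.raises(InvalidKError):
            knn_classify(f, proto, 4)


class TestRun:
    def test_output_total_and_deterministic(self, panel):
        lab1 = run_2spamh(panel, "step_count")
        lab2 = run_2spamh(panel, "step_count")
        assert len(lab1) == panel.T
        assert UNLABELED not in set(lab1)
        assert lab1.equals(lab2)

    def test_stage1_labels_preserved(self, panel):
        from twospamh import build_feature_space
        f = build_feature_space(panel)
        proto = select_prototypes(f)
        lab = run_2spamh(panel, "step_count")
        for i in proto.missing_idx:
            assert lab.iloc[f.included_rows[i]] == MISSING
        for i in proto.non_missing_idx:
            assert lab.iloc[f.included_rows[i]] == NON_MISSING

    def test_agrees_with_truth_on_well_separated_panel(self, sim_panel):
        panel, truth = sim_panel
        lab = run_2spamh(panel, "step_count").to_numpy()
        agree = (lab == truth.labels).mean()
        assert agree > 0.85

    def test_affine_rescaling_of_a_column_changes_nothing(self, panel):
        lab = run_2spamh(panel, "step_count")
        q = make_panel()  # same seed/content as the fixture
        q.Z["screen_unlocks"] = q.Z["screen_unlocks"] * 37.0 + 11.0
        assert run_2spamh(q, "step_count").equals(lab)

    def test_technical_missing_days_labeled_as_such(self):
        p = make_panel(T=60, with_nan=True)
        lab = run_2spamh(p, "step_count")
        assert lab.iloc[1] == "technical_missing"   # missing X cell
        assert lab.iloc[2] == "technical_missing"   # missing W cell
        assert UNLABELED not in set(lab)

    def test_empty_prototype_class_is_actionable_error(self):
        p = make_panel(T=30)
        # anti-correlated axes leave the corner quadrants empty
        v = np.arange(30, dtype=float)
        p.W["n_uploads"] = v
        p.Z = p.Z[["screen_unlocks"]].copy()
        p.Z["screen_unlocks"] = -v
        with pytest.raises(PrototypeError, match="widen the prototype band"):
            run_2spamh(p, "step_count")

    def test_all_columns_equals_per_column_runs(self):
        p = make_panel(T=60, seed=9)
        p.X["sleep_hours"] = np.random.default_rng(1).normal(7, 1, 60)
        m = run_2spamh_all(p)
        for col in p.x_cols:
            assert m.labels[col].equals(run_2spamh(p, col))

    def test_per_column_sensor_mapping_changes_feature_space(self):
        rng = np.random.default_rng(2)
        p = make_panel(T=60, seed=4)
        # second sensor with an unrelated activity pattern
        p.W["mic_uploads"] = rng.poisson(8, 60).astype(float)
        p.X["conversation"] = rng.gamma(2, 5, 60)
        res = TwoSpamH(
            p,
            w_cols_map={"step_count": ["n_uploads"],
                        "conversation": ["mic_uploads"]},
        ).fit()
        a = res.label_column("step_count")
        b = res.label_column("conversation")
        assert not a.equals(b)

    def test_summary_mentions_settings(self, panel):
        res = TwoSpamH(panel).fit()
        s = res.summary()
        assert "0.3" in s and "0.7" in s and "step_count" in s
        counts = res.prototype_counts()
        assert (counts["n_missing_prototypes"] > 0).all()
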