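"""From-scratch DBSCAN and modal pattern-feature extraction."""

import numpy as np
import pandas as pd
import pytest

import alarmscape as asc
from alarmscape.clustering import NOISE, mode_with_tiebreak

from conftest import brute_force_dbscan, labels_match_up_to_permutation


def params(eps=0.5, min_pts=10, scaling="none"):
    return asc.DBSCANParams(eps=eps, min_pts=min_pts, scaling=scaling)


class TestDBSCAN:
    def test_empty_input_gives_empty_result(self):
        result = asc.dbscan(np.empty((0, 2)), params())
        assert result.n_clusters == 0 and result.labels.size == 0

    def test_single_point_below_min_pts_is_noise(self):
        result = asc.dbscan(np.array([[0.0, 0.0]]), params(min_pts=2))
        assert list(result.labels) == [NOISE]

    def test_twelve_identical_points_form_one_cluster(self):
        pts = np.zeros((12, 2))
        result = asc.dbscan(pts, params(eps=0.5, min_pts=10))
        assert result.n_clusters == 1
        assert (result.labels == 0).all()
        assert result.core_flags.all()

    def test_two_well_separated_blobs(self):
        rng = np.random.default_rng(1)
        pts = np.vstack(
            [rng.normal(0, 0.1, (8, 2)), rng.normal(10, 0.1, (8, 2))]
        )
        result = asc.dbscan(pts, params(eps=1.0, min_pts=4))
        assert result.n_clusters == 2
        assert len(set(result.labels[:8])) == 1
        assert len(set(result.labels[8:])) == 1
        assert result.labels[0] != result.labels[8]

    def test_matches_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            n = int(rng.integers(1, 41))
            pts = rng.uniform(0, 4, size=(n, 2))
            eps = float(rng.uniform(0.2, 1.5))
            min_pts = int(rng.integers(2, 8))
            got = asc.dbscan(pts, params(eps=eps, min_pts=min_pts))
            exp_labels, exp_core = brute_force_dbscan(pts, eps, min_pts)
            assert np.array_equal(got.core_flags, exp_core)
            assert labels_match_up_to_permutation(got.labels, exp_labels)

    def test_matches_sklearn_partition(self):
        """Independent cross-check: identical core points and noise set, and
        the same partition of core points, as sklearn's implementation."""
        from sklearn.cluster import DBSCAN as SkDBSCAN

        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = rng.uniform(0, 3, size=(int(rng.integers(5, 40)), 2))
            eps, min_pts = float(rng.uniform(0.3, 1.0)), int(rng.integers(2, 6))
            mine = asc.dbscan(pts, params(eps=eps, min_pts=min_pts))
            sk = SkDBSCAN(eps=eps, min_samples=min_pts).fit(pts)
            sk_core = np.zeros(len(pts), dtype=bool)
            sk_core[sk.core_sample_indices_] = True
            assert np.array_equal(mine.core_flags, sk_core)
            assert np.array_equal(mine.labels == NOISE, sk.labels_ == -1)
            # partition of core points matches up to label permutation
            assert labels_match_up_to_permutation(
                mine.labels[sk_core], sk.labels_[sk_core]
            )

    def test_label_partition_invariant_under_shuffling(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 3, size=(30, 2))
        perm = rng.permutation(30)
        base = asc.dbscan(pts, params(eps=0.8, min_pts=4))
        shuffled = asc.dbscan(pts[perm], params(eps=0.8, min_pts=4))
        assert labels_match_up_to_permutation(base.labels[perm], shuffled.labels)

    def test_growing_eps_never_adds_noise(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 3, size=(40, 2))
        noise_counts = [
            int((asc.dbscan(pts, params(eps=e, min_pts=4)).labels == NOISE).sum())
            for e in (0.2, 0.4, 0.8, 1.6)
        ]
        assert noise_counts == sorted(noise_counts, reverse=True)

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            asc.DBSCANParams(eps=0)
        with pytest.raises(ValueError):
            asc.DBSCANParams(min_pts=0)
        with pytest.raises(ValueError):
            asc.dbscan(np.array([[np.nan, 0.0]]), params())


class TestMode:
    def test_strict_majority(self):
        assert mode_with_tiebreak(np.array([42, 42, 42, 55])) == 42

    def test_tie_broken_toward_reference_median(self):
        # counts tie between 40 and 50; reference median 46 is closer to 50
        values = np.array([40, 50])
        reference = np.array([40, 44, 46, 50, 55])
        assert mode_with_tiebreak(values, reference) == 50

    def test_remaining_tie_takes_smaller_value(self):
        values = np.array([40, 52])
        reference = np.array([46])  # equidistant from both
        assert mode_with_tiebreak(values, reference) == 40

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            mode_with_tiebreak(np.array([]))


def _windowed_frame(groups):
    """groups: list of (patient, signal, bound, status, values, durations)."""
    rows = []
    for pid, signal, bound, status, values, durations in groups:
        for v, d in zip(values, durations):
            rows.append(
                {
                    "patient_id": pid,
                    "signal": signal,
                    "bound": bound,
                    "cie_status": status,
                    "rep_value": float(v),
                    "duration_s": float(d),
                }
            )
    return pd.DataFrame(rows)


class TestPatternFeatures:
    def test_modal_value_is_majority_of_single_cluster(self):
        frame = _windowed_frame(
            [("p1", "ECGRR", "upper", "sepsis", [42, 42, 42, 55], [5, 5, 5, 5])]
        )
        out = asc.extract_pattern_features(frame, asc.DBSCANParams(min_pts=10))
        assert len(out) == 1
        assert out.loc[0, "modal_value"] == 42
        assert out.loc[0, "n_alarms"] == 4

    def test_modal_value_is_always_an_observed_value(self, reference_features, reference_windowed):
        observed = reference_windowed.groupby(["patient_id", "signal", "bound"])[
            "rep_value"
        ].agg(set)
        for _, row in reference_features.iterrows():
            key = (row["patient_id"], row["signal"], row["bound"])
            assert row["modal_value"] in observed[key]

    def test_sparse_groups_skip_clustering_and_take_global_mode(self):
        frame = _windowed_frame(
            [("p1", "SPO2", "lower", "none", [85, 85, 88], [3, 3, 3])]
        )
        out = asc.extract_pattern_features(frame, asc.DBSCANParams(min_pts=10))
        assert out.loc[0, "modal_value"] == 85
        assert out.loc[0, "largest_cluster_size"] == 3

    def test_noise_cluster_falls_back_to_all_points(self):
        # 10 widely spaced singleton values: everything is noise
        values = np.arange(10) * 1000.0
        frame = _windowed_frame(
            [("p1", "ECGHR", "upper", "none", values, np.ones(10))]
        )
        out = asc.extract_pattern_features(
            frame, asc.DBSCANParams(eps=0.01, min_pts=3, scaling="none")
        )
        assert out.loc[0, "largest_cluster_size"] == 10

    def test_largest_cluster_bounds_alarm_count(self, reference_features):
        assert (
            reference_features["n_alarms"]
            >= reference_features["largest_cluster_size"]
        ).all()

    def test_empty_windowed_frame_gives_empty_features(self):
        out = asc.extract_pattern_features(pd.DataFrame())
        assert len(out) == 0

    def test_pooled_grouping_merges_patients(self):
        frame = _windowed_frame(
            [
                ("p1", "ECGRR", "upper", "sepsis", [45, 45], [5, 5]),
                ("p2", "ECGRR", "upper", "sepsis", [45, 47], [5, 5]),
            ]
        )
        out = asc.extract_pattern_features(frame, group_by_patient=False)
        assert len(out) == 1
        assert out.loc[0, "n_alarms"] == 4
        assert out.loc[0, "modal_value"] == 45


def test_planted_ranges_recovered_in_modal_values(reference_features):
    """On the reference cohort the modal alarm values of the planted groups
    fall inside the planted ranges for at least 90% of event patients."""
    checks = [
        ("death_cpr_picu", "ECGRR", "upper", 40, 60),
        ("death_cpr_picu", "SPO2", "lower", 85, 90),
        ("sepsis", "ECGHR", "upper", 150, 180),
    ]
    for status, signal, bound, lo, hi in checks:
        sub = reference_features[
            (reference_features["cie_status"] == status)
            & (reference_features["signal"] == signal)
            & (reference_features["bound"] == bound)
        ]
        assert len(sub) >= 20
        inside = sub["modal_value"].between(lo, hi).mean()
        assert inside >= 0.90, (status, signal, bound, inside)
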