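"""Shared fixtures: the reference synthetic cohort and its derived stages.

The cohort regime mirrors the monitored-ward study conditions: 238 patients,
31% CIE prevalence with a 73:46 death-to-sepsis mix, the neonate/infant/
pediatric age mix, 24 h of 1 Hz recording with 2% dropout and ~2 transient
artifacts per hour, and the WHO pre-event pattern table planted before each
event. Stages are computed once per session and reused.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import alarmscape as asc
from alarmscape.cohort import cohort_manifest
from alarmscape.io import events_from_manifest, spans_from_patients
from alarmscape.windows import window_cohort_alarms

COHORT_SEED = 7


@pytest.fixture(scope="session")
def who_table():
    return asc.builtin_cutoffs("WHO")


@pytest.fixture(scope="session")
def goal3_table():
    return asc.builtin_cutoffs("GOAL3")


@pytest.fixture(scope="session")
def reference_cohort():
    cfg = asc.CohortConfig(n_patients=238, cie_fraction=0.31, seed=COHORT_SEED)
    return asc.generate_cohort(cfg, asc.DEFAULT_PATTERNS["WHO"])


@pytest.fixture(scope="session")
def reference_manifest(reference_cohort):
    return cohort_manifest(reference_cohort)


@pytest.fixture(scope="session")
def reference_alarms(reference_cohort, who_table):
    episodes = []
    for p in reference_cohort:
        episodes.extend(asc.detect_episodes(p.series, p.age_months, who_table))
    return asc.episodes_to_frame(episodes)


@pytest.fixture(scope="session")
def reference_windowed(reference_cohort, reference_alarms, reference_manifest):
    events = events_from_manifest(reference_manifest)
    spans = spans_from_patients(reference_cohort)
    return window_cohort_alarms(reference_alarms, events, spans=spans)


@pytest.fixture(scope="session")
def reference_features(reference_windowed):
    return asc.extract_pattern_features(reference_windowed)


@pytest.fixture(scope="session")
def reference_dataset(reference_features, reference_manifest):
    return asc.assemble_dataset(
        reference_features, reference_manifest, balance=True, seed=COHORT_SEED
    )


@pytest.fixture(scope="session")
def separable_dataset():
    """Perfectly separable per-patient features: the three classes occupy
    disjoint, widely spaced blocks of feature space with no overlap."""
    rng = np.random.default_rng(123)
    cols = [c for c in _feature_cols()]
    rows, labels, index = [], [], []
    centers = {"none": 0.0, "death_cpr_picu": 100.0, "sepsis": 200.0}
    for label, center in centers.items():
        for i in range(30):
            rows.append(center + rng.uniform(0, 1, size=len(cols)))
            labels.append(label)
            index.append(f"{label}-{i}")
    frame = pd.DataFrame(rows, columns=cols, index=pd.Index(index, name="patient_id"))
    frame["label"] = labels
    return frame


def _feature_cols():
    from alarmscape.classify import feature_column_names

    return feature_column_names()


# ---------------------------------------------------------------------------
# Independent oracles, deliberately naive: these re-derive the expected
# behavior by direct per-sample / per-pair enumeration and are used to
# validate the vectorized implementations.


def brute_force_episodes(timestamps, values, lower, upper, interval=1.0):
    """Per-sample scan: label every sample, group maximal same-side runs
    broken by NaN or a timestamp gap; returns (bound, start_idx, end_idx)."""
    runs = []
    current = None  # (bound, start_index)
    prev_t = None
    for i, (t, v) in enumerate(zip(timestamps, values)):
        gap = prev_t is not None and (t - prev_t) > interval
        if v is None or (isinstance(v, float) and np.isnan(v)):
            side = None
        elif upper is not None and v > upper:
            side = "upper"
        elif lower is not None and v < lower:
            side = "lower"
        else:
            side = None
        if current is not None and (side != current[0] or gap):
            runs.append((current[0], current[1], i - 1))
            current = None
        if side is not None and current is None:
            current = (side, i)
        prev_t = t
    if current is not None:
        runs.append((current[0], current[1], len(timestamps) - 1))
    return runs


def brute_force_dbscan(points, eps, min_pts):
    """Density-connected components by explicit pairwise enumeration and
    union-find over core points; borders join the lowest-id cluster.
    Returns (labels, core_flags) with clusters numbered by smallest member
    core index."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = len(pts)
    within = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            d = sum((pts[i, k] - pts[j, k]) ** 2 for k in range(pts.shape[1])) ** 0.5
            within[i][j] = d <= eps
    core = [sum(within[i]) >= min_pts for i in range(n)]

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(n):
            if core[i] and core[j] and within[i][j]:
                parent[find(i)] = find(j)

    # stable numbering: order components by their smallest core index
    comp_order = sorted(
        {find(i) for i in range(n) if core[i]},
        key=lambda r: min(k for k in range(n) if core[k] and find(k) == r),
    )
    cluster_of_root = {r: c for c, r in enumerate(comp_order)}
    labels = [-1] * n
    for i in range(n):
        if core[i]:
            labels[i] = cluster_of_root[find(i)]
    for i in range(n):
        if not core[i]:
            neighbor_clusters = [labels[j] for j in range(n) if core[j] and within[i][j]]
            if neighbor_clusters:
                labels[i] = min(neighbor_clusters)
    return np.array(labels), np.array(core)


def labels_match_up_to_permutation(a, b) -> bool:
    """True iff two labelings induce the same partition and noise set."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping: dict[int, int] = {}
    reverse: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(int(x), int(y)) != y:
            return False
        if reverse.setdefault(int(y), int(x)) != x:
            return False
    return True
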