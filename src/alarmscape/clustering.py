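"""Density-based clustering of alarm records and modal-pattern extraction.

Alarms from the pre-event window are clustered per patient x signal x bound
in the (representative value, duration) plane with DBSCAN, implemented here
from first principles:

* a point P is a *core point* iff its epsilon-neighborhood (Euclidean
  distance <= eps, the point itself included) holds at least ``min_pts``
  points;
* clusters are the maximal density-connected sets of core points plus the
  non-core points within eps of one of them (*border points*);
* remaining points are *noise*.

The pattern feature of a group is the mode of the alarm values (and of the
durations) within the largest non-noise cluster — the most frequent alarm
threshold value a patient kept hitting before the event — never an average,
so it is always an observed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DBSCANParams:
    """eps is measured in the (optionally standardized) coordinate space;
    ``scaling="standardize"`` rescales each dimension to unit spread within
    the group before clustering (a zero-spread dimension is left as is)."""

    eps: float = 0.5
    min_pts: int = 10
    scaling: str = "standardize"  # "none" | "standardize"

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be at least 1")
        if self.scaling not in ("none", "standardize"):
            raise ValueError("scaling must be 'none' or 'standardize'")


NOISE = -1


@dataclass
class ClusterResult:
    """labels[i] is the cluster id of point i (0-based) or -1 for noise."""

    labels: np.ndarray
    core_flags: np.ndarray
    n_clusters: int


def dbscan(points: np.ndarray, params: DBSCANParams) -> ClusterResult:
    """Density-based clustering of a point set.

    Parameters
    ----------
    points : (n, d) array
        Finite coordinates; no scaling is applied here (see
        :func:`extract_pattern_features` for the standardized pipeline).
    params : DBSCANParams

    Returns
    -------
    ClusterResult
        Deterministic for a fixed input order: clusters are numbered by the
        first core point encountered in index order, and a border point
        within eps of several clusters joins the one with the lowest id.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if n == 0:
        return ClusterResult(
            labels=np.empty(0, dtype=int),
            core_flags=np.empty(0, dtype=bool),
            n_clusters=0,
        )
    if not np.isfinite(pts).all():
        raise ValueError("point coordinates must be finite")

    # pairwise Euclidean adjacency; group sizes here are small (alarms per
    # patient-signal-bound), so the dense matrix is the simplest correct path
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    adjacency = dist <= params.eps
    core = adjacency.sum(axis=1) >= params.min_pts  # neighborhood includes self

    labels = np.full(n, NOISE, dtype=int)
    cluster_id = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        # expand a new cluster from this unassigned core point
        labels[i] = cluster_id
        frontier = [i]
        while frontier:
            j = frontier.pop()
            if not core[j]:
                continue
            for k in np.flatnonzero(adjacency[j]):
                if labels[k] == NOISE:
                    labels[k] = cluster_id
                    if core[k]:
                        frontier.append(k)
        cluster_id += 1

    # border-point tie-break: lowest cluster id among core neighbors
    for i in np.flatnonzero(~core & (labels != NOISE)):
        neighbor_clusters = labels[adjacency[i] & core]
        labels[i] = int(neighbor_clusters.min())

    return ClusterResult(labels=labels, core_flags=core, n_clusters=cluster_id)


def mode_with_tiebreak(values: np.ndarray, reference: np.ndarray | None = None) -> float:
    """Most frequent value; ties resolved to the value closest to the median
    of ``reference`` (default: ``values`` itself), then to the smaller value.

    The result is always one of the observed values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mode of empty set")
    ref = values if reference is None else np.asarray(reference, dtype=float)
    med = float(np.median(ref))
    uniq, counts = np.unique(values, return_counts=True)
    candidates = uniq[counts == counts.max()]
    dist = np.abs(candidates - med)
    best = candidates[dist == dist.min()]
    return float(best.min())


@dataclass
class PatternFeature:
    """Modal alarm pattern of one patient x signal x bound group."""

    patient_id: str
    signal: str
    bound: str
    cie_status: str
    modal_value: float
    modal_duration: float
    n_alarms: int
    largest_cluster_size: int


_FEATURE_COLUMNS = [
    "patient_id",
    "cie_status",
    "signal",
    "bound",
    "modal_value",
    "modal_duration",
    "n_alarms",
    "largest_cluster_size",
]


def features_to_frame(features: list[PatternFeature]) -> pd.DataFrame:
    if not features:
        return pd.DataFrame(columns=_FEATURE_COLUMNS)
    return pd.DataFrame([vars(f) for f in features])[_FEATURE_COLUMNS]


def _standardize(coords: np.ndarray) -> np.ndarray:
    out = coords.astype(float).copy()
    for j in range(out.shape[1]):
        sd = out[:, j].std()
        mean = out[:, j].mean()
        if sd > 0:
            out[:, j] = (out[:, j] - mean) / sd
        else:
            out[:, j] = 0.0
    return out


def extract_pattern_features(
    windowed: pd.DataFrame,
    params: DBSCANParams | None = None,
    space: str = "value-duration",
    group_by_patient: bool = True,
    coverage_log: list | None = None,
) -> pd.DataFrame:
    """Modal alarm patterns per patient x signal x bound.

    For each group the alarms are clustered in the chosen space
    (``"value-duration"``, the 2-D plane the pre-event alarm clouds live in,
    or ``"value"`` for 1-D); the modal value and modal duration are taken
    over the largest non-noise cluster. Groups with fewer than ``min_pts``
    alarms skip clustering (everything would be noise) and take the mode
    over all points; so do groups whose points are all labeled noise.

    Parameters
    ----------
    windowed : DataFrame
        Windowed alarms with ``patient_id``, ``signal``, ``bound``,
        ``rep_value``, ``duration_s`` and ``cie_status`` columns.
    params : DBSCANParams, optional
    space : {"value-duration", "value"}
    group_by_patient : bool
        If False, pool alarms across patients per (cie_status, signal,
        bound) — the pooled variant of the per-patient default.
    coverage_log : list, optional
        Appends (group key, reason) for groups that yielded no feature row.

    Returns
    -------
    DataFrame
        Features CSV dialect: one row per group with at least one alarm.
    """
    params = params or DBSCANParams()
    if space not in ("value-duration", "value"):
        raise ValueError("space must be 'value-duration' or 'value'")
    features: list[PatternFeature] = []
    if not len(windowed):
        return features_to_frame(features)
    keys = (
        ["patient_id", "signal", "bound"]
        if group_by_patient
        else ["cie_status", "signal", "bound"]
    )
    for key, group in windowed.groupby(keys, sort=True):
        if not len(group):  # pragma: no cover - groupby yields non-empty
            if coverage_log is not None:
                coverage_log.append((key, "no alarms"))
            continue
        values = group["rep_value"].to_numpy(dtype=float)
        durations = group["duration_s"].to_numpy(dtype=float)
        coords = (
            np.column_stack([values, durations])
            if space == "value-duration"
            else values[:, None]
        )
        if len(group) >= params.min_pts:
            scaled = (
                _standardize(coords) if params.scaling == "standardize" else coords
            )
            result = dbscan(scaled, params)
            member = _largest_cluster_mask(result.labels)
        else:
            member = np.ones(len(group), dtype=bool)
        cluster_values = values[member]
        cluster_durations = durations[member]
        pid = str(group["patient_id"].iloc[0]) if group_by_patient else "pooled"
        status = (
            str(group["cie_status"].iloc[0]) if "cie_status" in group.columns else "none"
        )
        features.append(
            PatternFeature(
                patient_id=pid,
                signal=str(group["signal"].iloc[0]),
                bound=str(group["bound"].iloc[0]),
                cie_status=status,
                modal_value=mode_with_tiebreak(cluster_values, reference=values),
                modal_duration=mode_with_tiebreak(
                    cluster_durations, reference=durations
                ),
                n_alarms=int(len(group)),
                largest_cluster_size=int(member.sum()),
            )
        )
    return features_to_frame(features)


def _largest_cluster_mask(labels: np.ndarray) -> np.ndarray:
    """Mask of the largest non-noise cluster; all points if everything is
    noise. Size ties go to the lowest cluster id."""
    non_noise = labels[labels != NOISE]
    if non_noise.size == 0:
        return np.ones(labels.size, dtype=bool)
    ids, sizes = np.unique(non_noise, return_counts=True)
    best = ids[sizes == sizes.max()].min()
    return labels == best
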