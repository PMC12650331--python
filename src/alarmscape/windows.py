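"""Pre-event windowing of alarm episodes.

Alarms are restricted to the 8 h preceding each critical illness event and
the window is divided into four 2 h segments (segment 1 = earliest,
[-8 h, -6 h)). Membership uses the episode *start* time on a half-open
window [event - 8 h, event): an episode straddling the left edge is kept iff
it starts inside, and one starting at or after the event is excluded.
Patients without an event get a pseudo-anchor (recording midpoint by
default, or the recording end) so their alarm features are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alarms import AlarmEpisode

#: default duration histogram bin edges, seconds (right edge open)
DEFAULT_DURATION_EDGES = (0.0, 10.0, 20.0, 30.0, 60.0, 120.0, np.inf)


@dataclass(frozen=True)
class CIEEvent:
    """One critical illness event annotation."""

    patient_id: str
    cie_type: str  # "death_cpr_picu" | "sepsis"
    event_time: int  # epoch seconds


@dataclass
class SegmentSummary:
    """Alarm distribution within one 2 h segment of the pre-event window."""

    segment_index: int  # 1..n_segments, 1 = earliest
    counts: dict[tuple[str, str], int]  # (signal, bound) -> episode count
    duration_edges: tuple[float, ...]
    duration_counts: np.ndarray
    fraction_under_30s: float

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


def window_alarms(
    episodes: list[AlarmEpisode] | pd.DataFrame,
    event: CIEEvent,
    window_hours: float = 8.0,
):
    """Episodes starting within ``[event_time - window, event_time)``.

    Accepts and returns either a list of :class:`AlarmEpisode` or an alarms
    DataFrame (a ``lead_time_s`` column — seconds before the event — is added
    in the frame case).
    """
    if window_hours <= 0:
        raise ValueError("window_hours must be positive")
    left = event.event_time - window_hours * 3600
    if isinstance(episodes, pd.DataFrame):
        sel = (episodes["start"] >= left) & (episodes["start"] < event.event_time)
        out = episodes.loc[sel].copy()
        out["lead_time_s"] = event.event_time - out["start"]
        return out
    return [e for e in episodes if left <= e.start < event.event_time]


def segment_index_of(
    start: float, event_time: float, window_hours: float = 8.0, n_segments: int = 4
) -> int:
    """1-based segment containing an episode start; 1 = earliest segment."""
    lead = event_time - start
    if not 0 < lead <= window_hours * 3600:
        raise ValueError("episode outside the pre-event window; window first")
    seg_len = window_hours * 3600 / n_segments
    # lead in (0, W]; segment counted from the left edge of the window
    idx = n_segments - int(np.ceil(lead / seg_len)) + 1
    return int(np.clip(idx, 1, n_segments))


def segment_summary(
    windowed: list[AlarmEpisode],
    event: CIEEvent,
    window_hours: float = 8.0,
    n_segments: int = 4,
    duration_edges: tuple[float, ...] = DEFAULT_DURATION_EDGES,
) -> list[SegmentSummary]:
    """Per-segment alarm counts, duration histogram and sub-30 s fraction.

    Every episode must already lie inside the window (use
    :func:`window_alarms` first); each is assigned to the segment containing
    its start, so segment totals partition the window total.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be at least 1")
    edges = np.asarray(duration_edges, dtype=float)
    buckets: list[list[AlarmEpisode]] = [[] for _ in range(n_segments)]
    for ep in windowed:
        idx = segment_index_of(ep.start, event.event_time, window_hours, n_segments)
        buckets[idx - 1].append(ep)
    summaries = []
    for i, eps in enumerate(buckets, start=1):
        counts: dict[tuple[str, str], int] = {}
        durations = np.array([e.duration for e in eps], dtype=float)
        for e in eps:
            key = (e.signal, e.bound)
            counts[key] = counts.get(key, 0) + 1
        hist, _ = np.histogram(durations, bins=edges)
        frac = float(np.mean(durations < 30.0)) if durations.size else 0.0
        summaries.append(
            SegmentSummary(
                segment_index=i,
                counts=counts,
                duration_edges=tuple(edges),
                duration_counts=hist,
                fraction_under_30s=frac,
            )
        )
    return summaries


def pseudo_anchor(series_start: int, series_end: int, policy: str = "midpoint") -> int:
    """Window anchor for patients without an event.

    ``midpoint`` anchors at the middle of the recording; ``end`` at the last
    sample (i.e. the final 8 h). Either gives non-event patients a pre-anchor
    window of the same shape as event patients'.
    """
    if policy == "midpoint":
        return int((series_start + series_end) // 2)
    if policy == "end":
        return int(series_end)
    raise ValueError(f"unknown anchor policy {policy!r}; valid: midpoint, end")


def window_cohort_alarms(
    alarms: pd.DataFrame,
    events: pd.DataFrame,
    spans: pd.DataFrame | None = None,
    window_hours: float = 8.0,
    n_segments: int = 4,
    anchor_policy: str = "midpoint",
) -> pd.DataFrame:
    """Window a whole cohort's alarms frame around each patient's anchor.

    Parameters
    ----------
    alarms : DataFrame
        Alarms CSV dialect (patient_id, organization, signal, bound, start,
        end, duration_s, rep_value, cutoff).
    events : DataFrame
        patient_id, cie_type, event_time. A patient with several events is
        anchored at the earliest one.
    spans : DataFrame, optional
        patient_id, start, end of each recording; required to anchor
        patients absent from ``events``.
    anchor_policy : str
        Pseudo-anchor rule for event-free patients (see
        :func:`pseudo_anchor`).

    Returns
    -------
    DataFrame
        The windowed alarms with ``cie_status``, ``anchor_time``,
        ``lead_time_s`` and ``segment_index`` columns added.
    """
    anchors: dict[str, tuple[str, int]] = {}
    if len(events):
        first = (
            events.sort_values("event_time").groupby("patient_id", sort=False).first()
        )
        for pid, row in first.iterrows():
            anchors[str(pid)] = (str(row["cie_type"]), int(row["event_time"]))
    if spans is not None:
        for _, row in spans.iterrows():
            pid = str(row["patient_id"])
            if pid not in anchors:
                anchors[pid] = (
                    "none",
                    pseudo_anchor(int(row["start"]), int(row["end"]), anchor_policy),
                )
    pieces = []
    for pid, (status, anchor) in anchors.items():
        sub = alarms[alarms["patient_id"] == pid]
        if not len(sub):
            continue
        ev = CIEEvent(patient_id=pid, cie_type=status, event_time=anchor)
        win = window_alarms(sub, ev, window_hours)
        if not len(win):
            continue
        win["cie_status"] = status
        win["anchor_time"] = anchor
        win["segment_index"] = [
            segment_index_of(s, anchor, window_hours, n_segments)
            for s in win["start"]
        ]
        pieces.append(win)
    if not pieces:
        cols = list(alarms.columns) + [
            "lead_time_s",
            "cie_status",
            "anchor_time",
            "segment_index",
        ]
        return pd.DataFrame(columns=cols)
    return pd.concat(pieces, ignore_index=True)
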