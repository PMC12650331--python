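"""Threshold-alarm episode detection with age-specific cut-offs.

A threshold alarm is a maximal run of consecutive samples on which a vital
sign strictly exceeds its age-specific upper limit or falls strictly below
its lower limit. Two cut-off tables are built in: the WHO pediatric normal
ranges and the GOAL3 monitor defaults. Runs are broken by missing samples
and by timestamp gaps, so sensor disconnections never inflate alarm
durations.

Conventions
-----------
* Violation is strict: ``value > upper`` or ``value < lower``. A value
  exactly at the limit is normal.
* Episode duration is ``n_member_samples * interval`` seconds, so a single
  violating sample yields a 1 s episode at 1 Hz. This keeps the invariant
  that the summed episode durations equal interval times the number of
  violating samples.
* The representative value of an episode is the median of its member
  samples by default (``rep="median"``); ``"mean"`` and ``"extremum"`` (the
  most extreme value on the violating side) are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import SIGNALS, VitalSeries

ORGANIZATIONS = ("WHO", "GOAL3")

#: Age cut-offs per organization. Keys are age bands as half-open month
#: intervals [lo, hi); each band maps signal -> (lower, upper) limits in
#: signal units (bpm, breaths/min, %). ``None`` means no limit on that side.
#: SPO2 has a lower limit only (90 for every band).
_WHO_CUTOFFS = {
    ("<1 year", 0, 12): {
        "ECGHR": (100, 160),
        "ECGRR": (20, 50),
        "SPO2": (90, None),
    },
    ("1-3 years", 12, 36): {
        "ECGHR": (90, 150),
        "ECGRR": (10, 40),
        "SPO2": (90, None),
    },
    # The WHO table stops at the 3-4 year band; older children reuse it so
    # that every age resolves to a cut-off row (extension warned at lookup).
    ("3-4 years", 36, None): {
        "ECGHR": (80, 140),
        "ECGRR": (10, 40),
        "SPO2": (90, None),
    },
}

_GOAL3_CUTOFFS = {
    ("<1 year", 0, 12): {
        "ECGHR": (80, 200),
        "ECGRR": (20, 60),
        "SPO2": (90, None),
    },
    ("1-3 years", 12, 36): {
        "ECGHR": (80, 180),
        "ECGRR": (20, 50),
        "SPO2": (90, None),
    },
    ("3-4 years", 36, 48): {
        "ECGHR": (70, 170),
        "ECGRR": (20, 50),
        "SPO2": (90, None),
    },
    (">4 years", 48, None): {
        "ECGHR": (70, 170),
        "ECGRR": (20, 40),
        "SPO2": (90, None),
    },
}


@dataclass(frozen=True)
class AgeBand:
    """One age band of a cut-off table: ``[lo_months, hi_months)``."""

    key: str
    lo_months: float
    hi_months: float | None  # None = unbounded above
    limits: dict[str, tuple[float | None, float | None]]  # signal -> (lower, upper)

    def contains(self, age_months: float) -> bool:
        upper_ok = self.hi_months is None or age_months < self.hi_months
        return age_months >= self.lo_months and upper_ok


@dataclass(frozen=True)
class CutoffTable:
    """Per-organization age cut-offs for ECGHR, ECGRR and SPO2."""

    organization: str
    bands: tuple[AgeBand, ...]

    def band_for_age(self, age_months: float) -> AgeBand:
        if age_months < 0:
            raise ValueError("age_months must be non-negative")
        for band in self.bands:
            if band.contains(age_months):
                if band.hi_months is None and self.organization == "WHO" and age_months >= 60:
                    warnings.warn(
                        f"age {age_months} months falls beyond the WHO table; "
                        f"using the extended top band {band.key!r}",
                        stacklevel=2,
                    )
                return band
        raise ValueError(f"no age band covers {age_months} months")  # pragma: no cover


def builtin_cutoffs(organization: str) -> CutoffTable:
    """Return the built-in WHO or GOAL3 cut-off table.

    Parameters
    ----------
    organization : {"WHO", "GOAL3"}
        Case-insensitive.
    """
    org = organization.upper()
    tables = {"WHO": _WHO_CUTOFFS, "GOAL3": _GOAL3_CUTOFFS}
    if org not in tables:
        raise ValueError(
            f"unknown organization {organization!r}; valid options: WHO, GOAL3"
        )
    bands = tuple(
        AgeBand(key=key, lo_months=lo, hi_months=hi, limits=dict(limits))
        for (key, lo, hi), limits in tables[org].items()
    )
    return CutoffTable(organization=org, bands=bands)


def assign_age_group(age_months: float, table: CutoffTable) -> str:
    """Return the key of the age band containing ``age_months``.

    Bands are half-open ``[lo, hi)`` in months, so an exactly-12-month-old
    falls in the 1-3 year band.
    """
    return table.band_for_age(age_months).key


@dataclass(frozen=True)
class AlarmEpisode:
    """One contiguous threshold violation.

    ``duration`` is member-sample count times the sampling interval;
    ``rep_value`` summarizes the violating samples and always violates
    ``cutoff`` on the stated side.
    """

    patient_id: str
    signal: str
    bound: str  # "upper" | "lower"
    start: int  # epoch seconds of first violating sample
    end: int  # epoch seconds of last violating sample
    duration: float  # seconds
    rep_value: float
    cutoff: float
    organization: str


_EPISODE_COLUMNS = [
    "patient_id",
    "organization",
    "signal",
    "bound",
    "start",
    "end",
    "duration_s",
    "rep_value",
    "cutoff",
]


def episodes_to_frame(episodes: list[AlarmEpisode]) -> pd.DataFrame:
    """Tabulate episodes in the alarms CSV dialect."""
    if not episodes:
        return pd.DataFrame(columns=_EPISODE_COLUMNS)
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in episodes],
            "organization": [e.organization for e in episodes],
            "signal": [e.signal for e in episodes],
            "bound": [e.bound for e in episodes],
            "start": [e.start for e in episodes],
            "end": [e.end for e in episodes],
            "duration_s": [e.duration for e in episodes],
            "rep_value": [e.rep_value for e in episodes],
            "cutoff": [e.cutoff for e in episodes],
        }
    )


def _representative(values: np.ndarray, bound: str, rep: str) -> float:
    if rep == "median":
        return float(np.median(values))
    if rep == "mean":
        return float(np.mean(values))
    if rep == "extremum":
        return float(values.max() if bound == "upper" else values.min())
    raise ValueError(f"unknown rep {rep!r}; valid: median, mean, extremum")


def detect_episodes(
    series: VitalSeries,
    age_months: float,
    table: CutoffTable,
    rep: str = "median",
) -> list[AlarmEpisode]:
    """Detect threshold-alarm episodes in one patient's stream.

    A sample violates iff ``value > upper`` (bound "upper") or
    ``value < lower`` (bound "lower") for the patient's age band. Maximal
    runs of consecutive violating samples on the same side form one episode
    each; a missing sample or a timestamp gap larger than the sampling
    interval terminates the run. Output is sorted by start time (ties broken
    by signal then bound for determinism).

    Returns an empty list for an empty series; an all-missing signal
    contributes no episodes.
    """
    if len(series) == 0:
        return []
    band = table.band_for_age(age_months)
    ts = series.timestamps
    # a gap strictly wider than the nominal interval splits runs
    gap_break = np.zeros(ts.size, dtype=bool)
    if ts.size > 1:
        gap_break[1:] = np.diff(ts) > series.interval

    episodes: list[AlarmEpisode] = []
    for signal in SIGNALS:
        values = series.signals.get(signal)
        limits = band.limits.get(signal)
        if values is None or limits is None:
            continue
        lower, upper = limits
        sides: list[tuple[str, float, np.ndarray]] = []
        with np.errstate(invalid="ignore"):
            if upper is not None:
                sides.append(("upper", float(upper), values > upper))
            if lower is not None:
                sides.append(("lower", float(lower), values < lower))
        for bound, cutoff, violating in sides:
            violating = violating & np.isfinite(values)
            if not violating.any():
                continue
            # run starts where a violating sample is not preceded by a
            # violating sample on a contiguous grid step
            starts = violating & (
                ~np.roll(violating, 1) | gap_break
            )
            starts[0] = violating[0]
            breaks = ~violating | gap_break
            idx_starts = np.flatnonzero(starts)
            # run end: next break at or after start
            break_idx = np.flatnonzero(breaks)
            for s in idx_starts:
                nxt = break_idx[np.searchsorted(break_idx, s + 1)] if (
                    break_idx.size and break_idx[-1] > s
                ) else ts.size
                e = nxt - 1
                run = values[s : e + 1]
                episodes.append(
                    AlarmEpisode(
                        patient_id=series.patient_id,
                        signal=signal,
                        bound=bound,
                        start=int(ts[s]),
                        end=int(ts[e]),
                        duration=float((e - s + 1) * series.interval),
                        rep_value=_representative(run, bound, rep),
                        cutoff=cutoff,
                        organization=table.organization,
                    )
                )
    episodes.sort(key=lambda ep: (ep.start, ep.signal, ep.bound))
    return episodes


def tabulate_counts(per_signal_counts: pd.DataFrame) -> pd.DataFrame:
    """Alarm-summary arithmetic on a strata x signals count table.

    Parameters
    ----------
    per_signal_counts : DataFrame
        Rows are patient strata (e.g. "without_cie", "with_cie"), columns
        are signals, values are alarm counts.

    Returns
    -------
    DataFrame
        Adds a ``total`` column (row sums), an ``all`` row (column sums),
        a ``pct_of_total`` column (each stratum's share of all alarms) and
        per-signal ``pct_<signal>`` columns (each signal's share of its
        stratum total), all percentages rounded to the nearest integer.
    """
    counts = per_signal_counts.astype("int64").copy()
    counts.loc["all"] = counts.sum(axis=0)
    counts["total"] = counts.drop(columns="total", errors="ignore").sum(axis=1)
    grand = counts.loc["all", "total"]
    if grand > 0:
        counts["pct_of_total"] = (100 * counts["total"] / grand).round().astype(int)
    else:
        counts["pct_of_total"] = 0
    for sig in per_signal_counts.columns:
        with np.errstate(invalid="ignore", divide="ignore"):
            share = 100 * counts[sig] / counts["total"]
        counts[f"pct_{sig.lower()}"] = (
            share.replace([np.inf, -np.inf], np.nan).fillna(0).round().astype(int)
        )
    return counts


def summarize_alarms(
    episodes: pd.DataFrame | list[AlarmEpisode],
    manifest: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Summary of alarm counts per organization, stratified by CIE status.

    Parameters
    ----------
    episodes : DataFrame or list of AlarmEpisode
        Alarm records tagged with ``organization``, ``signal``,
        ``patient_id``.
    manifest : DataFrame
        Cohort manifest with ``patient_id`` and ``cie_type`` ("none" marks
        patients without a critical illness event).

    Returns
    -------
    dict of organization -> DataFrame
        One table per organization in the style of a cohort alarm summary:
        strata "without_cie" / "with_cie" / "all", per-signal counts,
        totals and integer percentages (see :func:`tabulate_counts`).
    """
    if isinstance(episodes, list):
        episodes = episodes_to_frame(episodes)
    cie_by_patient = manifest.set_index("patient_id")["cie_type"]
    out: dict[str, pd.DataFrame] = {}
    orgs = episodes["organization"].unique() if len(episodes) else ORGANIZATIONS
    for org in orgs:
        sub = episodes[episodes["organization"] == org]
        strata = sub["patient_id"].map(cie_by_patient).fillna("none")
        strata = np.where(strata == "none", "without_cie", "with_cie")
        counts = (
            pd.crosstab(pd.Series(strata, name="stratum"), sub["signal"])
            if len(sub)
            else pd.DataFrame()
        )
        counts = counts.reindex(
            index=["without_cie", "with_cie"], columns=list(SIGNALS), fill_value=0
        ).fillna(0)
        out[org] = tabulate_counts(counts)
    return out
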