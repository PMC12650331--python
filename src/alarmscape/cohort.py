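"""Synthetic pediatric cohorts with planted pre-event alarm patterns.

Real high-dependency-unit monitoring data are not redistributable, so every
downstream stage of the pipeline is exercised on simulated cohorts that
emulate the relevant structure of ward monitoring: 1 Hz vital-sign streams
(ECG heart rate, ECG respiratory rate, oxygen saturation) of at least 24 h,
sensor-dropout gaps, brief motion/crying artifacts, a pediatric age mix, and
critical-illness events (death/CPR/PICU transfer, or sepsis) preceded by
bursts of threshold alarms whose values sit in signal-specific ranges.

The generative model is deliberately simple: each signal is a bounded
mean-reverting random walk around an age-appropriate baseline (the midpoint
of the WHO normal band, clipped inside the intersection of the WHO and GOAL3
bands so a healthy patient never alarms under either cut-off table), with
planted excursions overwriting the walk. Values are rounded to integers, as
monitors report them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alarms import builtin_cutoffs
from .series import SIGNALS, VitalSeries

CIE_TYPES = ("death_cpr_picu", "sepsis")

#: Table-style cohort age mix: month interval [lo, hi) -> proportion.
#: Neonates (<1 month), infants (1-11 months), pediatric (1-5 years).
DEFAULT_AGE_DISTRIBUTION = {
    (0.0, 1.0): 0.0014,
    (1.0, 12.0): 0.4261,
    (12.0, 60.0): 0.5725,
}

#: Observed CIE class mix among death/CPR/PICU (54 + 19) and sepsis (46).
DEFAULT_CIE_MIX = {"death_cpr_picu": 73 / 119, "sepsis": 46 / 119}


@dataclass(frozen=True)
class PatternSpec:
    """A planted pre-event alarm pattern for one (signal, bound).

    ``value_range`` is the inclusive range of integer alarm values injected;
    ``typical_duration`` the mean episode length in seconds; ``onset_window``
    the pre-event span (hours, at most 8) in which episodes occur;
    ``burst_rate`` the expected episodes per hour.
    """

    signal: str
    bound: str
    value_range: tuple[float, float]
    typical_duration: float = 12.0
    onset_window: float = 8.0
    burst_rate: float = 4.0

    def __post_init__(self) -> None:
        if self.signal not in SIGNALS:
            raise ValueError(f"unknown signal {self.signal!r}")
        if self.bound not in ("upper", "lower"):
            raise ValueError(f"bound must be 'upper' or 'lower', got {self.bound!r}")
        lo, hi = self.value_range
        if lo > hi:
            raise ValueError("value_range lo must be <= hi")
        if self.typical_duration <= 0:
            raise ValueError("typical_duration must be positive")
        if self.onset_window > 8:
            raise ValueError("onset_window must be at most 8 h")


def _spec(signal, bound, lo, hi, **kw):
    return PatternSpec(signal=signal, bound=bound, value_range=(lo, hi), **kw)


#: Pattern tables per cut-off organization and CIE type. The value ranges are
#: the signal-specific alarm clusters observed before each event type; the
#: GOAL3 SPO2 cluster sits at the 90% limit itself, so values just below
#: (88-90) are planted — a value exactly at the limit never alarms.
DEFAULT_PATTERNS = {
    "WHO": {
        "death_cpr_picu": [
            _spec("ECGRR", "upper", 40, 60),
            _spec("ECGRR", "lower", 0, 20),
            _spec("ECGHR", "lower", 80, 85),
            _spec("ECGHR", "upper", 140, 160),
            _spec("SPO2", "lower", 85, 90),
        ],
        "sepsis": [
            _spec("ECGRR", "upper", 40, 50),
            _spec("ECGRR", "lower", 0, 20),
            _spec("ECGHR", "upper", 150, 180),
            _spec("SPO2", "lower", 85, 85),
        ],
    },
    "GOAL3": {
        "death_cpr_picu": [
            _spec("ECGRR", "upper", 50, 70),
            _spec("ECGRR", "lower", 0, 20),
            _spec("ECGHR", "lower", 70, 85),
            _spec("ECGHR", "upper", 150, 175),
            _spec("SPO2", "lower", 88, 90),
        ],
        "sepsis": [
            _spec("ECGRR", "upper", 40, 50),
            _spec("ECGRR", "lower", 0, 20),
            _spec("ECGHR", "upper", 170, 200),
            _spec("SPO2", "lower", 88, 90),
        ],
    },
}


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults reproduce the cohort regime of a pediatric HDU monitoring
    study: 31% CIE prevalence, a 73:46 death-to-sepsis mix among modeled
    CIEs, the neonate/infant/pediatric age mix, 24 h of 1 Hz recording.
    """

    n_patients: int = 100
    cie_fraction: float = 0.31
    cie_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CIE_MIX))
    age_distribution: dict[tuple[float, float], float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTION)
    )
    record_hours: float = 24.0
    sample_interval: float = 1.0
    dropout_rate: float = 0.02
    artifact_rate: float = 2.0  # transient excursions per hour, non-CIE patients
    seed: int = 0
    allow_short_records: bool = False  # permit <24 h records (smoke tests)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not 0 <= self.cie_fraction <= 1:
            raise ValueError("cie_fraction must lie in [0, 1]")
        for name, mix in (("cie_mix", self.cie_mix), ("age_distribution", self.age_distribution)):
            if any(not 0 <= p <= 1 for p in mix.values()):
                raise ValueError(f"{name} proportions must lie in [0, 1]")
            if mix and abs(sum(mix.values()) - 1) > 1e-6:
                raise ValueError(f"{name} proportions must sum to 1")
        if self.record_hours < 24 and not self.allow_short_records:
            raise ValueError(
                "record_hours must be at least 24 (set allow_short_records=True "
                "for short smoke-test records)"
            )
        if self.record_hours <= 0 or self.sample_interval <= 0:
            raise ValueError("record_hours and sample_interval must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be non-negative")


@dataclass
class Injection:
    """Log entry for one planted excursion (pattern episode or artifact)."""

    signal: str
    bound: str
    start_index: int
    length: int
    value: float


@dataclass
class SyntheticPatient:
    """One simulated patient: stream, demographics, event annotation."""

    patient_id: str
    age_months: float
    sex: str
    cie_type: str  # "none" | "death_cpr_picu" | "sepsis"
    cie_time: int | None  # epoch seconds; None iff cie_type == "none"
    series: VitalSeries
    injections: list[Injection] = field(default_factory=list)


# --- baselines -------------------------------------------------------------

#: per-signal random-walk innovation scale (signal units per step at 1 Hz)
_NOISE_SCALE = {"ECGHR": 0.6, "ECGRR": 0.4, "SPO2": 0.15}
_MEAN_REVERSION = 0.01


def _safe_band(age_months: float, signal: str) -> tuple[float, float]:
    """Intersection of the WHO and GOAL3 normal bands for this age/signal,
    shrunk by a 2-unit margin so integer rounding cannot cross a limit."""
    lo, hi = -np.inf, np.inf
    for org in ("WHO", "GOAL3"):
        lower, upper = builtin_cutoffs(org).band_for_age(age_months).limits[signal]
        if lower is not None:
            lo = max(lo, lower)
        if upper is not None:
            hi = min(hi, upper)
    if not np.isfinite(hi):  # SPO2: lower limit only
        hi = 100.0
    return lo + 2.0, hi - 2.0


def baseline_value(age_months: float, signal: str) -> float:
    """Age-appropriate resting value: the WHO normal-band midpoint (97% for
    SPO2, which has no upper limit), clamped inside the safe band."""
    lower, upper = builtin_cutoffs("WHO").band_for_age(age_months).limits[signal]
    mid = 97.0 if upper is None else (lower + upper) / 2.0
    lo, hi = _safe_band(age_months, signal)
    return float(np.clip(mid, lo, hi))


def generate_vital_series(
    age_months: float,
    hours: float,
    interval: float = 1.0,
    seed: int = 0,
    noise_scale: dict[str, float] | None = None,
    start_epoch: int = 0,
    patient_id: str = "P0",
) -> VitalSeries:
    """Simulate one patient's healthy stream.

    Each signal is a mean-reverting random walk around the age-appropriate
    baseline, clipped inside the safe normal band and rounded to integers.
    ``noise_scale`` maps signal -> innovation standard deviation; an entry of
    0 gives a constant baseline. With the default scales a healthy stream
    triggers no alarms under either cut-off table.
    """
    if hours <= 0:
        raise ValueError("hours must be positive")
    n = int(round(hours * 3600 / interval))
    ts = start_epoch + np.arange(n, dtype=np.int64) * int(interval)
    rng = np.random.default_rng(seed)
    scales = dict(_NOISE_SCALE)
    if noise_scale:
        scales.update(noise_scale)
    signals = {}
    for sig in SIGNALS:
        mu = baseline_value(age_months, sig)
        sigma = scales[sig]
        lo, hi = _safe_band(age_months, sig)
        if sigma == 0:
            x = np.full(n, mu)
        else:
            steps = rng.normal(0.0, sigma, size=n)
            x = _mean_reverting_walk(mu, steps, lo, hi)
        x = np.clip(np.round(x), np.ceil(lo), np.floor(hi))
        if sig == "SPO2":
            x = np.clip(x, 0.0, 100.0)
        signals[sig] = x
    return VitalSeries(
        patient_id=patient_id, timestamps=ts, signals=signals, interval=interval
    )


def _mean_reverting_walk(
    mu: float, steps: np.ndarray, lo: float, hi: float
) -> np.ndarray:
    """x_t = x_{t-1} + theta*(mu - x_{t-1}) + step_t, clipped to [lo, hi].

    The recursion is the AR(1) filter y_t = (1-theta)*y_{t-1} + step_t on the
    deviation from mu, evaluated exactly with a linear IIR filter; clipping is
    applied at the end (the stationary spread is a few innovation SDs, so the
    clip rarely binds).
    """
    from scipy.signal import lfilter

    deviation = lfilter([1.0], [1.0, -(1.0 - _MEAN_REVERSION)], steps)
    return np.clip(mu + deviation, lo, hi)


def inject_dropout(series: VitalSeries, rate: float, seed: int = 0) -> VitalSeries:
    """Return a copy with a Bernoulli(rate) subset of samples set missing.

    Timestamps are untouched; the same mask applies to all signals, as a
    sensor disconnection drops the whole frame.
    """
    if not 0 <= rate < 1:
        raise ValueError("dropout rate must lie in [0, 1)")
    if rate == 0:
        return series
    rng = np.random.default_rng(seed)
    mask = rng.random(len(series)) < rate
    signals = {}
    for name, values in series.signals.items():
        values = values.copy()
        values[mask] = np.nan
        signals[name] = values
    return VitalSeries(
        patient_id=series.patient_id,
        timestamps=series.timestamps,
        signals=signals,
        interval=series.interval,
    )


def _inject_excursions(
    series: VitalSeries,
    specs: list[PatternSpec],
    anchor_epoch: int,
    rng: np.random.Generator,
) -> list[Injection]:
    """Overwrite the walk with planted episodes inside each spec's window.

    Episode count ~ Poisson(burst_rate * onset_window); start times uniform
    in [anchor - onset_window, anchor); durations geometric around
    typical_duration (clipped to [2, 120] samples); values integer-uniform
    in value_range, constant within an episode.
    """
    injections: list[Injection] = []
    ts0 = series.start
    n = len(series)
    for spec in specs:
        window_s = spec.onset_window * 3600
        n_eps = rng.poisson(spec.burst_rate * spec.onset_window)
        values = series.signals[spec.signal]
        for _ in range(n_eps):
            t = anchor_epoch - rng.uniform(0, window_s)
            i0 = int((t - ts0) / series.interval)
            if not 0 <= i0 < n:
                continue
            length = int(np.clip(rng.geometric(1.0 / spec.typical_duration), 2, 120))
            i1 = min(i0 + length, n)
            lo, hi = spec.value_range
            value = float(rng.integers(int(lo), int(hi) + 1))
            values[i0:i1] = value
            injections.append(
                Injection(
                    signal=spec.signal,
                    bound=spec.bound,
                    start_index=i0,
                    length=i1 - i0,
                    value=value,
                )
            )
    return injections


def _artifact_specs(age_months: float, rate: float) -> list[PatternSpec]:
    """Transient crying/coughing-style excursions just beyond the WHO limits,
    shorter than 30 s, spread over the whole record."""
    specs = []
    band = builtin_cutoffs("WHO").band_for_age(age_months)
    for sig in SIGNALS:
        lower, upper = band.limits[sig]
        for bound, limit in (("upper", upper), ("lower", lower)):
            if limit is None:
                continue
            if bound == "upper":
                vr = (limit + 1, limit + 8)
            else:
                vr = (max(limit - 8, 0), limit - 1)
            specs.append(
                PatternSpec(
                    signal=sig,
                    bound=bound,
                    value_range=vr,
                    typical_duration=6.0,
                    onset_window=8.0,  # unused for artifacts (full-record window)
                    burst_rate=rate / 6.0,  # rate split over 6 signal-bound slots
                )
            )
    return specs


def _inject_artifacts(
    series: VitalSeries,
    age_months: float,
    rate: float,
    hours: float,
    rng: np.random.Generator,
) -> list[Injection]:
    injections: list[Injection] = []
    n = len(series)
    for spec in _artifact_specs(age_months, rate):
        n_eps = rng.poisson(spec.burst_rate * hours)
        values = series.signals[spec.signal]
        for _ in range(n_eps):
            i0 = int(rng.integers(0, n))
            length = int(np.clip(rng.geometric(1.0 / spec.typical_duration), 1, 29))
            i1 = min(i0 + length, n)
            lo, hi = spec.value_range
            value = float(rng.integers(int(lo), int(hi) + 1))
            values[i0:i1] = value
            injections.append(
                Injection(spec.signal, spec.bound, i0, i1 - i0, value)
            )
    return injections


def generate_cohort(
    config: CohortConfig,
    pattern_specs: dict[str, list[PatternSpec]] | None = None,
) -> list[SyntheticPatient]:
    """Generate a cohort of synthetic patients.

    Parameters
    ----------
    config : CohortConfig
    pattern_specs : dict of cie_type -> list of PatternSpec, optional
        Planted pre-event patterns per event type; defaults to the WHO
        pattern table (:data:`DEFAULT_PATTERNS`).

    Returns
    -------
    list of SyntheticPatient
        Deterministic for a fixed config (per-patient streams are seeded
        from a spawned seed sequence).
    """
    if pattern_specs is None:
        pattern_specs = DEFAULT_PATTERNS["WHO"]
    active_types = [t for t, p in config.cie_mix.items() if p > 0]
    if config.cie_fraction > 0:
        missing = [t for t in active_types if not pattern_specs.get(t)]
        if missing:
            raise ValueError(f"pattern_specs missing for cie types: {missing}")
        for specs in pattern_specs.values():
            for spec in specs:
                if spec.onset_window > config.record_hours:
                    raise ValueError("onset_window exceeds record_hours")

    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_patients)

    age_groups = list(config.age_distribution.keys())
    age_probs = np.array([config.age_distribution[g] for g in age_groups])
    mix_types = list(config.cie_mix.keys())
    mix_probs = np.array([config.cie_mix[t] for t in mix_types]) if mix_types else None

    patients: list[SyntheticPatient] = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(child_seeds[i])
        lo, hi = age_groups[int(rng.choice(len(age_groups), p=age_probs))]
        age = float(rng.uniform(lo, hi))
        sex = "M" if rng.random() < 0.58 else "F"
        is_cie = bool(rng.random() < config.cie_fraction)
        cie_type = (
            mix_types[int(rng.choice(len(mix_types), p=mix_probs))]
            if is_cie and mix_types
            else "none"
        )
        pid = f"SYN-{config.seed}-{i:04d}"
        series = generate_vital_series(
            age_months=age,
            hours=config.record_hours,
            interval=config.sample_interval,
            seed=rng.integers(0, 2**31 - 1),
            patient_id=pid,
        )
        cie_time = None
        injections: list[Injection] = []
        if cie_type != "none":
            # event no earlier than 8 h in, so the pre-event window exists
            earliest = series.start + int(8 * 3600)
            cie_time = int(rng.integers(earliest, series.end + 1))
            injections = _inject_excursions(
                series, pattern_specs[cie_type], cie_time, rng
            )
        elif config.artifact_rate > 0:
            injections = _inject_artifacts(
                series, age, config.artifact_rate, config.record_hours, rng
            )
        if config.dropout_rate > 0:
            series = inject_dropout(
                series, config.dropout_rate, seed=int(rng.integers(0, 2**31 - 1))
            )
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                age_months=age,
                sex=sex,
                cie_type=cie_type,
                cie_time=cie_time,
                series=series,
                injections=injections,
            )
        )
    return patients


def cohort_manifest(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Manifest frame: patient_id, age_months, sex, cie_type, cie_time."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age_months": [p.age_months for p in patients],
            "sex": [p.sex for p in patients],
            "cie_type": [p.cie_type for p in patients],
            "cie_time": [p.cie_time for p in patients],
        }
    )
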