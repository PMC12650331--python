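"""In-memory containers for vital-sign streams.

A :class:`VitalSeries` holds one patient's regularly sampled multi-signal
stream (heart rate, respiratory rate, oxygen saturation) on an epoch-seconds
axis. Missing samples — sensor disconnections — are NaN; the timestamp grid
itself is never removed, so gaps are visible to downstream episode detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical signal names, fixed order used throughout
SIGNALS = ("ECGHR", "ECGRR", "SPO2")

#: CSV column names for each signal
_SIGNAL_COLUMNS = {"ECGHR": "ecghr", "ECGRR": "ecgrr", "SPO2": "spo2"}


@dataclass
class VitalSeries:
    """One patient's vital-sign stream.

    Parameters
    ----------
    patient_id : str
        Opaque patient identifier.
    timestamps : ndarray of int64
        Strictly increasing epoch seconds.
    signals : dict of str -> ndarray of float
        One array per signal in :data:`SIGNALS`, aligned to ``timestamps``.
        NaN marks a missing sample. SPO2 values lie in [0, 100] when present.
    interval : float
        Nominal sampling interval in seconds (default 1, i.e. 1 Hz).
    """

    patient_id: str
    timestamps: np.ndarray
    signals: dict[str, np.ndarray] = field(default_factory=dict)
    interval: float = 1.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for name, values in self.signals.items():
            values = np.asarray(values, dtype=float)
            if values.shape != self.timestamps.shape:
                raise ValueError(
                    f"signal {name!r} length {values.size} != "
                    f"{self.timestamps.size} timestamps"
                )
            self.signals[name] = values
        spo2 = self.signals.get("SPO2")
        if spo2 is not None:
            finite = spo2[np.isfinite(spo2)]
            if finite.size and (finite.min() < 0 or finite.max() > 100):
                raise ValueError("SPO2 values must lie in [0, 100]")
        if self.interval <= 0:
            raise ValueError("interval must be positive")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def start(self) -> int:
        return int(self.timestamps[0])

    @property
    def end(self) -> int:
        return int(self.timestamps[-1])

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: patient_id, timestamp, ecghr, ecgrr, spo2."""
        data = {"patient_id": self.patient_id, "timestamp": self.timestamps}
        for name in SIGNALS:
            if name in self.signals:
                data[_SIGNAL_COLUMNS[name]] = self.signals[name]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, interval: float = 1.0) -> "VitalSeries":
        """Rebuild a series from the CSV dialect written by :meth:`to_frame`."""
        pid = str(frame["patient_id"].iloc[0])
        ts = frame["timestamp"].to_numpy(dtype=np.int64)
        signals = {}
        for name, col in _SIGNAL_COLUMNS.items():
            if col in frame.columns:
                signals[name] = frame[col].to_numpy(dtype=float)
        return cls(patient_id=pid, timestamps=ts, signals=signals, interval=interval)
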