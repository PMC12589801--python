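"""Event-level data containers shared across the measurement chain.

An :class:`EventList` holds per-event scalars at one of two fidelity levels —
oscilloscope peak amplitudes (mV) or calibrated lineal energies (keV/µm) —
with bookkeeping for events clipped at the scope's full scale or dropped by
the affine calibration map.  A :class:`Trace` is a raw sampled waveform.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: unit tags used throughout the pipeline
UNIT_MV = "mV"
UNIT_KEV_UM = "keV/um"


@dataclass
class EventList:
    values: np.ndarray
    unit: str
    saturated_count: int = 0
    dropped_count: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("EventList values must be one-dimensional")
        if self.values.size and np.any(self.values < 0):
            raise ValueError("event values must be non-negative")
        if not self.unit:
            raise ValueError("EventList requires a unit tag")
        if self.saturated_count < 0 or self.dropped_count < 0:
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame({"event_id": np.arange(self.values.size),
                      "value": self.values,
                      "unit": self.unit}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, unit: str | None = None) -> "EventList":
        import pandas as pd

        df = pd.read_csv(path)
        unit = unit if unit is not None else str(df["unit"].iloc[0])
        return cls(df["value"].to_numpy(dtype=float), unit)


@dataclass
class Trace:
    """A sampled voltage waveform (mV) with a fixed sampling interval."""

    samples: np.ndarray
    sample_interval: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("Trace requires a non-empty 1-D sample array")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")

    def __len__(self) -> int:
        return self.samples.size

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame({"time": np.arange(self.samples.size) * self.sample_interval,
                      "voltage_mV": self.samples}).to_csv(path, index=False)
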