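"""In-memory containers shared across the pipeline.

A :class:`CsiSeries` holds the complex channel state information of one
(tx antenna, rx antenna, subcarrier) link over time, possibly on a
non-uniform time base.  A :class:`RatioSeries` holds the complex quotient
of two such links on a uniform grid; its trajectory on the I/Q plane is
the object the breathing extractor analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: (tx index, rx index), 1-based as reported by CSI collection firmware.
Link = tuple[int, int]

_GRID_ATOL = 1e-9  # seconds; tolerance for "uniform" spacing


@dataclass
class CsiSeries:
    """Time-ordered complex CSI samples for a single link/subcarrier."""

    timestamps: np.ndarray
    values: np.ndarray
    link: Link = (1, 1)
    subcarrier: int = 1
    freq_hz: float = 5.18e9

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.timestamps.ndim != 1 or self.values.ndim != 1:
            raise ValueError("timestamps and values must be 1-D")
        if self.timestamps.size != self.values.size:
            raise ValueError(
                f"length mismatch: {self.timestamps.size} timestamps vs "
                f"{self.values.size} values"
            )
        if self.timestamps.size and not np.all(np.isfinite(self.timestamps)):
            raise ValueError("non-finite timestamps")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite CSI values")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            i = int(np.argmax(np.diff(self.timestamps) <= 0))
            raise ValueError(
                f"timestamps not strictly increasing at index {i + 1} "
                f"(link {self.link}, subcarrier {self.subcarrier})"
            )

    @property
    def n(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def with_values(self, values: np.ndarray) -> "CsiSeries":
        return replace(self, values=np.asarray(values, dtype=complex))


@dataclass
class RatioSeries:
    """Complex two-link CSI ratio Q(t) on a uniform time grid.

    ``valid`` flags samples whose denominator magnitude cleared the
    amplitude floor; invalid samples carry NaN values and are excluded
    downstream.
    """

    timestamps: np.ndarray
    values: np.ndarray
    num_link: Link
    den_link: Link
    subcarrier: int = 1
    freq_hz: float = 5.18e9
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.valid is None:
            self.valid = np.ones(self.timestamps.size, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.timestamps.size == self.values.size == self.valid.size):
            raise ValueError("timestamps, values and valid must share length")
        if self.timestamps.size > 1:
            dt = np.diff(self.timestamps)
            if np.any(np.abs(dt - dt[0]) > _GRID_ATOL):
                raise ValueError("ratio grid is not uniform")

    @property
    def n(self) -> int:
        return self.timestamps.size

    @property
    def dt(self) -> float:
        if self.timestamps.size < 2:
            raise ValueError("grid spacing undefined for < 2 samples")
        return float(self.timestamps[1] - self.timestamps[0])

    @property
    def grid_rate(self) -> float:
        return 1.0 / self.dt
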