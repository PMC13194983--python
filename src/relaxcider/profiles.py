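"""Data containers: NMRD profiles, field bands, rate differences, decay series."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FieldPoint",
    "NMRDProfile",
    "FieldBand",
    "DEFAULT_BANDS",
    "RateDifferenceProfile",
    "DecaySeries",
    "BandStatistics",
]


@dataclass
class FieldPoint:
    """One T1 measurement: field B0 (T), T1 (s), optional SD (s), observation count."""

    B0: float
    T1: float
    T1_sd: Optional[float] = None
    n_obs: int = 1

    def __post_init__(self) -> None:
        if self.B0 <= 0:
            raise ValueError("B0 must be > 0 T")
        if self.T1 <= 0:
            raise ValueError("T1 must be > 0 s")
        if self.T1_sd is not None and self.T1_sd < 0:
            raise ValueError("T1_sd must be >= 0 s")

    @property
    def R1(self) -> float:
        return 1.0 / self.T1

    @property
    def R1_sd(self) -> Optional[float]:
        if self.T1_sd is None:
            return None
        return self.T1_sd / self.T1**2


@dataclass
class NMRDProfile:
    """A sample's T1-vs-field curve with uncertainties; points sorted by field."""

    sample_id: str
    points: List[FieldPoint]
    temperature: float = 293.0  # K
    pH: float = 7.6

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.B0)
        fields = [p.B0 for p in self.points]
        if len(set(fields)) != len(fields):
            raise ValueError(f"profile {self.sample_id}: duplicate B0 values")

    @property
    def fields(self) -> np.ndarray:
        return np.array([p.B0 for p in self.points])

    @property
    def t1(self) -> np.ndarray:
        return np.array([p.T1 for p in self.points])

    @property
    def t1_sd(self) -> np.ndarray:
        """SDs with NaN for unset values."""
        return np.array([np.nan if p.T1_sd is None else p.T1_sd for p in self.points])

    @property
    def rates(self) -> np.ndarray:
        return 1.0 / self.t1

    @property
    def rate_sd(self) -> np.ndarray:
        return self.t1_sd / self.t1**2


@dataclass(frozen=True)
class FieldBand:
    """Half-open field interval [B_min, B_max) in tesla."""

    name: str
    B_min: float
    B_max: float

    def __post_init__(self) -> None:
        if not self.B_min < self.B_max:
            raise ValueError("FieldBand requires B_min < B_max")

    def contains(self, B) -> np.ndarray:
        B = np.asarray(B)
        return (B >= self.B_min) & (B < self.B_max)


#: Default bands: low ~8 uT-8 mT, intermediate 0.1-1 T, high 1-10 T.  The
#: 8 mT-0.1 T gap is deliberately excluded from band statistics.
DEFAULT_BANDS: Tuple[FieldBand, ...] = (
    FieldBand("low", 5e-6, 8e-3),
    FieldBand("intermediate", 0.1, 1.0),
    FieldBand("high", 1.0, 10.0),
)


@dataclass
class BandStatistics:
    """Unweighted mean T1 +/- sample SD over the points inside one band."""

    band: FieldBand
    mean_t1: Optional[float]
    sd_t1: Optional[float]
    n: int
    single_observation: bool = False

    @property
    def empty(self) -> bool:
        return self.n == 0


@dataclass
class RateDifferenceProfile:
    """Pointwise R1 difference between two profiles (the isolated mechanism)."""

    pair: Tuple[str, str]
    B0: np.ndarray
    delta_R1: np.ndarray
    delta_R1_sd: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.B0 = np.asarray(self.B0, dtype=float)
        self.delta_R1 = np.asarray(self.delta_R1, dtype=float)
        self.delta_R1_sd = np.asarray(self.delta_R1_sd, dtype=float)
        if np.any(self.delta_R1_sd[np.isfinite(self.delta_R1_sd)] < 0):
            raise ValueError("delta_R1_sd must be >= 0")


@dataclass
class DecaySeries:
    """Time-stamped signal amplitudes with the acquisition flip angle."""

    time: np.ndarray  # s
    signal: np.ndarray
    flip_angle: float = 90.0  # degrees
    repetition_time: Optional[float] = None  # s, uniform sampling interval

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size
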