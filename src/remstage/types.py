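"""Core domain containers for single-channel sleep-EEG analysis.

The pipeline operates on a single EEG channel in microvolts, staged on the
AASM 30-second epoch grid with the five-stage vocabulary (AWA, REM, N1, N2,
N3) plus an UNSCORED marker for epochs the expert could not classify.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np

from .errors import ConfigError, DataError

#: AASM five-stage vocabulary plus the unscorable marker.
STAGES = ("AWA", "REM", "N1", "N2", "N3")
UNSCORED = "UNSCORED"
VOCABULARY = STAGES + (UNSCORED,)

#: Analysis grid constants: 30-s epochs of 1-s sub-epochs at 256 Hz.
EPOCH_LENGTH_S = 30
SUBEPOCH_LENGTH_S = 1
TARGET_RATE = 256
EPOCH_SAMPLES = EPOCH_LENGTH_S * TARGET_RATE  # 7680
SUBEPOCHS_PER_EPOCH = EPOCH_LENGTH_S // SUBEPOCH_LENGTH_S


@dataclass
class SignalRecord:
    """One EEG channel: samples in microvolts at a fixed sampling rate."""

    samples: np.ndarray
    rate: float
    channel_label: str = "EEG"
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.size == 0:
            raise DataError("signal must contain at least one sample")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class Hypnogram:
    """Ordered stage labels on the 30-s epoch grid."""

    labels: tuple[str, ...]
    epoch_length_s: int = EPOCH_LENGTH_S

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 1:
            raise DataError("hypnogram must contain at least one epoch label")
        bad = sorted({l for l in self.labels if l not in VOCABULARY})
        if bad:
            raise DataError(f"labels outside vocabulary {VOCABULARY}: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> dict[str, int]:
        return {s: sum(1 for l in self.labels if l == s) for s in VOCABULARY}


@dataclass
class EpochGrid:
    """Stage-labelled 30-s sample blocks at 256 Hz (rows of shape 7680)."""

    stages: list[str]
    blocks: np.ndarray
    rate: int = TARGET_RATE

    def __post_init__(self) -> None:
        self.blocks = np.atleast_2d(np.asarray(self.blocks, dtype=float))
        if self.blocks.shape[0] != len(self.stages):
            raise DataError(
                f"{len(self.stages)} stage labels but {self.blocks.shape[0]} blocks"
            )
        expected = EPOCH_LENGTH_S * self.rate
        if self.blocks.shape[1] != expected:
            raise DataError(
                f"epoch blocks must have {expected} samples, got {self.blocks.shape[1]}"
            )

    def __len__(self) -> int:
        return len(self.stages)

    def restrict(self, stage: str) -> "EpochGrid":
        idx = [i for i, s in enumerate(self.stages) if s == stage]
        if not idx:
            raise DataError(f"no {stage} epochs present")
        return EpochGrid([self.stages[i] for i in idx], self.blocks[idx], self.rate)


@dataclass
class SpectrumEstimate:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    density: np.ndarray
    window_length_s: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.freqs.size != self.density.size:
            raise DataError("frequency grid and density must have equal length")
        if self.freqs.size >= 2 and not np.all(np.diff(self.freqs) > 0):
            raise DataError("frequency grid must be strictly increasing")
        if np.any(self.density < -1e-12):
            raise DataError("power density must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class SefSummary:
    """Spectral-edge summary of one epoch: median (SEF50), 95% edge, difference."""

    sef50: float
    sef95: float

    def __post_init__(self) -> None:
        if not 0 <= self.sef50 <= self.sef95:
            raise DataError(f"need 0 <= SEF50 <= SEF95, got {self.sef50}, {self.sef95}")

    @property
    def sefd(self) -> float:
        return self.sef95 - self.sef50


@dataclass(frozen=True)
class BandPair:
    """Derived phasic (FREM, lower) and tonic (TREM, upper) frequency bands in Hz."""

    frem: tuple[float, float]
    trem: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("frem", self.frem), ("trem", self.trem)):
            if not lo < hi:
                raise DataError(f"{name} band must satisfy lo < hi, got ({lo}, {hi})")
        if self.frem[0] > self.trem[0] or self.frem[1] > self.trem[1]:
            raise DataError(
                f"FREM must be the lower band: frem={self.frem}, trem={self.trem}"
            )


#: The bands obtained on the reference dataset; used when no REM labels are
#: available to re-derive them.
DEFAULT_BANDS = BandPair(frem=(2.0, 8.0), trem=(7.0, 16.0))
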