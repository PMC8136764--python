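"""Resampling, zero-phase Chebyshev-I band limiting and epoch segmentation.

The analysis grid is fixed at 256 Hz: signals are first resampled, then
high-pass filtered (Chebyshev type I, order 1, 0.5 Hz) and low-pass
filtered (Chebyshev type I, order 11, 40 Hz), both applied forward and
backward so the net phase is zero, and finally cut into 30-s stage-labelled
epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DataError
from .types import (
    EPOCH_LENGTH_S,
    TARGET_RATE,
    UNSCORED,
    EpochGrid,
    Hypnogram,
    SignalRecord,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter/resampler parameters.

    The ripple is a conventional design value; the cutoffs and orders define
    the 0.5-40 Hz analysis band.
    """

    target_rate: int = TARGET_RATE
    hp_cutoff: float = 0.5
    hp_order: int = 1
    lp_cutoff: float = 40.0
    lp_order: int = 11
    ripple_db: float = 1.0


DEFAULT_CONFIG = PreprocessConfig()


def resample_to_target(rec: SignalRecord, target_rate: float = TARGET_RATE) -> SignalRecord:
    """Polyphase rational resampling to ``target_rate`` (anti-aliased)."""
    if target_rate <= 0:
        raise ConfigError(f"target rate must be positive, got {target_rate}")
    if rec.rate == target_rate:
        return rec
    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    y = sps.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return SignalRecord(
        samples=y, rate=float(target_rate), channel_label=rec.channel_label,
        start_time=rec.start_time,
    )


def _sos(cfg: PreprocessConfig, rate: float):
    hp = sps.cheby1(cfg.hp_order, cfg.ripple_db, cfg.hp_cutoff, "highpass",
                    fs=rate, output="sos")
    lp = sps.cheby1(cfg.lp_order, cfg.ripple_db, cfg.lp_cutoff, "lowpass",
                    fs=rate, output="sos")
    return hp, lp

def bandlimit(rec: SignalRecord, cfg: PreprocessConfig = DEFAULT_CONFIG) -> SignalRecord:
    """Zero-phase 0.5-40 Hz band limiting at the 256 Hz analysis rate.

    Forward-backward application doubles the effective filter order; the
    design intent is anti-causal (zero-lag) behaviour, not a particular
    transfer function.
    """
    if rec.rate != cfg.target_rate:
        raise ConfigError(
            f"bandlimit expects the {cfg.target_rate} Hz analysis rate, got "
            f"{rec.rate} Hz; resample first"
        )
    hp, lp = _sos(cfg, rec.rate)
    y = sps.sosfiltfilt(hp, rec.samples)
    y = sps.sosfiltfilt(lp, y)
    return SignalRecord(samples=y, rate=rec.rate, channel_label=rec.channel_label,
                        start_time=rec.start_time)


def bandlimit_response_db(freq_hz: float, cfg: PreprocessConfig = DEFAULT_CONFIG,
                          rate: float = TARGET_RATE) -> float:
    """Net forward-backward cascade magnitude (dB) at one frequency."""
    hp, lp = _sos(cfg, rate)
    w = [freq_hz]
    _, h_hp = sps.sosfreqz(hp, worN=w, fs=rate)
    _, h_lp = sps.sosfreqz(lp, worN=w, fs=rate)
    mag = (np.abs(h_hp[0]) * np.abs(h_lp[0])) ** 2  # applied twice
    return float(20 * np.log10(mag + 1e-300))


def segment(
    rec: SignalRecord,
    hyp: Hypnogram | None = None,
    drop_unscored: bool = True,
) -> EpochGrid:
    """Cut the signal into labelled 30-s epochs (0-based, half-open blocks).

    Epoch ``i`` holds samples ``[i*7680, (i+1)*7680)``.  A trailing partial
    epoch is dropped.  Without a hypnogram every full epoch is kept with an
    UNSCORED placeholder label and ``drop_unscored`` is ignored.
    """
    if rec.rate != TARGET_RATE:
        raise ConfigError(f"segment expects {TARGET_RATE} Hz input, got {rec.rate}")
    per = EPOCH_LENGTH_S * TARGET_RATE
    n_signal = rec.samples.size // per
    if n_signal < 1:
        raise DataError("signal shorter than one complete 30-s epoch")

    if hyp is None:
        labels = [UNSCORED] * n_signal
        drop_unscored = False
    else:
        labels = list(hyp.labels)
        if len(labels) != n_signal:
            log.warning(
                "hypnogram has %d labels but signal has %d full epochs; "
                "truncating to the shorter", len(labels), n_signal,
            )
        n_signal = min(n_signal, len(labels))
        labels = labels[:n_signal]

    blocks = rec.samples[: n_signal * per].reshape(n_signal, per)
    if drop_unscored:
        keep = [i for i, l in enumerate(labels) if l != UNSCORED]
        if not keep:
            raise DataError("all epochs are UNSCORED")
        labels = [labels[i] for i in keep]
        blocks = blocks[keep]
    return EpochGrid(stages=list(labels), blocks=blocks, rate=TARGET_RATE)
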