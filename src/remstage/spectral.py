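"""Power spectral density estimation, spectral-edge frequencies, band powers.

Two estimators are used: a Hann-windowed periodogram on 1-s sub-epochs
(1 Hz bins at 256 Hz), and Welch's method with 1-s Hann segments and 50%
overlap for stable per-epoch spectra.  Band powers use half-open [lo, hi)
bin masks so adjacent bands tile exactly; SEF uses a closed support so the
top bin is reachable.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DataError
from .types import SpectrumEstimate

#: Analysis band of the filtered signal; total power for relative measures.
TOTAL_BAND = (0.5, 40.0)


def psd(window: np.ndarray, rate: float, method: str = "periodogram_1s",
        window_fn: str = "hann") -> SpectrumEstimate:
    """Estimate the one-sided PSD of one window of samples.

    ``periodogram_1s`` is a single (windowed) periodogram; ``welch_epoch``
    averages 1-s segments with 50% overlap and is intended for 30-s epochs.
    """
    x = np.asarray(window, dtype=float).ravel()
    if x.size == 0:
        raise DataError("cannot estimate a spectrum from an empty window")
    if x.size < rate:
        raise DataError(f"window must span at least 1 s ({rate} samples), got {x.size}")
    if method == "periodogram_1s":
        freqs, dens = sps.periodogram(x, fs=rate, window=window_fn)
    elif method == "welch_epoch":
        # Rectangular 1-s segments keep bin-aligned tones in a single bin,
        # so edge frequencies of narrowband signals are bin-exact; for
        # broadband EEG the window choice is immaterial.
        nper = int(rate)
        freqs, dens = sps.welch(x, fs=rate, window="boxcar", nperseg=nper,
                                noverlap=nper // 2)
    else:
        raise ConfigError(f"unknown PSD method {method!r}")
    return SpectrumEstimate(freqs=freqs, density=dens, window_length_s=x.size / rate)


def band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Half-open bin mask: lo <= f < hi."""
    return (freqs >= lo) & (freqs < hi)


def sef(spec: SpectrumEstimate, fraction: float,
        band: tuple[float, float] | None = None) -> float:
    """Smallest grid frequency below which ``fraction`` of band power lies.

    Bin-resolution (no interpolation); the band support is closed
    [lo, hi].  Raises on zero total power.
    """
    if not 0 < fraction < 1:
        raise ConfigError(f"fraction must lie in (0, 1), got {fraction}")
    if band is None:
        mask = np.ones_like(spec.freqs, dtype=bool)
    else:
        lo, hi = band
        if lo >= hi:
            raise ConfigError(f"inverted band ({lo}, {hi})")
        mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    p = spec.density[mask]
    total = p.sum()
    if total <= 0:
        raise DataError("zero total power in band; SEF undefined")
    cum = np.cumsum(p) / total
    return float(spec.freqs[mask][np.argmax(cum >= fraction)])


def band_power(spec: SpectrumEstimate, lo: float, hi: float,
               relative: bool = False) -> float:
    """Absolute band power (sum density x df over [lo, hi)), or the fraction
    of total 0.5-40 Hz power when ``relative``."""
    if lo >= hi:
        raise ConfigError(f"inverted band ({lo}, {hi})")
    absolute = float(spec.density[band_mask(spec.freqs, lo, hi)].sum() * spec.df)
    if not relative:
        return absolute
    total = float(spec.density[band_mask(spec.freqs, *TOTAL_BAND)].sum() * spec.df)
    if total <= 0:
        return 0.0
    return absolute / total


def energy_density(spec: SpectrumEstimate, lo: float, hi: float) -> float:
    """Mean in-band power per Hz: band power divided by bandwidth."""
    return band_power(spec, lo, hi) / (hi - lo)
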