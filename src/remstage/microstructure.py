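"""Derivation of the phasic (FREM) and tonic (TREM) frequency bands.

REM sleep alternates between two micro-states with distinct spectra:
phasic periods carry increased delta/theta power, tonic periods increased
alpha/beta power.  Rather than classifying individual micro-states, two
frequency bands are derived globally from the distribution of per-REM-epoch
spectral edge frequencies:

* each REM epoch contributes a SEF50 (median frequency) and SEF95,
* the FREM band is bounded by the means of the SEF50 and SEF95 values in
  the lower quartile of their respective distributions (values <= the 25th
  percentile),
* the TREM band by the means of the values in the upper quartile
  (values >= the 75th percentile),

with bounds rounded to the nearest integer Hz.  On the reference dataset
this yields FREM = 2-8 Hz and TREM = 7-16 Hz, shipped as
:data:`remstage.types.DEFAULT_BANDS` for use when no REM labels exist.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np

from .errors import DataError
from .spectral import TOTAL_BAND, band_power, energy_density, psd, sef
from .types import BandPair, EpochGrid, SefSummary, SpectrumEstimate

log = logging.getLogger(__name__)


def sef_distribution(rem_epochs: EpochGrid) -> list[SefSummary]:
    """SEF50/SEF95 per REM epoch, from Welch spectra over 0.5-40 Hz."""
    grid = rem_epochs
    if any(s != "REM" for s in grid.stages):
        grid = grid.restrict("REM")
    if len(grid) == 0:
        raise DataError("no REM epochs to summarize")
    out = []
    for block in grid.blocks:
        spec = psd(block, grid.rate, method="welch_epoch")
        out.append(SefSummary(sef50=sef(spec, 0.5, TOTAL_BAND),
                              sef95=sef(spec, 0.95, TOTAL_BAND)))
    return out


def derive_bands(sefs: Sequence[SefSummary], lower_pct: float = 25.0,
                 upper_pct: float = 75.0, round_bounds: bool = True) -> BandPair:
    """Percentile-averaged FREM/TREM band bounds from SEF summaries.

    "Belonging to the Nth percentile" is read as <= (lower) / >= (upper) the
    percentile value, computed with the linear-interpolation convention.
    Requires at least 4 entries so the quartile subsets are non-empty.
    """
    if len(sefs) < 4:
        raise DataError(f"need at least 4 SEF summaries, got {len(sefs)}")
    s50 = np.array([s.sef50 for s in sefs], dtype=float)
    s95 = np.array([s.sef95 for s in sefs], dtype=float)

    def tail_mean(values: np.ndarray, pct: float, upper: bool) -> float:
        q = np.percentile(values, pct)
        subset = values[values >= q] if upper else values[values <= q]
        return float(subset.mean())

    frem = (tail_mean(s50, lower_pct, False), tail_mean(s95, lower_pct, False))
    trem = (tail_mean(s50, upper_pct, True), tail_mean(s95, upper_pct, True))
    if round_bounds:
        frem = (float(round(frem[0])), float(round(frem[1])))
        trem = (float(round(trem[0])), float(round(trem[1])))
    return BandPair(frem=frem, trem=trem)


def microstructure_features(
    spec: SpectrumEstimate, bands: BandPair, include_ratios: bool = False
) -> dict[str, float]:
    """Named REM-microstructure features of one spectrum.

    Absolute power, relative power and energy density in each derived band,
    plus the global SEF50/SEF95/SEFd over 0.5-40 Hz.  Degenerate (all-zero)
    spectra yield 0 for every feature with a logged warning.  Band-power
    ratio features exist behind ``include_ratios`` and are off by default.
    """
    out: dict[str, float] = {}
    for name, (lo, hi) in (("frem", bands.frem), ("trem", bands.trem)):
        out[f"{name}_abs_power"] = band_power(spec, lo, hi)
        out[f"{name}_rel_power"] = band_power(spec, lo, hi, relative=True)
        out[f"{name}_energy_density"] = energy_density(spec, lo, hi)
    try:
        s50 = sef(spec, 0.5, TOTAL_BAND)
        s95 = sef(spec, 0.95, TOTAL_BAND)
    except DataError:
        log.warning("zero-power spectrum: SEF features set to 0")
        s50 = s95 = 0.0
    out["sef50"] = s50
    out["sef95"] = s95
    out["sefd"] = s95 - s50
    if include_ratios:
        ft, tf = out["frem_rel_power"], out["trem_rel_power"]
        out["frem_trem_ratio"] = ft / tf if tf > 0 else 0.0
        out["trem_frem_ratio"] = tf / ft if ft > 0 else 0.0
    return out
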