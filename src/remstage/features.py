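"""The 164-feature extractor with sub-epoch averaging, scaling, selection.

Features fall in four categories.  Time features are computed once per
30-s epoch; frequency, time-frequency and non-linear features are computed
in each 1-s sub-epoch and averaged across the 30 sub-epochs (short windows
give approximate wide-sense stationarity and a 1 Hz spectral resolution).

The registry enumerates exactly 164 named features:

========================  =====
time                         24
frequency                    30
time-frequency              104
non-linear                    6
========================  =====

* time: 7 moment/order statistics, 6 Hjorth parameters (signal and first
  difference), zero-crossing rate, 5 percentile features, 3 envelope
  features, 2 coastlines;
* frequency: absolute + relative power in 6 clinical bands, SEF50/SEF95/
  SEFd, 6 FREM/TREM microstructure features, spectral + approximate
  entropy, 7 FFT-magnitude statistics;
* time-frequency: 8 STFT statistics and 8 statistics per sub-band of two
  5-level wavelet decompositions (Daubechies-4 and Haar, 6 sub-bands each);
* non-linear: 6 Teager-Kaiser energy operator statistics.

The registry is mirrored in ``data/feature_manifest.yaml`` so the
composition is auditable; a test asserts the two agree.

Degenerate inputs (flat sub-epochs, zero spectra) produce 0 for ratio-type
features with a logged warning, never NaN.  Min-max scaling maps each
fitted column onto [-1, 1] (constant columns to 0) and the variance filter
keeps scaled columns with variance >= 0.2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats as sstats

from .errors import ConfigError, DataError
from .spectral import TOTAL_BAND, band_mask
from .types import (
    DEFAULT_BANDS,
    SUBEPOCHS_PER_EPOCH,
    TARGET_RATE,
    BandPair,
    EpochGrid,
)

log = logging.getLogger(__name__)

#: Clinical EEG bands (Hz); alpha/sigma overlap at 12-13 Hz by convention.
CLINICAL_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
    "gamma": (30.0, 40.0),
}

_STAT_NAMES = ("mean", "std", "skewness", "kurtosis", "range", "max", "min")
_DWT_WAVELETS = ("db4", "haar")
_DWT_LEVELS = 5
_DWT_SUBBANDS = ("a5", "d5", "d4", "d3", "d2", "d1")
_DWT_STATS = ("energy", "rel_energy", "mean", "std", "skewness", "kurtosis",
              "max", "min")

#: The six novel REM-microstructure power/energy features (ablation set).
MICROSTRUCTURE_POWER_FEATURES = (
    "frem_abs_power", "frem_rel_power", "frem_energy_density",
    "trem_abs_power", "trem_rel_power", "trem_energy_density",
)


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class FeatureSpec:
    """One registry entry.

    ``window`` is "epoch" for whole-epoch features or "subepoch_mean" for
    1-s features averaged over the epoch.  ``equivariance`` tags how the
    feature responds to amplitude scaling by c > 0: "invariant", "linear"
    (x c) or "quadratic" (x c^2); used by property tests.
    """

    name: str
    category: str  # time | frequency | time_frequency | nonlinear
    window: str
    equivariance: str


def _build_registry() -> tuple[FeatureSpec, ...]:
    specs: list[FeatureSpec] = []

    def add(name, category, equivariance, window=None):
        if window is None:
            window = "epoch" if category == "time" else "subepoch_mean"
        specs.append(FeatureSpec(name, category, window, equivariance))

    stat_eq = {"mean": "linear", "std": "linear", "skewness": "invariant",
               "kurtosis": "invariant", "range": "linear", "max": "linear",
               "min": "linear"}

    # --- time ---
    for s in _STAT_NAMES:
        add(f"time_{s}", "time", stat_eq[s])
    for src in ("", "d1_"):
        add(f"hjorth_{src}activity", "time", "quadratic")
        add(f"hjorth_{src}mobility", "time", "invariant")
        add(f"hjorth_{src}complexity", "time", "invariant")
    add("zcr", "time", "invariant")
    for p in ("25", "75", "95"):
        add(f"pct{p}", "time", "linear")
    add("pct75_25", "time", "linear")
    add("pct95_25", "time", "linear")
    add("env_peak_count", "time", "invariant")
    add("env_peak_prominence", "time", "linear")
    add("env_peak_width", "time", "invariant")
    add("coastline_d1", "time", "linear")
    add("coastline_d2", "time", "linear")

    # --- frequency ---
    for b in CLINICAL_BANDS:
        add(f"bp_abs_{b}", "frequency", "quadratic")
    for b in CLINICAL_BANDS:
        add(f"bp_rel_{b}", "frequency", "invariant")
    add("sef50", "frequency", "invariant")
    add("sef95", "frequency", "invariant")
    add("sefd", "frequency", "invariant")
    for band in ("frem", "trem"):
        add(f"{band}_abs_power", "frequency", "quadratic")
        add(f"{band}_rel_power", "frequency", "invariant")
        add(f"{band}_energy_density", "frequency", "quadratic")
    add("spectral_entropy", "frequency", "invariant")
    add("approx_entropy", "frequency", "invariant")
    for s in _STAT_NAMES:
        add(f"fft_{s}", "frequency", stat_eq[s])

    # --- time-frequency ---
    for s in _STAT_NAMES:
        add(f"stft_mag_{s}", "time_frequency", stat_eq[s])
    add("stft_density_max", "time_frequency", "quadratic")
    dwt_eq = {"energy": "quadratic", "rel_energy": "invariant", "mean": "linear",
              "std": "linear", "skewness": "invariant", "kurtosis": "invariant",
              "max": "linear", "min": "linear"}
    for wav in _DWT_WAVELETS:
        for sb in _DWT_SUBBANDS:
            for s in _DWT_STATS:
                add(f"dwt_{wav}_{sb}_{s}", "time_frequency", dwt_eq[s])

    # --- non-linear ---
    for s in ("mean", "std", "skewness", "kurtosis", "max", "min"):
        eq = "invariant" if s in ("skewness", "kurtosis") else "quadratic"
        add(f"tkeo_{s}", "nonlinear", eq)

    names = [s.name for s in specs]
    assert len(names) == len(set(names)), "duplicate feature names"
    return tuple(specs)


REGISTRY: tuple[FeatureSpec, ...] = _build_registry()
FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in REGISTRY)


def registry_manifest() -> list[dict]:
    return [
        {"name": s.name, "category": s.category, "window": s.window,
         "equivariance": s.equivariance}
        for s in REGISTRY
    ]


# ---------------------------------------------------------------------------
# per-family computations


def _safe_stats(values: np.ndarray, axis: int | None = None) -> dict[str, np.ndarray]:
    """mean/std/skewness/kurtosis/range/max/min with 0 for undefined moments."""
    v = np.asarray(values, dtype=float)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # near-constant windows trigger scipy's precision warning; the
        # resulting NaNs are mapped to 0 by the degenerate-input rule
        warnings.simplefilter("ignore", RuntimeWarning)
        out = {
            "mean": v.mean(axis=axis),
            "std": v.std(axis=axis),
            "skewness": sstats.skew(v, axis=axis),
            "kurtosis": sstats.kurtosis(v, axis=axis),
            "range": v.max(axis=axis) - v.min(axis=axis),
            "max": v.max(axis=axis),
            "min": v.min(axis=axis),
        }
    return {k: np.nan_to_num(np.asarray(a, dtype=float), nan=0.0)
            for k, a in out.items()}


def hjorth_parameters(x: np.ndarray) -> tuple[float, float, float]:
    """Activity (variance), mobility and complexity of one signal.

    Mobility is computed on the plain first difference, so a pure sinusoid
    of angular frequency w rad/sample has mobility 2*sin(w/2).
    """
    x = np.asarray(x, dtype=float)
    v0 = x.var()
    if v0 == 0:
        return 0.0, 0.0, 0.0
    d1 = np.diff(x)
    v1 = d1.var()
    mobility = np.sqrt(v1 / v0)
    if v1 == 0:
        return float(v0), float(mobility), 0.0
    v2 = np.diff(d1).var()
    complexity = np.sqrt(v2 / v1) / mobility
    return float(v0), float(mobility), float(complexity)


def zero_crossing_rate(x: np.ndarray, rate: float) -> float:
    """Strict sign-change count divided by duration (crossings per second)."""
    x = np.asarray(x, dtype=float)
    s = np.sign(x)
    s = s[s != 0]  # skip exact zeros so a zero signal has no crossings
    crossings = int(np.sum(s[1:] != s[:-1])) if s.size > 1 else 0
    return crossings / (x.size / rate)


def teager_kaiser(x: np.ndarray) -> np.ndarray:
    """Discrete Teager-Kaiser energy: psi[n] = x[n]^2 - x[n-1]*x[n+1]."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DataError("TKEO needs at least 3 samples")
    return x[1:-1] ** 2 - x[:-2] * x[2:]


def approximate_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Approximate entropy with embedding m and tolerance r = r_factor * sd.

    Template distances are Chebyshev; the m- and (m+1)-length distance
    matrices are built incrementally from the pairwise sample distances.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_factor * sd

    d1 = np.abs(x[:, None] - x[None, :])
    dm = d1
    for k in range(1, m):
        dm = np.maximum(dm[:-1, :-1], d1[k:, k:])
    dm1 = np.maximum(dm[:-1, :-1], d1[m:, m:])

    def phi(d: np.ndarray) -> float:
        c = np.count_nonzero(d <= r, axis=1) / d.shape[0]
        return float(np.mean(np.log(c)))

    return phi(dm) - phi(dm1)


def spectral_entropy(density: np.ndarray) -> float:
    """Shannon entropy (nats) of the bin-normalized density."""
    total = density.sum()
    if total <= 0:
        return 0.0
    p = density / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _time_features(x: np.ndarray, rate: float) -> dict[str, float]:
    out = {f"time_{k}": float(v) for k, v in _safe_stats(x).items()}

    a, m, c = hjorth_parameters(x)
    out.update(hjorth_activity=a, hjorth_mobility=m, hjorth_complexity=c)
    a, m, c = hjorth_parameters(np.diff(x))
    out.update(hjorth_d1_activity=a, hjorth_d1_mobility=m, hjorth_d1_complexity=c)

    out["zcr"] = zero_crossing_rate(x, rate)

    p25, p75, p95 = np.percentile(x, [25, 75, 95])
    out.update(pct25=float(p25), pct75=float(p75), pct95=float(p95),
               pct75_25=float(p75 - p25), pct95_25=float(p95 - p25))

    env = np.abs(sps.hilbert(x))
    peaks, _ = sps.find_peaks(env)
    out["env_peak_count"] = float(peaks.size)
    if peaks.size:
        out["env_peak_prominence"] = float(sps.peak_prominences(env, peaks)[0].mean())
        out["env_peak_width"] = float(sps.peak_widths(env, peaks)[0].mean())
    else:
        out["env_peak_prominence"] = 0.0
        out["env_peak_width"] = 0.0

    d1 = np.diff(x)
    out["coastline_d1"] = float(np.abs(d1).sum())
    out["coastline_d2"] = float(np.abs(np.diff(d1)).sum())
    return out


def _subepoch_sef(freqs: np.ndarray, dens: np.ndarray, fraction: float) -> np.ndarray:
    """Vectorized bin-resolution SEF per sub-epoch row over 0.5-40 Hz."""
    mask = (freqs >= TOTAL_BAND[0]) & (freqs <= TOTAL_BAND[1])
    f = freqs[mask]
    p = dens[:, mask]
    totals = p.sum(axis=1)
    ok = totals > 0
    out = np.zeros(dens.shape[0])
    if ok.any():
        cum = np.cumsum(p[ok], axis=1) / totals[ok, None]
        out[ok] = f[np.argmax(cum >= fraction, axis=1)]
    return out


def _freq_features(sub: np.ndarray, freqs: np.ndarray, dens: np.ndarray,
                   rate: float, bands: BandPair) -> dict[str, float]:
    df = freqs[1] - freqs[0]
    total = dens[:, band_mask(freqs, *TOTAL_BAND)].sum(axis=1) * df
    ok = total > 0
    out: dict[str, float] = {}

    def rel_mean(absolute: np.ndarray) -> float:
        r = np.zeros_like(absolute)
        r[ok] = absolute[ok] / total[ok]
        return float(r.mean())

    for name, (lo, hi) in CLINICAL_BANDS.items():
        absolute = dens[:, band_mask(freqs, lo, hi)].sum(axis=1) * df
        out[f"bp_abs_{name}"] = float(absolute.mean())
        out[f"bp_rel_{name}"] = rel_mean(absolute)

    s50 = _subepoch_sef(freqs, dens, 0.5)
    s95 = _subepoch_sef(freqs, dens, 0.95)
    out["sef50"] = float(s50.mean())
    out["sef95"] = float(s95.mean())
    out["sefd"] = float((s95 - s50).mean())

    for name, (lo, hi) in (("frem", bands.frem), ("trem", bands.trem)):
        absolute = dens[:, band_mask(freqs, lo, hi)].sum(axis=1) * df
        out[f"{name}_abs_power"] = float(absolute.mean())
        out[f"{name}_rel_power"] = rel_mean(absolute)
        out[f"{name}_energy_density"] = float(absolute.mean()) / (hi - lo)

    in_band = dens[:, band_mask(freqs, *TOTAL_BAND)]
    out["spectral_entropy"] = float(np.mean([spectral_entropy(row) for row in in_band]))
    out["approx_entropy"] = float(np.mean([approximate_entropy(row) for row in sub]))

    mag = np.abs(np.fft.rfft(sub, axis=1))
    fmask = (freqs >= TOTAL_BAND[0]) & (freqs <= TOTAL_BAND[1])
    stats = _safe_stats(mag[:, fmask], axis=1)
    for k in _STAT_NAMES:
        out[f"fft_{k}"] = float(stats[k].mean())
    return out


def _tf_features(sub: np.ndarray, rate: float) -> dict[str, float]:
    out: dict[str, float] = {}

    nper = int(rate) // 4  # 0.25-s frames inside each 1-s sub-epoch
    f, _, Z = sps.stft(sub, fs=rate, nperseg=nper, noverlap=nper // 2, axis=-1)
    mask = f <= 40.0
    mag = np.abs(Z[:, mask, :])
    stats = _safe_stats(mag.reshape(mag.shape[0], -1), axis=1)
    for k in _STAT_NAMES:
        out[f"stft_mag_{k}"] = float(stats[k].mean())
    fs_, _, Sxx = sps.spectrogram(sub, fs=rate, nperseg=nper, noverlap=nper // 2,
                                  axis=-1, scaling="density")
    out["stft_density_max"] = float(Sxx[:, fs_ <= 40.0, :].max(axis=(1, 2)).mean())

    for wav in _DWT_WAVELETS:
        coeffs = pywt.wavedec(sub, wav, mode="periodization", level=_DWT_LEVELS,
                              axis=-1)
        energies = np.stack([ (c ** 2).sum(axis=1) for c in coeffs ])  # (6, n_sub)
        total = energies.sum(axis=0)
        ok = total > 0
        for sb, c, e in zip(_DWT_SUBBANDS, coeffs, energies):
            rel = np.zeros_like(e)
            rel[ok] = e[ok] / total[ok]
            stats = _safe_stats(c, axis=1)
            out[f"dwt_{wav}_{sb}_energy"] = float(e.mean())
            out[f"dwt_{wav}_{sb}_rel_energy"] = float(rel.mean())
            for k in ("mean", "std", "skewness", "kurtosis", "max", "min"):
                out[f"dwt_{wav}_{sb}_{k}"] = float(stats[k].mean())
    return out


def _nl_features(sub: np.ndarray) -> dict[str, float]:
    psi = sub[:, 1:-1] ** 2 - sub[:, :-2] * sub[:, 2:]
    stats = _safe_stats(psi, axis=1)
    return {f"tkeo_{k}": float(stats[k].mean())
            for k in ("mean", "std", "skewness", "kurtosis", "max", "min")}


# ---------------------------------------------------------------------------
# epoch / matrix extraction


def extract_epoch(block: np.ndarray, rate: int = TARGET_RATE,
                  bands: BandPair = DEFAULT_BANDS) -> dict[str, float]:
    """All 164 registry features of one 30-s block, in registry order."""
    x = np.asarray(block, dtype=float).ravel()
    if x.size != rate * SUBEPOCHS_PER_EPOCH:
        raise DataError(
            f"epoch block must have {rate * SUBEPOCHS_PER_EPOCH} samples, got {x.size}"
        )
    sub = x.reshape(SUBEPOCHS_PER_EPOCH, rate)
    freqs, dens = sps.periodogram(sub, fs=rate, window="hann", axis=-1)

    vals: dict[str, float] = {}
    vals.update(_time_features(x, rate))
    vals.update(_freq_features(sub, freqs, dens, rate, bands))
    vals.update(_tf_features(sub, rate))
    vals.update(_nl_features(sub))

    bad = [k for k, v in vals.items() if not np.isfinite(v)]
    if bad:
        log.warning("degenerate input: %d features set to 0 (%s...)", len(bad), bad[:3])
        for k in bad:
            vals[k] = 0.0
    ordered = {name: vals[name] for name in FEATURE_NAMES}
    assert len(ordered) == len(REGISTRY)
    return ordered


@dataclass
class FeatureMatrix:
    """Epochs x named features with the stage label per row."""

    features: pd.DataFrame
    stages: pd.Series

    def __post_init__(self) -> None:
        self.stages = pd.Series(list(self.stages), index=self.features.index,
                                name="stage")

    def __len__(self) -> int:
        return len(self.features)

    def to_csv(self, path: str | Path) -> Path:
        df = self.features.copy()
        df["stage"] = self.stages.values
        df.to_csv(path, index=False)
        return Path(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, comment="#")
        if "stage" not in df.columns:
            raise DataError(f"feature CSV {path} lacks a 'stage' column")
        return cls(features=df.drop(columns=["stage"]), stages=df["stage"])


def extract_matrix(grid: EpochGrid, bands: BandPair = DEFAULT_BANDS) -> FeatureMatrix:
    rows = [extract_epoch(b, grid.rate, bands) for b in grid.blocks]
    return FeatureMatrix(features=pd.DataFrame(rows), stages=pd.Series(grid.stages))


# ---------------------------------------------------------------------------
# scaling and selection


@dataclass
class ScalerParams:
    """Per-column (min, max) fitted on training rows only."""

    mins: pd.Series
    maxs: pd.Series


def fit_scaler(features: pd.DataFrame) -> ScalerParams:
    return ScalerParams(mins=features.min(axis=0), maxs=features.max(axis=0))


def apply_scaler(features: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """Min-max map onto [-1, 1]: fitted min -> -1, max -> +1, constant
    columns -> 0.  Unseen values are not clipped."""
    if not features.columns.equals(params.mins.index):
        raise ConfigError("scaler params were fitted on different columns")
    span = params.maxs - params.mins
    const = span == 0
    span = span.where(~const, 1.0)
    scaled = 2.0 * (features - params.mins) / span - 1.0
    scaled.loc[:, const] = 0.0
    return scaled


def variance_select(scaled: pd.DataFrame, threshold: float = 0.2
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Keep columns of the scaled matrix with population variance >= threshold."""
    if threshold < 0:
        raise ConfigError(f"variance threshold must be >= 0, got {threshold}")
    variances = scaled.var(axis=0, ddof=0)
    kept = [c for c in scaled.columns if variances[c] >= threshold]
    return scaled[kept], kept
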