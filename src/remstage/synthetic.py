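"""Seeded generator of stage-labelled EEG with controllable spectra.

The signal model is band-shaped Gaussian noise: each 30-s epoch is drawn
in the frequency domain with a power density matching the stage profile's
relative band powers, inverse-transformed, scaled to the profile's RMS
amplitude, and optionally decorated with oscillatory transients (sleep
spindle bursts for N2, slow sawtooth bursts for phasic REM).  REM epochs
are drawn from a phasic-like (delta/theta-weighted) or tonic-like
(alpha/sigma-weighted) profile, so the per-epoch SEF distribution is
bimodal and the phasic/tonic band derivation is exercised end to end.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
spawning, so every output is reproducible from the configuration alone.
This generator emulates stage-specific spectra and cyclic hypnograms only;
it makes no attempt at physiologically realistic waveform morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from . import io as rio
from .types import (
    EPOCH_SAMPLES,
    STAGES,
    TARGET_RATE,
    EpochGrid,
    Hypnogram,
    SignalRecord,
)

#: Non-overlapping synthesis bands (Hz).
SYNTH_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
    "gamma": (30.0, 40.0),
}


@dataclass(frozen=True)
class Transient:
    """Oscillatory burst added on top of the noise background."""

    kind: str            # "spindle" (sinusoid) or "sawtooth"
    freq_hz: float
    duration_s: float
    per_epoch: int = 2
    amplitude_factor: float = 1.25  # relative to the epoch RMS


@dataclass(frozen=True)
class StageProfile:
    """Relative band-power targets plus RMS amplitude for one stage."""

    band_rel: dict[str, float]
    amplitude_uv: float
    transient: Transient | None = None

    def __post_init__(self) -> None:
        if set(self.band_rel) != set(SYNTH_BANDS):
            raise ConfigError(f"profile must define bands {sorted(SYNTH_BANDS)}")
        vals = np.array(list(self.band_rel.values()))
        if np.any(vals < 0) or not np.isclose(vals.sum(), 1.0, atol=1e-6):
            raise ConfigError("relative band powers must be >= 0 and sum to 1")
        if self.amplitude_uv < 0:
            raise ConfigError("amplitude must be >= 0")


DEFAULT_PROFILES: dict[str, StageProfile] = {
    "AWA": StageProfile(
        {"delta": .15, "theta": .10, "alpha": .40, "sigma": .10, "beta": .20,
         "gamma": .05}, amplitude_uv=30.0),
    "N1": StageProfile(
        {"delta": .25, "theta": .40, "alpha": .15, "sigma": .08, "beta": .09,
         "gamma": .03}, amplitude_uv=40.0),
    "N2": StageProfile(
        {"delta": .30, "theta": .28, "alpha": .10, "sigma": .22, "beta": .08,
         "gamma": .02}, amplitude_uv=55.0,
        transient=Transient("spindle", freq_hz=13.0, duration_s=1.0)),
    "N3": StageProfile(
        {"delta": .65, "theta": .20, "alpha": .06, "sigma": .04, "beta": .04,
         "gamma": .01}, amplitude_uv=80.0),
    # REM micro-states: phasic skewed to delta/theta, tonic to alpha/sigma.
    "REM_PHASIC": StageProfile(
        {"delta": .32, "theta": .49, "alpha": .10, "sigma": .05, "beta": .03,
         "gamma": .01}, amplitude_uv=35.0,
        transient=Transient("sawtooth", freq_hz=3.0, duration_s=2.0)),
    "REM_TONIC": StageProfile(
        {"delta": .08, "theta": .14, "alpha": .40, "sigma": .28, "beta": .08,
         "gamma": .02}, amplitude_uv=30.0),
}

#: One sleep cycle on the epoch grid: stage -> (min, max) epochs per visit.
CYCLE = (
    ("AWA", (2, 5)), ("N1", (2, 5)), ("N2", (6, 12)), ("N3", (6, 12)),
    ("N2", (4, 8)), ("REM", (5, 12)),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic recording."""

    seed: int
    n_epochs: int = 120
    frem_fraction: float = 0.5     # probability a REM epoch is phasic-like
    noise_floor: float = 0.02      # broadband power fraction outside the profile
    channel_label: str = "C3-A2"
    profiles: dict[str, StageProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES))

    def __post_init__(self) -> None:
        if not 0 <= self.frem_fraction <= 1:
            raise ConfigError("frem_fraction must lie in [0, 1]")
        if self.n_epochs < 1:
            raise ConfigError("need at least one epoch")


def _shaped_noise(density_fn, rng: np.random.Generator, n: int = EPOCH_SAMPLES,
                  fs: float = TARGET_RATE) -> np.ndarray:
    """Gaussian noise with one-sided spectral shape ``density_fn(freqs)``."""
    nf = n // 2 + 1
    freqs = np.arange(nf) * fs / n
    amp = np.sqrt(np.maximum(density_fn(freqs), 0.0))
    spec = amp * (rng.standard_normal(nf) + 1j * rng.standard_normal(nf))
    spec[0] = 0.0
    return np.fft.irfft(spec, n)


def _profile_density(profile: StageProfile, noise_floor: float):
    def density(freqs: np.ndarray) -> np.ndarray:
        d = np.zeros_like(freqs)
        for name, (lo, hi) in SYNTH_BANDS.items():
            d[(freqs >= lo) & (freqs < hi)] += profile.band_rel[name] / (hi - lo)
        d *= 1.0 - noise_floor
        d += noise_floor / (TARGET_RATE / 2)
        return d
    return density


def _add_transients(x: np.ndarray, tr: Transient, amplitude_uv: float,
                    rng: np.random.Generator, fs: float = TARGET_RATE) -> None:
    n_burst = int(tr.duration_s * fs)
    t = np.arange(n_burst) / fs
    envelope = np.hanning(n_burst)
    if tr.kind == "spindle":
        burst = np.sin(2 * np.pi * tr.freq_hz * t)
    elif tr.kind == "sawtooth":
        burst = sps.sawtooth(2 * np.pi * tr.freq_hz * t)
    else:
        raise ConfigError(f"unknown transient kind {tr.kind!r}")
    burst = tr.amplitude_factor * amplitude_uv * envelope * burst
    for start in rng.integers(0, x.size - n_burst, size=tr.per_epoch):
        x[start:start + n_burst] += burst


def generate_epoch(profile: StageProfile, seed, noise_floor: float = 0.02
                   ) -> np.ndarray:
    """One 30-s block at 256 Hz whose expected relative band powers match
    the profile; ``seed`` may be an int or a Generator."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if profile.amplitude_uv == 0:
        return np.zeros(EPOCH_SAMPLES)
    x = _shaped_noise(_profile_density(profile, noise_floor), rng)
    x *= profile.amplitude_uv / np.sqrt(np.mean(x ** 2))
    if profile.transient is not None:
        _add_transients(x, profile.transient, profile.amplitude_uv, rng)
    return x


def _rem_profile(cfg: SyntheticConfig, rng: np.random.Generator) -> StageProfile:
    phasic = rng.random() < cfg.frem_fraction
    return cfg.profiles["REM_PHASIC" if phasic else "REM_TONIC"]


def cyclic_hypnogram(n_epochs: int, rng: np.random.Generator) -> Hypnogram:
    """Repeating AWA -> N1 -> N2 -> N3 -> N2 -> REM cycle, seeded durations."""
    labels: list[str] = []
    while len(labels) < n_epochs:
        for stage, (lo, hi) in CYCLE:
            labels.extend([stage] * int(rng.integers(lo, hi + 1)))
    return Hypnogram(tuple(labels[:n_epochs]))


def generate_recording(cfg: SyntheticConfig) -> tuple[SignalRecord, Hypnogram]:
    """A continuous synthetic recording plus its hypnogram."""
    root = np.random.SeedSequence(cfg.seed)
    hyp_rng = np.random.default_rng(root.spawn(1)[0])
    hyp = cyclic_hypnogram(cfg.n_epochs, hyp_rng)
    blocks = _labelled_blocks(list(hyp.labels), cfg, root)
    return (
        SignalRecord(samples=np.concatenate(blocks), rate=float(TARGET_RATE),
                     channel_label=cfg.channel_label),
        hyp,
    )


def _labelled_blocks(labels: list[str], cfg: SyntheticConfig,
                     root: np.random.SeedSequence) -> list[np.ndarray]:
    children = root.spawn(len(labels) + 1)[1:]
    blocks = []
    for label, child in zip(labels, children):
        rng = np.random.default_rng(child)
        profile = _rem_profile(cfg, rng) if label == "REM" else cfg.profiles[label]
        blocks.append(generate_epoch(profile, rng, cfg.noise_floor))
    return blocks


def generate_stage_epochs(epochs_per_stage: int, seed: int,
                          frem_fraction: float = 0.5,
                          noise_floor: float = 0.02) -> EpochGrid:
    """Balanced stage-labelled epochs (no temporal structure); the standard
    substrate for classifier experiments."""
    if epochs_per_stage < 1:
        raise ConfigError("need at least one epoch per stage")
    cfg = SyntheticConfig(seed=seed, frem_fraction=frem_fraction,
                          noise_floor=noise_floor)
    labels = [s for s in STAGES for _ in range(epochs_per_stage)]
    blocks = _labelled_blocks(labels, cfg, np.random.SeedSequence(seed))
    return EpochGrid(stages=labels, blocks=np.vstack(blocks))


def simulate_to_files(cfg: SyntheticConfig, out_dir: str | Path
                      ) -> tuple[Path, Path]:
    """Write the recording as EDF plus a simple-dialect hypnogram CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec, hyp = generate_recording(cfg)
    edf = rio.write_edf(rec, out / "recording.edf")
    csv = rio.write_hypnogram(hyp, out / "hypnogram.csv")
    return edf, csv


# ---------------------------------------------------------------------------
# band-ratio-only binary substrate (ablation experiments)


def make_band_ratio_dataset(n_per_class: int, seed: int,
                            low_fraction: tuple[float, float] = (0.20, 0.45),
                            noise_floor: float = 0.08) -> EpochGrid:
    """REM vs N2 epochs separable (mainly) through tonic-band-ratio cues.

    Every epoch carries a narrow 1-Hz-wide component plus broadband power
    spread over 4-30 Hz with a random per-epoch spectral tilt.  REM epochs
    place the component at 7-8 Hz -- inside the reference tonic band
    (7-16 Hz) -- N2 epochs at 5-6 Hz, outside it.  Both placements lie
    entirely inside the clinical theta band (4-8 Hz), inside the phasic
    band (2-8 Hz) and inside the same 4-8 Hz wavelet detail sub-band, and
    have equal bandwidth; the random tilt adds spectral-centroid noise
    larger than the 2 Hz placement shift.  Clinical band powers, sub-band
    energies, entropies and SEF summaries therefore separate the classes
    poorly, while the TREM band powers see the shift directly.  The
    component's power fraction is drawn per epoch from ``low_fraction`` so
    the class distributions overlap and no feature separates perfectly;
    per-epoch gain jitter removes amplitude information.
    """
    if n_per_class < 1:
        raise ConfigError("need at least one epoch per class")
    root = np.random.SeedSequence(seed)
    spread = (4.0, 30.0)
    labels, blocks = [], []
    for label, child in zip(
        ["REM"] * n_per_class + ["N2"] * n_per_class,
        root.spawn(2 * n_per_class),
    ):
        rng = np.random.default_rng(child)
        lo, hi = (7.0, 8.0) if label == "REM" else (5.0, 6.0)
        tilt = rng.uniform(-0.5, 0.5)
        lf = rng.uniform(*low_fraction)
        # class-independent slow-wave distractor: adds delta/low-frequency
        # variance to both classes so approximation-sub-band and delta
        # features stay uninformative
        slow_frac = rng.uniform(0.0, 0.25)

        def density(freqs, lo=lo, hi=hi, tilt=tilt, low_fraction=lf,
                    slow_frac=slow_frac):
            d = np.where((freqs >= lo) & (freqs < hi),
                         low_fraction / (hi - lo), 0.0)
            d = d + np.where((freqs >= 0.8) & (freqs < 3.8),
                             slow_frac / 3.0, 0.0)
            mid = 0.5 * (spread[0] + spread[1])
            half = 0.5 * (spread[1] - spread[0])
            shape = np.clip(1.0 + tilt * (freqs - mid) / half, 0.0, None)
            in_spread = (freqs >= spread[0]) & (freqs < spread[1])
            d = d + np.where(in_spread,
                             (1 - low_fraction - slow_frac) * shape
                             / (spread[1] - spread[0]),
                             0.0)
            return (1 - noise_floor) * d + noise_floor / (TARGET_RATE / 2)

        x = _shaped_noise(density, rng)
        amp = 30.0 * rng.uniform(0.7, 1.4)
        x *= amp / np.sqrt(np.mean(x ** 2))
        labels.append(label)
        blocks.append(x)
    return EpochGrid(stages=labels, blocks=np.vstack(blocks))
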