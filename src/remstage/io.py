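"""EDF signal and hypnogram file input/output.

EDF/EDF+ reading goes through :mod:`mne`; writing uses a minimal EDF
writer (16-bit, one-second data records) sufficient for single-channel
recordings produced by this package.  Hypnograms are plain text files,
one stage token per line, interpreted through per-dialect mapping tables
(see ``data/dialects.yaml``).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ChannelNotFoundError, ConfigError, DataError, DialectError
from .types import EPOCH_LENGTH_S, UNSCORED, Hypnogram, SignalRecord

log = logging.getLogger(__name__)

#: Channel fallback order used when no explicit channel is requested.
DEFAULT_CHANNEL_ORDER = ("C3-A2", "C4-A1")

_DIG_MIN, _DIG_MAX = -32768, 32767


# ---------------------------------------------------------------------------
# dialects


def _load_dialects(path: str | Path | None = None) -> dict:
    if path is None:
        text = (resources.files("remstage") / "data" / "dialects.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


_DIALECTS = _load_dialects()


def available_dialects() -> tuple[str, ...]:
    return tuple(_DIALECTS)


def _dialect(name: str) -> dict:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise ConfigError(
            f"unknown hypnogram dialect {name!r}; available: {sorted(_DIALECTS)}"
        ) from None


# ---------------------------------------------------------------------------
# hypnograms


def _majority(window: list[str]) -> str:
    """Majority label of a sub-30-s window; ties are conservatively UNSCORED."""
    counts = Counter(window).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return UNSCORED
    return counts[0][0]


def read_hypnogram(path: str | Path, dialect: str = "simple") -> Hypnogram:
    """Read a hypnogram text file, one stage token per line.

    Tokens are mapped through the dialect table; native epochs shorter than
    30 s are aggregated by majority vote (ties -> UNSCORED, trailing partial
    windows dropped).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"hypnogram file not found: {path}")
    table = _dialect(dialect)
    mapping = {str(k): v for k, v in table["mapping"].items()}
    native_len = int(table["epoch_length_s"])

    labels: list[str] = []
    for raw in path.read_text().splitlines():
        token = raw.strip().strip(",")
        if not token or token.startswith("#"):
            continue
        if token not in mapping:
            raise DialectError(
                f"token {token!r} not covered by dialect {dialect!r} "
                f"(known tokens: {sorted(mapping)})"
            )
        labels.append(mapping[token])

    if not labels:
        raise DataError(f"no stage tokens found in {path}")

    if native_len < EPOCH_LENGTH_S:
        if EPOCH_LENGTH_S % native_len:
            raise ConfigError(
                f"native epoch length {native_len}s does not divide {EPOCH_LENGTH_S}s"
            )
        per = EPOCH_LENGTH_S // native_len
        n_full = len(labels) // per
        if len(labels) % per:
            log.warning(
                "dropping trailing partial scoring window (%d of %d labels)",
                len(labels) % per, per,
            )
        labels = [_majority(labels[i * per:(i + 1) * per]) for i in range(n_full)]
        if not labels:
            raise DataError("hypnogram shorter than one 30-s epoch after aggregation")
    elif native_len != EPOCH_LENGTH_S:
        raise ConfigError(f"native epoch length {native_len}s > {EPOCH_LENGTH_S}s unsupported")

    return Hypnogram(tuple(labels))


def write_hypnogram(hyp: Hypnogram, path: str | Path, dialect: str = "simple") -> Path:
    """Write one token per line using the dialect's write table."""
    table = _dialect(dialect)
    if int(table["epoch_length_s"]) != EPOCH_LENGTH_S:
        raise ConfigError(f"dialect {dialect!r} cannot represent 30-s epochs directly")
    write_map = table["write"]
    path = Path(path)
    path.write_text("".join(f"{write_map[l]}\n" for l in hyp.labels))
    return path


# ---------------------------------------------------------------------------
# EDF reading (mne)


def read_edf_channel(
    path: str | Path, channel: str | int | None = None
) -> SignalRecord:
    """Read one channel of an EDF/EDF+ file at its native rate, in microvolts.

    ``channel`` may be a label, a zero-based index, or None, in which case
    the conventional fallback order (C3-A2, then C4-A1) is tried.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"EDF file not found: {path}")
    import mne  # deferred: slow import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        except Exception as exc:  # corrupt header etc.
            raise DataError(f"could not read EDF file {path}: {exc}") from exc

    names = list(raw.ch_names)
    if channel is None:
        for cand in DEFAULT_CHANNEL_ORDER:
            if cand in names:
                channel = cand
                break
        else:
            raise ChannelNotFoundError(
                f"none of the default channels {DEFAULT_CHANNEL_ORDER} present; "
                f"available channels: {names}"
            )
    if isinstance(channel, int):
        if not 0 <= channel < len(names):
            raise ChannelNotFoundError(
                f"channel index {channel} out of range; available channels: {names}"
            )
        label = names[channel]
    else:
        if channel not in names:
            raise ChannelNotFoundError(
                f"channel {channel!r} not found; available channels: {names}"
            )
        label = channel

    data = raw.get_data(picks=[label], units="uV")[0]
    meas_date = raw.info.get("meas_date")
    start = meas_date.replace(tzinfo=None) if meas_date is not None else None
    return SignalRecord(
        samples=data, rate=float(raw.info["sfreq"]), channel_label=label,
        start_time=start,
    )


# ---------------------------------------------------------------------------
# EDF writing (minimal)


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ConfigError(f"EDF header field {s!r} exceeds {width} ascii characters")
    return s.ljust(width).encode("ascii")


def _fit_sym(x: float) -> str:
    """Format a positive float into at most 7 ascii characters, so both
    the value and its negation fit an 8-character EDF header field."""
    for fmt in (".6g", ".5g", ".4g", ".3g", ".2g"):
        s = format(x, fmt)
        if len(s) <= 7:
            return s
    raise ConfigError(f"cannot represent {x} in an EDF header field")


def write_edf(rec: SignalRecord, path: str | Path) -> Path:
    """Write a single-channel EDF file with 1-s data records.

    Samples are quantized to 16 bits over a symmetric physical range chosen
    from the data; the quantization step is (phys_max - phys_min) / 65535.
    Requires an integer sampling rate; the signal is zero-padded to a whole
    number of seconds if needed.
    """
    path = Path(path)
    rate = rec.rate
    if rate != int(rate) or rate <= 0:
        raise ConfigError(f"EDF writer requires a positive integer rate, got {rate}")
    spr = int(rate)  # samples per 1-s record

    x = rec.samples
    if x.size % spr:
        pad = spr - x.size % spr
        log.warning("padding signal with %d zero samples to a whole second", pad)
        x = np.concatenate([x, np.zeros(pad)])
    n_records = x.size // spr

    # Symmetric physical range; re-parse the ascii value so the
    # quantization grid matches what a reader will reconstruct.
    peak = float(np.max(np.abs(x))) if np.any(x) else 1.0
    pm = float(_fit_sym(peak))
    while pm < peak:
        pm = float(_fit_sym(pm * 1.001))
    phys_min, phys_max = -pm, pm

    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.round((x - phys_min) * scale + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    start = rec.start_time
    date_s = start.strftime("%d.%m.%y") if start else "01.01.00"
    time_s = start.strftime("%H.%M.%S") if start else "00.00.00"

    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate X X X X", 80),
        _ascii(date_s, 8),
        _ascii(time_s, 8),
        _ascii(256 * 2, 8),          # header bytes: global + one signal
        _ascii("", 44),
        _ascii(n_records, 8),
        _ascii(1, 8),                # record duration, seconds
        _ascii(1, 4),                # number of signals
        _ascii(rec.channel_label, 16),
        _ascii("", 80),              # transducer
        _ascii("uV", 8),
        _ascii(f"-{_fit_sym(pm)}", 8),
        _ascii(_fit_sym(pm), 8),
        _ascii(_DIG_MIN, 8),
        _ascii(_DIG_MAX, 8),
        _ascii("", 80),              # prefiltering
        _ascii(spr, 8),
        _ascii("", 32),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
    return path
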