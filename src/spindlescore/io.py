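"""File I/O: Neuroscope flat-binary LFP files and motion CSV traces.

The flat-binary convention is little-endian int16, channel-multiplexed
(sample-major): the file holds frames of ``n_channels`` consecutive int16
values, one frame per sample.  Motion traces are CSV with either two
columns (time_s, speed) or a single speed column preceded by a
``# rate_hz: <value>`` comment line.  Times in all outputs are seconds
from recording start.  Channel indices are 0-based throughout.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CorruptFileError, FormatError, InvalidParameterError
from .intervals import write_intervals_tsv
from .signals import SignalTrace

__all__ = [
    "LfpFileSpec",
    "read_lfp_channel",
    "write_lfp",
    "float_to_int16",
    "read_motion_csv",
    "write_motion_csv",
    "write_session",
]

BYTES_PER_SAMPLE = 2  # int16


@dataclass(frozen=True)
class LfpFileSpec:
    """Layout of a flat-binary ``.lfp``/``.dat`` file."""

    path: str | os.PathLike
    n_channels: int
    sample_rate: float = 1250.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise InvalidParameterError("n_channels must be >= 1")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")


def read_lfp_channel(
    spec: LfpFileSpec, channel_index: int, gain: float = 1.0
) -> SignalTrace:
    """De-multiplex one channel of a flat-binary file into a trace.

    Values are returned in raw integer units unless a ``gain`` (volts or
    any unit per integer step) is supplied.
    """
    if not (0 <= channel_index < spec.n_channels):
        raise InvalidParameterError(
            f"channel_index {channel_index} out of range for "
            f"{spec.n_channels} channels"
        )
    path = Path(spec.path)
    size = path.stat().st_size
    frame = BYTES_PER_SAMPLE * spec.n_channels
    if size == 0 or size % frame != 0:
        raise CorruptFileError(
            f"{path}: size {size} bytes is not a multiple of the "
            f"{frame}-byte frame ({spec.n_channels} int16 channels)"
        )
    raw = np.fromfile(path, dtype="<i2").reshape(-1, spec.n_channels)
    samples = raw[:, channel_index].astype(float) * gain
    return SignalTrace(samples, spec.sample_rate)


def write_lfp(path, channels: np.ndarray) -> None:
    """Write int16 channel data as a flat-binary file.

    ``channels`` has shape (n_samples, n_channels) — or (n_samples,) for a
    single channel — and must already be int16.
    """
    arr = np.asarray(channels)
    if arr.dtype != np.int16:
        raise InvalidParameterError(
            "channels must be int16; convert with float_to_int16 first"
        )
    if arr.ndim == 1:
        arr = arr[:, None]
    arr.astype("<i2").tofile(path)


def float_to_int16(samples: np.ndarray, gain: float = 1000.0) -> np.ndarray:
    """Quantize a float trace to int16 at ``gain`` integer steps per unit."""
    scaled = np.round(np.asarray(samples, dtype=float) * gain)
    return np.clip(scaled, -32768, 32767).astype(np.int16)


def read_motion_csv(path, rate: float | None = None) -> SignalTrace:
    """Read an angular-speed trace from CSV.

    Accepted dialects:

    * two columns (time_s, speed), with or without a header — the time
      column must be strictly increasing; non-uniform timestamps are
      resampled onto a uniform grid with a warning;
    * one speed column, the rate given either by a leading
      ``# rate_hz: <value>`` comment or the ``rate`` argument.
    """
    path = Path(path)
    header_rate = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        text = first.lstrip("#").strip()
        if ":" in text or "=" in text:
            key, _, value = text.replace("=", ":").partition(":")
            if key.strip().lower() in ("rate", "rate_hz", "sampling_rate"):
                header_rate = float(value)
    df = pd.read_csv(path, comment="#", header=None if _headerless(first) else 0)
    df = df.dropna(axis=1, how="all")
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError(f"{path}: time column is not strictly increasing")
        med = float(np.median(dt))
        # overall span gives a far better rate estimate than any single step
        out_rate = (len(t) - 1) / (t[-1] - t[0])
        if np.max(np.abs(dt - med)) > max(1e-9, 1e-3 * med):
            warnings.warn(
                f"{path}: non-uniform timestamps; resampling to "
                f"{out_rate:.6g} Hz",
                stacklevel=2,
            )
            uniform_t = t[0] + np.arange(len(t)) / out_rate
            v = np.interp(uniform_t, t, v)
        return SignalTrace(v, out_rate, start_time=float(t[0]))
    out_rate = rate if rate is not None else header_rate
    if out_rate is None:
        raise FormatError(
            f"{path}: single-column file needs a '# rate_hz:' header or an "
            "explicit rate"
        )
    return SignalTrace(df.iloc[:, 0].to_numpy(dtype=float), float(out_rate))


def _headerless(first_line: str) -> bool:
    if first_line.startswith("#"):
        return False  # let pandas treat next line as header
    fields = first_line.split(",")
    try:
        [float(f) for f in fields]
        return True
    except ValueError:
        return False


def write_motion_csv(path, speed: SignalTrace, two_column: bool = True) -> None:
    """Write a speed trace in one of the dialects :func:`read_motion_csv` reads."""
    if two_column:
        with open(path, "w") as fh:
            fh.write("time_s,speed\n")
            np.savetxt(
                fh,
                np.column_stack((speed.times(), speed.samples)),
                fmt=["%.6f", "%.8g"],
                delimiter=",",
            )
    else:
        with open(path, "w") as fh:
            fh.write(f"# rate_hz: {speed.rate:g}\n")
            fh.write("speed\n")
            np.savetxt(fh, speed.samples, fmt="%.8g")


def write_session(session, out_dir, gain: float = 1000.0) -> dict[str, Path]:
    """Persist a synthetic session in the on-disk formats the readers accept.

    Writes ``session.lfp`` (2 channels: 0 = cortical, 1 = hippocampal,
    int16 at ``gain`` steps per unit), ``motion.csv`` and ``truth.tsv``.
    Returns the paths keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lfp_path = out / "session.lfp"
    channels = np.column_stack(
        (
            float_to_int16(session.cortical.samples, gain),
            float_to_int16(session.hpc.samples, gain),
        )
    )
    write_lfp(lfp_path, channels)
    motion_path = out / "motion.csv"
    write_motion_csv(motion_path, session.speed)
    truth_path = out / "truth.tsv"
    write_intervals_tsv(truth_path, session.truth)
    return {"lfp": lfp_path, "motion": motion_path, "truth": truth_path}
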