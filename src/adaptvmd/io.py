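"""Signal file I/O: plain CSV and WFDB records, plus reproducibility sidecars.

CSV dialect: one sample per row, with the sampling rate in a leading
``# fs=<Hz>`` comment (a bare ``fs=<Hz>`` first line is also accepted).

The WFDB reader is a minimal, self-contained decoder of the PhysioNet
header + signal layout, covering the two sample encodings used by the
MIT-BIH Arrhythmia Database family: format 212 (two 12-bit samples packed
into 3 bytes) and format 16 (little-endian int16).  Amplitudes are converted
to physical units via (adc - baseline) / gain.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np

from .signals import ECGSignal, InvalidSignalError


def read_csv_signal(path: str | Path, fs: float | None = None) -> ECGSignal:
    """Read a one-column CSV; ``fs`` from the header unless given explicitly."""
    path = Path(path)
    samples: list[float] = []
    header_fs: float | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                line = line[1:].strip()
                if line.startswith("fs="):
                    header_fs = float(line[3:])
                continue
            if line.startswith("fs="):
                header_fs = float(line[3:])
                continue
            samples.append(float(line))
    fs = fs if fs is not None else header_fs
    if fs is None:
        raise InvalidSignalError(f"{path}: no sampling rate (expected a '# fs=<Hz>' header)")
    return ECGSignal(np.asarray(samples), fs, label=path.stem)


def write_csv_signal(path: str | Path, signal: ECGSignal) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={signal.fs:g}\n")
        for v in signal.samples:
            fh.write(f"{float(v)!r}\n")


@dataclasses.dataclass
class _WFDBChannel:
    filename: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


def _parse_header(hea_path: Path) -> tuple[int, float, int, list[_WFDBChannel]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec = lines[0].split()
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    channels = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, 0, "mV"
        if len(tok) > 2:
            g = tok[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, base = g.split("(")
                baseline = int(base.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
            # adc zero (token 4) is the baseline fallback when no '(baseline)'
            if "(" not in tok[2] and len(tok) > 4:
                baseline = int(tok[4])
        description = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(channels)}"
        channels.append(_WFDBChannel(tok[0], fmt, gain, baseline, units, description))
    return n_sig, fs, n_samples, channels


def _decode_212(raw: bytes, n_sig: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    s0 = np.where(s0 > 2047, s0 - 4096, s0)
    s1 = np.where(s1 > 2047, s1 - 4096, s1)
    flat = np.empty(s0.size + s1.size, dtype=np.int32)
    flat[0::2] = s0
    flat[1::2] = s1
    return flat.reshape(-1, n_sig) if n_sig > 1 else flat.reshape(-1, 1)


def _decode_16(raw: bytes, n_sig: int) -> np.ndarray:
    flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    flat = flat[: (flat.size // n_sig) * n_sig]
    return flat.reshape(-1, n_sig)


def read_wfdb_signal(record: str | Path, channel: int | None = None) -> ECGSignal:
    """Read one channel of a WFDB record given its path without extension
    (or its ``.hea`` path).  Defaults to channel 0 with a warning when the
    record is multi-channel and no channel is named."""
    record = Path(record)
    hea_path = record if record.suffix == ".hea" else record.with_suffix(".hea")
    if not hea_path.exists():
        raise FileNotFoundError(hea_path)
    n_sig, fs, n_samples, channels = _parse_header(hea_path)
    if channel is None:
        channel = 0
        if n_sig > 1:
            warnings.warn(
                f"{hea_path.name}: {n_sig} channels, defaulting to channel 0 "
                f"({channels[0].description})",
                stacklevel=2,
            )
    if not 0 <= channel < n_sig:
        raise InvalidSignalError(f"channel {channel} out of range for {n_sig} channels")

    ch = channels[channel]
    same_file = [i for i, c in enumerate(channels) if c.filename == ch.filename]
    dat_path = hea_path.parent / ch.filename
    raw = dat_path.read_bytes()
    if ch.fmt == 212:
        adc = _decode_212(raw, len(same_file))
    elif ch.fmt == 16:
        adc = _decode_16(raw, len(same_file))
    else:
        raise InvalidSignalError(f"unsupported WFDB sample format {ch.fmt}")
    col = same_file.index(channel)
    samples = (adc[:, col] - ch.baseline) / ch.gain
    if n_samples:
        samples = samples[:n_samples]
    return ECGSignal(samples, fs, label=f"{hea_path.stem}:{ch.description}")


def read_signal(
    path: str | Path, format: str | None = None, channel: int | None = None,
    fs: float | None = None,
) -> ECGSignal:
    """Dispatch on ``format`` ('wfdb' or 'csv'), inferring from the extension
    when not given."""
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix in (".hea", ".dat") or not path.suffix else "csv"
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        return read_csv_signal(path, fs=fs)
    if format == "wfdb":
        return read_wfdb_signal(path, channel=channel)
    raise InvalidSignalError(f"unknown signal format {format!r}")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_sidecar(path: str | Path, payload: Any) -> None:
    """Write a JSON sidecar recording every resolved parameter of a run, so
    the run can be reproduced exactly."""
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
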