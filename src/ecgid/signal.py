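"""Single-lead ECG container and record I/O.

Supported on-disk formats:

* single-column CSV/TXT of voltage samples (sampling rate supplied by the
  caller), and
* a minimal WFDB-style record (``.hea`` text header plus a format-16
  little-endian int16 ``.dat`` signal file), which is the layout PhysioNet
  uses for most single-lead exports.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ECGSignal", "read_record", "write_csv", "write_wfdb"]


@dataclass
class ECGSignal:
    """A uniformly sampled single-lead voltage series.

    Parameters
    ----------
    samples : array-like
        Voltage samples (mV or arbitrary units). Must be finite, length >= 2.
    fs : float
        Sampling rate in Hz, strictly positive.
    record_id : str
        Free-text label for the recording.
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float).ravel()
        if samples.size < 2:
            raise ValueError("ECGSignal needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("ECGSignal samples must be finite")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs!r}")
        self.samples = samples
        self.fs = float(self.fs)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    def time(self) -> np.ndarray:
        """Sample times in seconds (0-based)."""
        return np.arange(self.samples.size) / self.fs


# ---------------------------------------------------------------------------
# Readers / writers


def read_record(path: str | pathlib.Path, fs: float | None = None,
                channel: int = 0, record_id: str | None = None) -> ECGSignal:
    """Read an ECG recording from CSV/TXT or a WFDB-style header.

    ``path`` ending in ``.hea`` (or a bare record name whose ``.hea`` exists)
    selects the WFDB path; anything else is parsed as a single-column text
    file and requires ``fs``.
    """
    path = pathlib.Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if path.suffix == ".hea" or (path.suffix == "" and hea.exists()):
        return _read_wfdb(hea, channel=channel, fs_override=fs)
    if not path.exists():
        raise FileNotFoundError(path)
    data = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None,
                      ndmin=2, comments="#")
    if fs is None:
        raise ValueError("sampling rate (fs) is required for CSV/TXT input")
    return ECGSignal(data[:, channel], fs=fs,
                     record_id=record_id if record_id is not None else path.stem)


def write_csv(signal: ECGSignal, path: str | pathlib.Path) -> None:
    """Write samples as single-column CSV with an fs comment header."""
    header = f"record_id={signal.record_id} fs={signal.fs}"
    np.savetxt(path, signal.samples, fmt="%.9g", header=header)


def _read_wfdb(header_path: pathlib.Path, channel: int = 0,
               fs_override: float | None = None) -> ECGSignal:
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    lines = [ln.strip() for ln in header_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty WFDB header: {header_path}")
    rec = lines[0].split()
    try:
        name = rec[0]
        n_sig = int(rec[1])
        fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
        n_samp = int(rec[3]) if len(rec) > 3 else None
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed WFDB record line: {lines[0]!r}") from exc
    if not 0 <= channel < n_sig:
        raise ValueError(f"channel {channel} out of range for {n_sig} signals")
    sig_lines = lines[1:1 + n_sig]
    if len(sig_lines) < n_sig:
        raise ValueError("WFDB header lists fewer signal lines than n_sig")
    toks = sig_lines[channel].split()
    dat_file = toks[0]
    fmt = toks[1].split("x")[0].split(":")[0].split("+")[0]
    if fmt != "16":
        raise ValueError(f"unsupported WFDB signal format {fmt!r} (only 16)")
    gain, baseline = 200.0, 0.0
    if len(toks) > 2:
        g = toks[2]
        units_split = g.split("/")[0]
        if "(" in units_split:
            gpart, bpart = units_split.split("(")
            gain = float(gpart) if gpart else 200.0
            baseline = float(bpart.rstrip(")"))
        elif units_split:
            gain = float(units_split)
    if gain == 0:
        gain = 200.0
    raw = np.fromfile(header_path.parent / dat_file, dtype="<i2")
    raw = raw.reshape(-1, n_sig)
    if n_samp is not None:
        raw = raw[:n_samp]
    phys = (raw[:, channel].astype(float) - baseline) / gain
    return ECGSignal(phys, fs=fs_override if fs_override else fs, record_id=name)


def write_wfdb(signal: ECGSignal, path_stem: str | pathlib.Path,
               gain: float = 1000.0, units: str = "mV") -> pathlib.Path:
    """Write a minimal single-channel WFDB record (format 16).

    Samples are quantised to ``round(x * gain)`` int16 ADC units; returns the
    header path.
    """
    stem = pathlib.Path(path_stem)
    name = stem.name
    adc = np.round(signal.samples * gain)
    if np.any(np.abs(adc) > 32767):
        raise ValueError("signal exceeds int16 range at this gain")
    adc = adc.astype("<i2")
    (stem.parent / f"{name}.dat").write_bytes(adc.tobytes())
    hea = stem.with_suffix(".hea")
    hea.write_text(
        f"{name} 1 {signal.fs:g} {adc.size}\n"
        f"{name}.dat 16 {gain:g}(0)/{units} 16 0 {int(adc[0])} 0 0 ECG\n"
    )
    return hea
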