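"""Reading and validating ECG recordings and per-minute annotations.

Two on-disk dialects are supported: a minimal WFDB-style ``.hea``/``.dat``
pair (format 16, single signal) and a plain CSV fallback with one sample per
line.  Per-minute apnea annotations live in a ``.apn`` sidecar, either one
character per line or a single string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["EcgRecording", "FormatError", "read_recording", "segment_minutes", "ahi_class"]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file failed to parse or violated a recording invariant."""


@dataclass
class EcgRecording:
    record_id: str
    signal: np.ndarray
    fs: float
    minute_labels: list[str] | None = None   # 'A'/'N', one per full minute
    ahi_class: str | None = None             # 'A'/'B'/'C' severity metadata

    @property
    def n_minutes(self) -> int:
        return int(len(self.signal) // (60 * self.fs))

    def validate(self) -> None:
        if self.fs <= 0:
            raise FormatError(f"{self.record_id}: fs must be > 0, got {self.fs}")
        if len(self.signal) < 60 * self.fs:
            raise FormatError(
                f"{self.record_id}: recording shorter than one minute "
                f"({len(self.signal)} samples at {self.fs} Hz)"
            )
        if self.minute_labels is not None and len(self.minute_labels) != self.n_minutes:
            raise FormatError(
                f"{self.record_id}: {len(self.minute_labels)} labels for "
                f"{self.n_minutes} full minutes of signal"
            )


def ahi_class(ahi: float) -> str:
    """Severity class from AHI: C (<5, normal), B (5-10, borderline), A (>10)."""
    if ahi < 5:
        return "C"
    if ahi > 10:
        return "A"
    return "B"


def _read_labels(path: Path) -> list[str]:
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) == 1 and len(lines[0]) > 1:
        labels = list(lines[0])          # single-string dialect
    else:
        labels = lines                   # one-char-per-line dialect
    bad = sorted(set(labels) - {"A", "N"})
    if bad:
        raise FormatError(f"{path}: invalid annotation label(s) {bad}")
    return labels


def _read_wfdb(prefix: Path) -> tuple[np.ndarray, float]:
    hea = prefix.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"missing header file {hea}")
    lines = [
        ln for ln in hea.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}: header line needs 'name nsig fs nsamp'")
    try:
        n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    except ValueError as e:
        raise FormatError(f"{hea}: malformed header fields: {e}") from e
    if fs <= 0:
        raise FormatError(f"{hea}: fs must be > 0, got {fs}")
    if n_sig != 1:
        raise FormatError(f"{hea}: only single-signal records supported, got {n_sig}")
    sig_line = lines[1].split()
    if sig_line[1] != "16":
        raise FormatError(f"{hea}: only format 16 supported, got {sig_line[1]}")
    gain = float(sig_line[2]) if len(sig_line) > 2 else 200.0
    if gain == 0:
        gain = 200.0
    dat = prefix.with_suffix(".dat")
    if not dat.exists():
        raise FormatError(f"missing signal file {dat}")
    digital = np.fromfile(dat, dtype="<i2")
    if len(digital) < n_samp:
        raise FormatError(f"{dat}: {len(digital)} samples, header declares {n_samp}")
    return digital[:n_samp].astype(float) / gain, fs


def read_recording(
    path: str | Path, format: str = "wfdb", fs: float = 100.0
) -> EcgRecording:
    """Read one recording given its prefix path (extension optional).

    ``fs`` is only used by the headerless CSV dialect.  A trailing partial
    minute of signal is discarded with a logged warning; labels must then
    match the number of full minutes retained.
    """
    prefix = Path(path)
    if prefix.suffix in (".hea", ".dat", ".csv", ".apn"):
        prefix = prefix.with_suffix("")
    if format == "wfdb":
        signal, fs = _read_wfdb(prefix)
    elif format == "csv":
        csv = prefix.with_suffix(".csv")
        if not csv.exists():
            raise FormatError(f"missing signal file {csv}")
        signal = np.loadtxt(csv, ndmin=1)
        if signal.ndim != 1:
            raise FormatError(f"{csv}: expected a single column of samples")
    else:
        raise FormatError(f"unknown format {format!r} (use 'wfdb' or 'csv')")

    spm = int(round(60 * fs))
    n_minutes = len(signal) // spm
    if n_minutes < 1:
        raise FormatError(f"{prefix}: recording shorter than one minute")
    if len(signal) > n_minutes * spm:
        logger.warning(
            "%s: discarding trailing partial minute (%d samples)",
            prefix.name,
            len(signal) - n_minutes * spm,
        )
        signal = signal[: n_minutes * spm]

    labels = None
    apn = prefix.with_suffix(".apn")
    if apn.exists():
        labels = _read_labels(apn)
        if len(labels) != n_minutes:
            raise FormatError(
                f"{apn}: {len(labels)} labels for {n_minutes} minutes of signal"
            )
    rec = EcgRecording(record_id=prefix.name, signal=signal, fs=fs, minute_labels=labels)
    if labels is not None:
        rec.ahi_class = ahi_class(60.0 / n_minutes * labels.count("A"))
    rec.validate()
    return rec


def segment_minutes(rec: EcgRecording) -> list[tuple[int, slice]]:
    """Non-overlapping 1-minute sample slices, half-open and 0-based.

    Minute ``k`` covers samples ``[k*60*fs, (k+1)*60*fs)``; a trailing partial
    minute is never returned.
    """
    rec.validate()
    spm = int(round(60 * rec.fs))
    return [(k, slice(k * spm, (k + 1) * spm)) for k in range(rec.n_minutes)]
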