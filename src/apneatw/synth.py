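"""Synthetic single-lead apnea-ECG generator with known ground truth.

The generator does not attempt physiological ECG morphology.  It produces the
two signal properties the downstream pipeline actually consumes — R-peak times
and R-peak amplitudes — with the spectral signature that separates apnea from
normal breathing in minute-level HRV analysis:

* apnea minutes: the RR series and the R-amplitude (EDR) series are both
  modulated by a slow cyclic oscillation (default 0.02 Hz, inside the VLF
  band), the well-known cyclical-variation-of-heart-rate pattern of repetitive
  apneas;
* normal minutes: both series carry a small respiratory-sinus-arrhythmia
  modulation at the breathing rate (default 0.25 Hz, inside the HF band).

Beats are laid down by integrating an instantaneous RR series, each rendered
as a raised-cosine QRS spike on a sampled grid, plus white Gaussian noise.
Per-minute apnea severity is varied (a uniform scale per apnea minute) and a
multiplicative RR jitter provides an HRV noise floor, so that single-minute
features are informative but imperfect — as in real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SynthConfig",
    "SynthRecording",
    "generate_recording",
    "write_fixture",
    "markov_labels",
    "labels_for_ahi",
]


class SynthConfigError(ValueError):
    """Invalid synthetic-generator configuration; names the offending field."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording.

    ``label_pattern`` may be a string/sequence of per-minute 'A'/'N' labels, a
    float target AHI (events/hour; apnea minutes placed as one contiguous
    bout), or None to draw labels from a two-state Markov chain whose
    persistence produces multi-minute apnea bouts (the temporal dependence the
    time-window classifier exploits).
    """

    duration_min: int = 60
    fs: float = 100.0
    baseline_rr_s: float = 1.0
    apnea_rr_modulation_depth: float = 0.25
    apnea_cycle_hz: float = 0.02          # inside VLF (0-0.04 Hz)
    normal_hf_depth: float = 0.05
    normal_hf_hz: float = 0.25            # inside HF (0.15-0.4 Hz)
    amp_modulation_depth: float = 0.2
    noise_sd: float = 0.05
    qrs_width_ms: float = 40.0
    rr_jitter_frac: float = 0.03          # multiplicative white RR jitter
    # slow non-apneic background variability (Mayer waves, vasomotor drift):
    # an Ornstein-Uhlenbeck process multiplying RR and amplitude in ALL
    # minutes, so weak apnea minutes genuinely overlap with normal ones
    rr_wander_sd: float = 0.06
    amp_wander_sd: float = 0.05
    wander_tau_s: float = 50.0
    apnea_severity_range: tuple[float, float] = (0.0, 1.0)
    p_stay_apnea: float = 0.92            # Markov persistence: mean apneic episode ~12 min
    p_stay_normal: float = 0.95
    label_pattern: str | float | Sequence[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise SynthConfigError("fs must be > 0")
        if self.duration_min < 1:
            raise SynthConfigError("duration_min must be >= 1")
        if not (0.3 < self.baseline_rr_s < 2.0):
            raise SynthConfigError("baseline_rr_s must lie in (0.3, 2.0)")
        for name in (
            "apnea_rr_modulation_depth",
            "normal_hf_depth",
            "amp_modulation_depth",
        ):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise SynthConfigError(f"{name} must lie in [0, 1)")
        if self.noise_sd < 0:
            raise SynthConfigError("noise_sd must be >= 0")
        if self.qrs_width_ms <= 0:
            raise SynthConfigError("qrs_width_ms must be > 0")
        if self.rr_jitter_frac < 0:
            raise SynthConfigError("rr_jitter_frac must be >= 0")
        if self.rr_wander_sd < 0 or self.amp_wander_sd < 0:
            raise SynthConfigError("wander sd values must be >= 0")
        if self.wander_tau_s <= 0:
            raise SynthConfigError("wander_tau_s must be > 0")


@dataclass
class SynthRecording:
    record_id: str
    signal: np.ndarray            # float samples, length duration_min*60*fs
    fs: float
    true_r_peaks: np.ndarray      # sample indices, strictly increasing
    true_r_amplitudes: np.ndarray
    minute_labels: list[str]      # 'A' / 'N', one per minute
    true_ahi: float               # 60/T * #apnea minutes, T = duration_min

    @property
    def duration_min(self) -> int:
        return len(self.minute_labels)


def markov_labels(
    n_minutes: int, p_stay_apnea: float, p_stay_normal: float, rng: np.random.Generator
) -> list[str]:
    """Per-minute labels from a two-state Markov chain (start state ~ stationary)."""
    # stationary P(A) for the 2-state chain
    pa = (1 - p_stay_normal) / ((1 - p_stay_normal) + (1 - p_stay_apnea))
    labels = []
    state = "A" if rng.random() < pa else "N"
    for _ in range(n_minutes):
        labels.append(state)
        stay = p_stay_apnea if state == "A" else p_stay_normal
        if rng.random() >= stay:
            state = "N" if state == "A" else "A"
    return labels


def labels_for_ahi(n_minutes: int, target_ahi: float) -> list[str]:
    """One contiguous apnea bout sized so that 60/T * n_A == target_ahi."""
    n_apnea = int(round(target_ahi * n_minutes / 60.0))
    if not (0 <= n_apnea <= n_minutes):
        raise SynthConfigError("label_pattern target AHI out of range")
    start = (n_minutes - n_apnea) // 4
    labels = ["N"] * n_minutes
    for k in range(start, start + n_apnea):
        labels[k] = "A"
    return labels


def _resolve_labels(cfg: SynthConfig, rng: np.random.Generator) -> list[str]:
    lp = cfg.label_pattern
    if lp is None:
        return markov_labels(cfg.duration_min, cfg.p_stay_apnea, cfg.p_stay_normal, rng)
    if isinstance(lp, (int, float)) and not isinstance(lp, bool):
        return labels_for_ahi(cfg.duration_min, float(lp))
    labels = list(lp)
    if len(labels) != cfg.duration_min:
        raise SynthConfigError(
            f"label_pattern has {len(labels)} labels for {cfg.duration_min} minutes"
        )
    bad = sorted(set(labels) - {"A", "N"})
    if bad:
        raise SynthConfigError(f"label_pattern contains invalid labels {bad}")
    return labels


def _qrs_template(fs: float, width_ms: float) -> np.ndarray:
    """Raised-cosine spike with unit peak at its centre sample."""
    half = max(1, int(round(width_ms / 1000.0 * fs / 2.0)))
    k = np.arange(-half, half + 1)
    return 0.5 * (1.0 + np.cos(np.pi * k / half))


def generate_recording(config: SynthConfig, record_id: str = "synth") -> SynthRecording:
    """Simulate one recording; every ground-truth field comes from the construction."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    labels = _resolve_labels(cfg, rng)
    duration_s = cfg.duration_min * 60.0
    n_samples = int(round(cfg.duration_min * 60 * cfg.fs))

    # Per-minute modulation gains.  Apnea severity scales the cyclic VLF
    # component and suppresses respiratory HF modulation proportionally (a
    # severe event abolishes breathing; a mild event / hypopnea keeps most of
    # it).  Normal minutes keep a variable respiratory depth.  This severity
    # heterogeneity is what makes single-minute classification imperfect.
    lo, hi = cfg.apnea_severity_range
    severity = lo + (hi - lo) * rng.random(cfg.duration_min)
    resp_scale = 0.3 + 0.7 * rng.random(cfg.duration_min)
    vlf_gain = np.zeros(cfg.duration_min)
    hf_gain = np.zeros(cfg.duration_min)
    amp_vlf_gain = np.zeros(cfg.duration_min)
    amp_hf_gain = np.zeros(cfg.duration_min)
    for m, lab in enumerate(labels):
        if lab == "A":
            vlf_gain[m] = cfg.apnea_rr_modulation_depth * severity[m]
            hf_gain[m] = cfg.normal_hf_depth * (1.0 - severity[m])
            amp_vlf_gain[m] = cfg.amp_modulation_depth * severity[m]
            amp_hf_gain[m] = cfg.normal_hf_depth * (1.0 - severity[m])
        else:
            hf_gain[m] = cfg.normal_hf_depth * resp_scale[m]
            amp_hf_gain[m] = cfg.normal_hf_depth * resp_scale[m]

    phase = rng.uniform(0, 2 * np.pi)

    # integrate the instantaneous RR series into beat times
    beat_times: list[float] = []
    beat_amps: list[float] = []
    t = 0.5 * cfg.baseline_rr_s
    # beat-to-beat Ornstein-Uhlenbeck wander states (stationary start)
    rr_wander = cfg.rr_wander_sd * rng.standard_normal() if cfg.rr_wander_sd else 0.0
    amp_wander = cfg.amp_wander_sd * rng.standard_normal() if cfg.amp_wander_sd else 0.0
    while t < duration_s:
        minute = min(int(t // 60.0), cfg.duration_min - 1)
        s_vlf = np.sin(2 * np.pi * cfg.apnea_cycle_hz * t + phase)
        s_hf = np.sin(2 * np.pi * cfg.normal_hf_hz * t + phase)
        mod = vlf_gain[minute] * s_vlf + hf_gain[minute] * s_hf
        amp = 1.0 + amp_vlf_gain[minute] * s_vlf + amp_hf_gain[minute] * s_hf
        beat_times.append(t)
        beat_amps.append(amp * (1.0 + amp_wander))
        rr = cfg.baseline_rr_s * (1.0 + mod + rr_wander)
        if cfg.rr_jitter_frac > 0:
            rr *= 1.0 + cfg.rr_jitter_frac * rng.standard_normal()
        rr = max(rr, 0.33 * cfg.baseline_rr_s)
        # advance the OU states by one beat interval
        decay = np.exp(-rr / cfg.wander_tau_s)
        diffuse = np.sqrt(max(0.0, 1.0 - decay**2))
        if cfg.rr_wander_sd:
            rr_wander = rr_wander * decay + cfg.rr_wander_sd * diffuse * rng.standard_normal()
        if cfg.amp_wander_sd:
            amp_wander = amp_wander * decay + cfg.amp_wander_sd * diffuse * rng.standard_normal()
        t += rr

    r_idx = np.round(np.asarray(beat_times) * cfg.fs).astype(np.int64)
    keep = r_idx < n_samples
    r_idx = r_idx[keep]
    r_amp = np.asarray(beat_amps)[keep]
    # integration step guarantees strictly increasing times; rounding to the
    # sample grid cannot merge beats because RR >= 0.33*baseline > 2/fs
    assert np.all(np.diff(r_idx) > 0)

    signal = np.zeros(n_samples)
    tpl = _qrs_template(cfg.fs, cfg.qrs_width_ms)
    half = (len(tpl) - 1) // 2
    for idx, amp in zip(r_idx, r_amp):
        a = max(idx - half, 0)
        b = min(idx + half + 1, n_samples)
        signal[a:b] += amp * tpl[a - (idx - half) : b - (idx - half)]
    if cfg.noise_sd > 0:
        signal = signal + cfg.noise_sd * rng.standard_normal(n_samples)

    true_ahi = 60.0 / cfg.duration_min * labels.count("A")
    return SynthRecording(
        record_id=record_id,
        signal=signal,
        fs=cfg.fs,
        true_r_peaks=r_idx,
        true_r_amplitudes=r_amp,
        minute_labels=labels,
        true_ahi=true_ahi,
    )


# ---------------------------------------------------------------------------
# fixtures on disk

WFDB_GAIN = 1000.0  # ADU per signal unit for the 16-bit container


def write_fixture(rec: SynthRecording, path: str | Path, format: str = "wfdb") -> Path:
    """Write ``rec`` under directory ``path`` as a wfdb-like or csv fixture.

    wfdb-like: ``<id>.hea`` (text header), ``<id>.dat`` (16-bit little-endian),
    ``<id>.apn`` (one label character per minute, one per line).
    csv: ``<id>.csv`` (one sample per line) + the same ``.apn`` sidecar.
    Returns the record prefix path (without extension).
    """
    if len(rec.signal) == 0 or rec.duration_min == 0:
        raise ValueError("cannot write an empty recording")
    if format not in ("wfdb", "csv"):
        raise ValueError(f"unknown fixture format {format!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    prefix = path / rec.record_id
    if format == "wfdb":
        digital = np.clip(
            np.round(rec.signal * WFDB_GAIN), -32768, 32767
        ).astype("<i2")
        digital.tofile(prefix.with_suffix(".dat"))
        fs_txt = f"{rec.fs:g}"
        header = (
            f"{rec.record_id} 1 {fs_txt} {len(rec.signal)}\n"
            f"{rec.record_id}.dat 16 {WFDB_GAIN:g} 16 0 0 0 0 ECG\n"
        )
        prefix.with_suffix(".hea").write_text(header)
    else:
        np.savetxt(prefix.with_suffix(".csv"), rec.signal, fmt="%.6f")
    prefix.with_suffix(".apn").write_text("".join(f"{c}\n" for c in rec.minute_labels))
    return prefix
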