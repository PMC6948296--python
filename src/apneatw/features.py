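"""The 18 per-segment features and z-score normalization.

Six time-domain HRV features of the RR series (MRR, MHR, RMSSD, SDNN, NN50,
pNN50), six Welch band-power features of the RR tachogram (VLF, LF, HF, LF/HF,
LF/(LF+HF), HF/(LF+HF)) and the same six band-power features of the R-peak
amplitude (EDR) series.  Both unevenly sampled series are cubic-spline
interpolated onto a uniform grid (default 4 Hz) before the Welch estimate
(Hann window, 256-point FFT, 50% overlap); band powers are trapezoidal
integrals of the PSD over VLF 0-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.4 Hz.

Feature order is frozen in ``FEATURE_NAMES`` so trained model weights remain
portable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from apneatw.config import FeatureConfig, RunConfig, WelchConfig
from apneatw.io import EcgRecording
from apneatw.preprocess import (
    RrSeries,
    SegmentBeats,
    bandpass_filter,
    correct_rr,
    detect_r_peaks,
    per_segment_beats,
    rr_from_beats,
)

__all__ = [
    "FEATURE_NAMES",
    "BANDS",
    "NormStats",
    "time_domain_features",
    "spectral_features",
    "extract_segment",
    "featurize_recording",
    "fit_normalizer",
    "apply_normalizer",
]

FEATURE_NAMES = [
    "MRR", "MHR", "RMSSD", "SDNN", "NN50", "pNN50",
    "rr_VLF", "rr_LF", "rr_HF", "rr_LF_HF", "rr_LF_norm", "rr_HF_norm",
    "amp_VLF", "amp_LF", "amp_HF", "amp_LF_HF", "amp_LF_norm", "amp_HF_norm",
]

#: HRV band edges in Hz; bands are half-open [lo, hi)
BANDS = {"VLF": (0.0, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}

NN50_THRESHOLD_S = 0.05
MIN_SPECTRAL_POINTS = 4
MIN_SPECTRAL_SPAN_S = 10.0


class InvalidSegment(ValueError):
    """A segment lacks the beats needed for feature extraction."""


def time_domain_features(
    rr: RrSeries | np.ndarray, cfg: FeatureConfig | None = None
) -> dict[str, float]:
    """MRR, MHR, RMSSD, SDNN, NN50, pNN50 of one segment's RR values (seconds).

    MRR is the sample mean; RMSSD the root mean square of successive
    differences with denominator N-1; SDNN the sample standard deviation
    (denominator N-1); NN50 counts successive differences strictly exceeding
    50 ms; pNN50 = NN50 over the number of adjacent pairs (N-1) by default,
    configurable to divide by N instead; MHR is the mean of the instantaneous
    rates 60/RR(n) in beats/min.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(rr.rr_s if isinstance(rr, RrSeries) else rr, dtype=float)
    n = len(x)
    if n < 2:
        raise InvalidSegment(f"need >= 2 RR intervals, got {n}")
    diffs = np.diff(x)
    nn50 = int(np.sum(np.abs(diffs) > NN50_THRESHOLD_S))
    denom = n - 1 if cfg.pnn50_denominator == "pairs" else n
    return {
        "MRR": float(np.mean(x)),
        "MHR": float(np.mean(60.0 / x)),
        "RMSSD": float(np.sqrt(np.sum(diffs**2) / (n - 1))),
        "SDNN": float(np.std(x, ddof=1)),
        "NN50": float(nn50),
        "pNN50": float(nn50 / denom),
    }


def spectral_features(
    values: np.ndarray,
    times_s: np.ndarray,
    cfg: WelchConfig | None = None,
) -> dict[str, float]:
    """VLF/LF/HF band powers and ratios of an unevenly sampled series.

    The series is cubic-spline interpolated onto a uniform ``interp_hz`` grid
    spanning its own time range, mean-removed, and fed to a Welch PSD
    (``nfft``-point FFT).  Ratios use 0/0 -> 0 and x/0 -> ``ratio_cap``.
    """
    cfg = cfg or WelchConfig()
    values = np.asarray(values, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if len(values) < MIN_SPECTRAL_POINTS or (
        len(times_s) and times_s[-1] - times_s[0] <= MIN_SPECTRAL_SPAN_S
    ):
        raise InvalidSegment(
            f"need >= {MIN_SPECTRAL_POINTS} points spanning > {MIN_SPECTRAL_SPAN_S} s"
        )
    grid = np.arange(times_s[0], times_s[-1] + 1e-9, 1.0 / cfg.interp_hz)
    x = CubicSpline(times_s, values)(grid)
    x = x - np.mean(x)
    nperseg = min(cfg.nfft, len(x))
    freqs, psd = sps.welch(
        x,
        fs=cfg.interp_hz,
        window=cfg.window,
        nperseg=nperseg,
        noverlap=int(cfg.overlap * nperseg),
        nfft=cfg.nfft,
        detrend="constant",
    )
    powers = {}
    for name, (lo, hi) in BANDS.items():
        band = (freqs >= lo) & (freqs < hi)
        powers[name] = float(np.trapezoid(psd[band], freqs[band])) if band.sum() > 1 else 0.0

    def ratio(a: float, b: float) -> float:
        if b > 0:
            return a / b
        return 0.0 if a == 0 else cfg.ratio_cap

    lf, hf, vlf = powers["LF"], powers["HF"], powers["VLF"]
    return {
        "VLF": vlf,
        "LF": lf,
        "HF": hf,
        "LF_HF": ratio(lf, hf),
        "LF_norm": ratio(lf, lf + hf),
        "HF_norm": ratio(hf, lf + hf),
    }


_SENTINEL = float("nan")


def extract_segment(
    seg: SegmentBeats,
    feature_cfg: FeatureConfig | None = None,
    welch_cfg: WelchConfig | None = None,
) -> tuple[np.ndarray, bool]:
    """Assemble the 18 features of one minute in ``FEATURE_NAMES`` order.

    Returns ``(vector, valid)``; an invalid minute (too few beats, or any
    sub-extractor failing) yields a NaN sentinel vector and ``valid=False``.
    """
    if not seg.valid:
        return np.full(len(FEATURE_NAMES), _SENTINEL), False
    try:
        td = time_domain_features(seg.rr, feature_cfg)
        rr_sp = spectral_features(seg.rr.rr_s, seg.rr.end_times_s, welch_cfg)
        amp_sp = spectral_features(seg.amp_values, seg.amp_times_s, welch_cfg)
    except InvalidSegment:
        return np.full(len(FEATURE_NAMES), _SENTINEL), False
    vec = np.array(
        [td[k] for k in ("MRR", "MHR", "RMSSD", "SDNN", "NN50", "pNN50")]
        + [rr_sp[k] for k in ("VLF", "LF", "HF", "LF_HF", "LF_norm", "HF_norm")]
        + [amp_sp[k] for k in ("VLF", "LF", "HF", "LF_HF", "LF_norm", "HF_norm")]
    )
    return vec, bool(np.all(np.isfinite(vec)))


def featurize_recording(rec: EcgRecording, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Full per-recording pipeline: filter, detect, correct, segment, extract.

    RR correction is applied once per recording, before segmentation.  Returns
    one row per minute with columns ``record_id, minute_index, label, valid``
    plus the 18 features (NaN where invalid).
    """
    cfg = cfg or RunConfig()
    rec.validate()
    filtered = bandpass_filter(rec.signal, rec.fs, cfg.filter)
    beats = detect_r_peaks(filtered, rec.fs)
    rows = []
    n_minutes = rec.n_minutes
    if len(beats) >= 2:
        rr = correct_rr(rr_from_beats(beats), cfg.rr_correct)
        segs = per_segment_beats(beats, rr, n_minutes, cfg.features)
    else:
        segs = None
    for k in range(n_minutes):
        if segs is None:
            vec, valid = np.full(len(FEATURE_NAMES), _SENTINEL), False
        else:
            vec, valid = extract_segment(segs[k], cfg.features, cfg.welch)
        row = {
            "record_id": rec.record_id,
            "minute_index": k,
            "label": (
                int(rec.minute_labels[k] == "A") if rec.minute_labels is not None else -1
            ),
            "valid": valid,
        }
        row.update(dict(zip(FEATURE_NAMES, vec)))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class NormStats:
    """Per-feature z-score statistics, fitted on the training split only."""

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: str = ""

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "fitted_on": self.fitted_on,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(np.asarray(d["mean"]), np.asarray(d["sd"]), d.get("fitted_on", ""))


def fit_normalizer(features: np.ndarray | pd.DataFrame, fitted_on: str = "") -> NormStats:
    """Per-feature mean and (population) standard deviation of the training set."""
    X = _as_matrix(features)
    if len(X) < 2:
        raise ValueError("need >= 2 training segments to fit the normalizer")
    return NormStats(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=0), fitted_on=fitted_on)


def apply_normalizer(
    features: np.ndarray | pd.DataFrame, stats: NormStats
) -> np.ndarray:
    """(x - mean)/sd with the fitted statistics; zero-variance features map to 0."""
    X = _as_matrix(features)
    sd = np.where(stats.sd > 0, stats.sd, 1.0)
    out = (X - stats.mean) / sd
    out[:, stats.sd == 0] = 0.0
    return out


def _as_matrix(features: np.ndarray | pd.DataFrame) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[FEATURE_NAMES].to_numpy(dtype=float)
    return np.asarray(features, dtype=float)
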