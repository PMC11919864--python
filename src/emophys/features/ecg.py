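"""R-peak detection and heart-rate-variability features.

The detector follows the classic Pan-Tompkins recipe: 5-15 Hz bandpass to
emphasise the QRS complex, differentiation, squaring, 150 ms moving-window
integration, then peak picking with an adaptive amplitude threshold and a
200 ms refractory period, with each peak refined to the local ECG maximum.
It is fully deterministic.

From the resulting RR series (ms) we compute the standard HRV panel:

* time domain — mean RR, heart rate (60000/meanRR bpm), SDNN, RMSSD, NN50,
  pNN50;
* Poincare plot — SD1 = sqrt(Var(dRR)/2) (short-term) and
  SD2 = sqrt(2 SDNN^2 - SD1^2) (long-term), population variances so that
  SD1^2 + SD2^2 = 2 SDNN^2 exactly;
* frequency domain — VLF/LF/HF power (ms^2) of the 4 Hz cubic-resampled
  tachogram over the Task-Force bands 0.0033-0.04 / 0.04-0.15 / 0.15-0.4 Hz
  plus the LF/HF sympathovagal ratio. On 30 s windows the VLF band has
  essentially no support and is flagged unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.interpolate as spi
import scipy.signal as sps

from ..preprocess import Segment

__all__ = [
    "RRSeries",
    "HRVBandSpec",
    "ECGFeatureSpec",
    "InsufficientBeatsError",
    "detect_r_peaks",
    "hrv_time",
    "poincare",
    "hrv_freq",
    "ecg_feature_vector",
    "ECG_FULL_FAMILIES",
    "ECG_SELECTED_FAMILIES",
]

logger = logging.getLogger(__name__)

ECG_FULL_FAMILIES = [
    "mean_rr", "heart_rate", "sdnn", "rmssd", "nn50", "pnn50",
    "sd1", "sd2", "vlf", "lf", "hf", "lf_hf",
]

#: The 5-family post-selection ECG set (importance-ranked HRV rows).
ECG_SELECTED_FAMILIES = ["mean_rr", "heart_rate", "vlf", "sd2", "sdnn"]


class InsufficientBeatsError(ValueError):
    """Raised when too few heartbeats are detected to form an RR series."""


@dataclass
class HRVBandSpec:
    """Task-Force HRV spectral bands (Hz)."""

    vlf: tuple[float, float] = (0.0033, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)
    resample_hz: float = 4.0


@dataclass
class ECGFeatureSpec:
    rr_gate_ms: tuple[float, float] = (300.0, 2000.0)
    bands: HRVBandSpec = field(default_factory=HRVBandSpec)
    families: list[str] | None = None  # None -> full set


@dataclass
class RRSeries:
    """Ordered R-peak times (s) and the successive RR intervals (ms)."""

    peak_times: np.ndarray
    channel: str | None = None
    segment_id: str | None = None

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if len(self.peak_times) >= 2 and not (np.diff(self.peak_times) > 0).all():
            raise ValueError("peak times must be strictly increasing")

    @property
    def rr(self) -> np.ndarray:
        """Successive RR intervals in milliseconds."""
        return np.diff(self.peak_times) * 1000.0

    def gated(self, gate_ms: tuple[float, float] = (300.0, 2000.0)) -> "RRSeries":
        """Drop beats creating RR intervals outside the physiologic gate."""
        lo, hi = gate_ms
        times = list(self.peak_times[:1])
        dropped = 0
        for t in self.peak_times[1:]:
            dt = (t - times[-1]) * 1000.0
            if lo <= dt <= hi:
                times.append(t)
            else:
                dropped += 1
        if dropped:
            logger.info("RR gate [%g, %g] ms dropped %d beats", lo, hi, dropped)
        return RRSeries(np.asarray(times), self.channel, self.segment_id)

    def shifted(self, dt: float) -> "RRSeries":
        return RRSeries(self.peak_times + dt, self.channel, self.segment_id)


def detect_r_peaks(x: np.ndarray, rate: float, channel: str | None = None) -> RRSeries:
    """Locate R-peaks in one ECG channel (Pan-Tompkins-style)."""
    x = np.asarray(x, dtype=float)
    if rate < 100:
        raise ValueError(f"sampling rate {rate} Hz too low for QRS detection")
    if len(x) < rate:
        raise InsufficientBeatsError("segment shorter than 1 s")
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=rate, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(filt)
    squared = deriv**2
    win = max(1, int(round(0.150 * rate)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")
    peak_level = float(np.percentile(integrated, 98))
    if peak_level <= 0 or not np.isfinite(peak_level):
        raise InsufficientBeatsError("no QRS energy found (flat or degenerate signal)")
    threshold = 0.25 * peak_level
    refractory = int(round(0.200 * rate))
    locs, _ = sps.find_peaks(integrated, height=threshold, distance=refractory)
    # refine each detection to the local maximum of the QRS-band signal
    half = int(round(0.050 * rate))
    refined = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(len(x), loc + half + 1)
        refined.append(lo + int(np.argmax(filt[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory period after refinement
    kept: list[int] = []
    for r in refined:
        if not kept or r - kept[-1] >= refractory:
            kept.append(r)
        elif filt[r] > filt[kept[-1]]:
            kept[-1] = r
    if len(kept) < 3:
        raise InsufficientBeatsError(f"only {len(kept)} beats detected; need >= 3")
    return RRSeries(np.asarray(kept, dtype=float) / rate, channel=channel)


def _require_beats(rr: np.ndarray, minimum: int) -> None:
    if len(rr) < minimum:
        raise InsufficientBeatsError(f"need >= {minimum} RR intervals, got {len(rr)}")


def hrv_time(series: RRSeries) -> dict[str, float]:
    """Time-domain HRV panel from an RR series."""
    rr = series.rr
    _require_beats(rr, 3)
    drr = np.diff(rr)
    mean_rr = float(np.mean(rr))
    nn50 = int(np.count_nonzero(np.abs(drr) > 50.0))
    return {
        "mean_rr": mean_rr,
        "heart_rate": 60000.0 / mean_rr,
        "sdnn": float(np.std(rr)),
        "rmssd": float(np.sqrt(np.mean(drr**2))) if len(drr) else 0.0,
        "nn50": float(nn50),
        "pnn50": nn50 / len(drr) if len(drr) else 0.0,
    }


def poincare(series: RRSeries) -> tuple[float, float]:
    """Poincare ellipse axes (SD1, SD2) in ms."""
    rr = series.rr
    _require_beats(rr, 3)
    drr = np.diff(rr)
    sd1_sq = float(np.var(drr)) / 2.0
    sdnn_sq = float(np.var(rr))
    sd2_sq = 2.0 * sdnn_sq - sd1_sq
    if sd2_sq < 0:
        logger.warning("SD2^2 numerically negative (%g); clamped to 0", sd2_sq)
        sd2_sq = 0.0
    return float(np.sqrt(sd1_sq)), float(np.sqrt(sd2_sq))


def hrv_freq(series: RRSeries, bands: HRVBandSpec | None = None) -> dict[str, float]:
    """Spectral HRV: VLF/LF/HF power (ms^2) and the LF/HF ratio.

    The irregularly sampled tachogram is cubic-interpolated onto a uniform
    ``resample_hz`` grid, mean-removed, and a periodogram-style Welch PSD is
    integrated over each band. ``lf_hf`` is NaN when HF is zero.
    """
    bands = bands or HRVBandSpec()
    rr = series.rr
    _require_beats(rr, 4)
    t = series.peak_times[1:]  # each RR value sits at its ending beat
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("degenerate RR series")
    grid = np.arange(t[0], t[-1], 1.0 / bands.resample_hz)
    kind = "cubic" if len(rr) >= 4 else "linear"
    tach = spi.interp1d(t, rr, kind=kind)(grid)
    tach = tach - np.mean(tach)
    nper = len(tach)
    freqs, psd = sps.welch(tach, fs=bands.resample_hz, window="hann", nperseg=nper, noverlap=0)

    def power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(psd[mask], freqs[mask])) if mask.sum() > 1 else 0.0

    vlf = power(*bands.vlf)
    lf = power(*bands.lf)
    hf = power(*bands.hf)
    return {
        "vlf": vlf,
        "lf": lf,
        "hf": hf,
        "lf_hf": lf / hf if hf > 0 else float("nan"),
    }


def ecg_feature_vector(segment: Segment, spec: ECGFeatureSpec | None = None) -> pd.Series:
    """All configured HRV features of one ECG segment, channel-major.

    Channels on which detection fails ("insufficient beats") yield NaNs,
    which the selection stage imputes; names follow ``<channel>.<family>``.
    """
    spec = spec or ECGFeatureSpec()
    if segment.modality != "ECG":
        raise ValueError(f"expected an ECG segment, got {segment.modality}")
    families = spec.families or ECG_FULL_FAMILIES
    values: dict[str, float] = {}
    for ch_idx, ch in enumerate(segment.channel_names):
        try:
            series = detect_r_peaks(segment.data[ch_idx], segment.rate, channel=ch)
            series = series.gated(spec.rr_gate_ms)
            feats: dict[str, float] = {}
            feats.update(hrv_time(series))
            sd1, sd2 = poincare(series)
            feats["sd1"], feats["sd2"] = sd1, sd2
            feats.update(hrv_freq(series, spec.bands))
        except (InsufficientBeatsError, ValueError) as exc:
            logger.warning("HRV failed on %s/%s: %s", segment.segment_id, ch, exc)
            feats = {fam: float("nan") for fam in ECG_FULL_FAMILIES}
        for fam in families:
            values[f"{ch}.{fam}"] = feats[fam]
    return pd.Series(values, name=segment.segment_id)
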