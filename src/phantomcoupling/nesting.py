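"""Theta-gamma nesting: percent of time the windowed correlation between
the theta current and the gamma Hilbert envelope exceeds a threshold.

Per region of interest the procedure is: band-pass the 3-component
current in the theta (4-7.5 Hz) and gamma (30.5-44 Hz) bands; reduce each
band to its first principal component over the whole recording; take the
Hilbert envelope of the gamma component; correlate the theta component
with that envelope in 1-s windows (Pearson r); report the percentage of
windows with r >= 0.15. With 180 one-second windows (3 min of clean EEG)
0.15 is the two-sided 5% critical value of r — the threshold's published
rationale. Note the windows are 1 s of band-limited, hence autocorrelated,
data, so the effective per-window sample size is smaller than the sample
count; the published definition is kept as is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .inverse import ROITimeSeries
from .preprocess import bandpass_array


@dataclass(frozen=True)
class NestingParams:
    theta_band: tuple[float, float] = (4.0, 7.5)
    gamma_band: tuple[float, float] = (30.5, 44.0)
    window_s: float = 1.0
    hop: int | None = None  # samples between window starts; None = window length
    threshold_r: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_r < 1.0):
            raise ValueError("threshold_r must be in (0, 1)")
        if self.hop is not None and self.hop < 1:
            raise ValueError("hop must be >= 1 sample")

    def window_samples(self, rate_hz: float) -> int:
        w = self.window_s * rate_hz
        if abs(w - round(w)) > 1e-9:
            raise ValueError("window_s * rate_hz must be an integer")
        w = int(round(w))
        if w < 3:
            raise ValueError("window must span at least 3 samples")
        return w


@dataclass
class NestingResult:
    """Windowed correlation series and the percent-time summary.

    ``r_series`` may contain NaN for windows where either input had zero
    variance; those are excluded from ``percent_time``'s denominator.
    """

    r_series: np.ndarray
    percent_time: float
    n_windows: int
    params: NestingParams


def first_principal_component(roi_ts: ROITimeSeries | np.ndarray) -> np.ndarray:
    """Project the 3-component current onto its leading eigenvector.

    The eigenvector of the 3x3 time-domain covariance with the largest
    eigenvalue; sign fixed so the loading of largest magnitude is positive
    (equivalently, the component correlates positively with its
    dominant input axis), making the output deterministic.
    """
    x = roi_ts.data if isinstance(roi_ts, ROITimeSeries) else np.asarray(roi_ts, float)
    if x.ndim != 2 or x.shape[0] != 3 or x.shape[1] < 3:
        raise ValueError("input must be 3 x T with T >= 3")
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc @ xc.T / x.shape[1]
    if not np.any(np.diag(cov) > 0):
        raise ValueError("zero-variance input")
    w, V = np.linalg.eigh(cov)
    vec = V[:, -1]
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    return vec @ xc


def hilbert_envelope(signal: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (instantaneous amplitude)."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size < 8:
        raise ValueError("signal must be 1-D with length >= 8")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    return np.abs(hilbert(signal))


def windowed_correlation(
    theta_sig: np.ndarray,
    gamma_env: np.ndarray,
    params: NestingParams,
    rate_hz: float,
) -> np.ndarray:
    """Pearson r in windows of ``window_s`` seconds advanced by ``hop``.

    Windows where either input is constant have undefined correlation and
    are returned as NaN.
    """
    theta_sig = np.asarray(theta_sig, dtype=float)
    gamma_env = np.asarray(gamma_env, dtype=float)
    if theta_sig.shape != gamma_env.shape or theta_sig.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    win = params.window_samples(rate_hz)
    if theta_sig.size < win:
        raise ValueError("signals shorter than one window")
    hop = params.hop if params.hop is not None else win
    starts = np.arange(0, theta_sig.size - win + 1, hop)
    # strided window view; vectorized per-window Pearson
    tw = np.lib.stride_tricks.sliding_window_view(theta_sig, win)[starts]
    gw = np.lib.stride_tricks.sliding_window_view(gamma_env, win)[starts]
    tc = tw - tw.mean(axis=1, keepdims=True)
    gc = gw - gw.mean(axis=1, keepdims=True)
    st = np.sqrt(np.sum(tc**2, axis=1))
    sg = np.sqrt(np.sum(gc**2, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sum(tc * gc, axis=1) / (st * sg)
    r[(st == 0) | (sg == 0)] = np.nan
    return np.clip(r, -1.0, 1.0)  # clip propagates NaN


def nesting_percent_time(r_series: np.ndarray, threshold_r: float = 0.15) -> float:
    """100 x fraction of defined windows with r >= threshold (one-sided,
    inclusive)."""
    r = np.asarray(r_series, dtype=float)
    defined = ~np.isnan(r)
    if not np.any(defined):
        raise ValueError("all windows undefined")
    return float(100.0 * np.mean(r[defined] >= threshold_r))


def theta_gamma_nesting(
    roi_ts: ROITimeSeries,
    params: NestingParams | None = None,
) -> NestingResult:
    """Full nesting statistic for one region.

    Steps, in order: band-pass both bands on the 3 x T current; first
    principal component per band (over the whole recording); Hilbert
    envelope of the gamma component; windowed Pearson correlation; percent
    time above threshold.
    """
    params = params or NestingParams()
    rate = roi_ts.rate_hz
    theta3 = bandpass_array(roi_ts.data, *params.theta_band, rate_hz=rate)
    gamma3 = bandpass_array(roi_ts.data, *params.gamma_band, rate_hz=rate)
    theta1 = first_principal_component(theta3)
    gamma1 = first_principal_component(gamma3)
    env = hilbert_envelope(gamma1)
    r = windowed_correlation(theta1, env, params, rate)
    pct = nesting_percent_time(r, params.threshold_r)
    return NestingResult(
        r_series=r,
        percent_time=pct,
        n_windows=int(np.sum(~np.isnan(r))),
        params=params,
    )
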