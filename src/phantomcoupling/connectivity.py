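"""Lagged (noninstantaneous) phase synchronization between ROI series.

Volume conduction mixes sources into sensors (and leaks between source
estimates) with zero lag, which inflates any naive coupling measure. The
lagged measure used here is built from band coherency c:

    lagged = Im(c)^2 / (1 - Re(c)^2)

Instantaneous (zero-lag) dependence contributes only to Re(c), so the
statistic is insensitive to it; a quarter-period lag at the band center
drives the value toward 1. Two variants are supported: ``phase``
(per-epoch Fourier coefficients normalized to unit modulus before
averaging — amplitude-blind) and ``linear`` (ordinary coherency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .preprocess import BandScheme, band_bins

VARIANTS = ("phase", "linear")


@dataclass
class ConnectivityResult:
    """Long-format lagged synchronization values per band and ROI pair."""

    table: pd.DataFrame  # columns: band, roi_a, roi_b, value, variant, n_epochs

    def value(self, band: str, roi_a: str, roi_b: str) -> float:
        a, b = sorted((roi_a, roi_b))
        t = self.table
        row = t[(t.band == band) & (t.roi_a == a) & (t.roi_b == b)]
        if row.empty:
            raise KeyError((band, roi_a, roi_b))
        return float(row.value.iloc[0])


def _band_coeffs(epochs: np.ndarray, rate_hz: float, band: str, scheme: BandScheme):
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 2 or epochs.shape[0] < 2:
        raise ValueError("need >= 2 epochs of shape n_epochs x n_samples")
    n_s = epochs.shape[1]
    idx = band_bins(n_s, rate_hz, scheme)[band]
    if idx.size == 0:
        raise ValueError(f"band {band} has no DFT bins at this rate/epoch length")
    window = np.hanning(n_s)
    return np.fft.rfft(epochs * window, axis=1)[:, idx]


def band_coherency(
    x_epochs: np.ndarray,
    y_epochs: np.ndarray,
    band: str,
    rate_hz: float,
    variant: str = "phase",
    scheme: BandScheme | None = None,
) -> complex:
    """Complex coherency between two epoch sets in one frequency band.

    Cross- and auto-products are averaged over epochs and over the band's
    DFT bins. For ``variant="phase"`` every coefficient is first scaled to
    unit modulus, making the statistic depend on phase differences only.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    scheme = scheme or BandScheme()
    X = _band_coeffs(x_epochs, rate_hz, band, scheme)
    Y = _band_coeffs(y_epochs, rate_hz, band, scheme)
    if X.shape != Y.shape:
        raise ValueError("x and y epoch sets differ in shape")
    if variant == "phase":
        ax, ay = np.abs(X), np.abs(Y)
        if np.any(ax == 0) or np.any(ay == 0):
            raise ZeroDivisionError("zero Fourier coefficient in phase variant")
        X, Y = X / ax, Y / ay
    sxx = float(np.mean(np.abs(X) ** 2))
    syy = float(np.mean(np.abs(Y) ** 2))
    if sxx == 0 or syy == 0:
        raise ZeroDivisionError("zero auto-power in band")
    sxy = complex(np.mean(X * np.conj(Y)))
    return sxy / np.sqrt(sxx * syy)


def lagged_phase_sync(
    x_epochs: np.ndarray,
    y_epochs: np.ndarray,
    band: str,
    rate_hz: float,
    variant: str = "phase",
    scheme: BandScheme | None = None,
) -> float:
    """Im(c)^2 / (1 - Re(c)^2) on the band coherency c, in [0, 1].

    Zero for purely instantaneous dependence (in expectation). Degenerate
    identical signals (Re(c) = +/-1) are defined as 0 with a warning.
    """
    c = band_coherency(x_epochs, y_epochs, band, rate_hz, variant, scheme)
    re2 = c.real**2
    if re2 >= 1.0 - 1e-12:
        warnings.warn(
            "coherency real part is +/-1 (identical signals up to scale); "
            "lagged synchronization defined as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.clip(c.imag**2 / (1.0 - re2), 0.0, 1.0))


def connectivity_table(
    roi_epochs: dict[str, np.ndarray],
    rate_hz: float,
    bands: tuple[str, ...] | None = None,
    variant: str = "phase",
    scheme: BandScheme | None = None,
) -> ConnectivityResult:
    """Lagged synchronization for every ROI pair and band.

    ``roi_epochs`` maps ROI name to an n_epochs x n_samples array (e.g.
    the epoched first principal component or a single current component).
    """
    scheme = scheme or BandScheme()
    bands = bands or scheme.names
    rows = []
    for roi_a, roi_b in combinations(sorted(roi_epochs), 2):
        n_ep = np.asarray(roi_epochs[roi_a]).shape[0]
        for band in bands:
            v = lagged_phase_sync(
                roi_epochs[roi_a], roi_epochs[roi_b], band, rate_hz, variant, scheme
            )
            rows.append(
                {
                    "band": band,
                    "roi_a": roi_a,
                    "roi_b": roi_b,
                    "value": v,
                    "variant": variant,
                    "n_epochs": n_ep,
                }
            )
    return ConnectivityResult(table=pd.DataFrame(rows))
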