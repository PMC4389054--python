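"""Sensor-space conditioning and band-wise cross-spectral estimation.

The processing chain mirrors a standard resting-state EEG pipeline:
band-pass 2-44 Hz, resample to 128 Hz, common-average reference,
amplitude-based epoch rejection, then averaged Fourier cross-spectral
matrices per frequency band (delta through gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

#: 19-electrode 10-20 montage, in recording order.
MONTAGE_10_20 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

#: Offline analysis band, Hz.
ANALYSIS_BAND = (2.0, 44.0)

#: Analysis sampling rate after resampling, Hz.
ANALYSIS_RATE = 128.0

#: Epoch length used for cross-spectra and connectivity, seconds.
EPOCH_SECONDS = 2.0

#: Amplitude criterion for automated artifact rejection (same units as data).
DEFAULT_AMP_THRESHOLD = 100e-6


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples.

    ``reference_state`` is ``"raw"`` until a common-average reference is
    applied, then ``"common-average"``.
    """

    data: np.ndarray
    rate_hz: float
    channel_labels: tuple[str, ...] = MONTAGE_10_20
    reference_state: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands with inclusive bounds in Hz.

    Defaults are the six resting-state bands spanning the 2-44 Hz
    analysis range: delta 2-3.5, theta 4-7.5, alpha 8-12, low beta
    13-21, high beta 21.5-30, gamma 30.5-44.
    """

    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 2.0, 3.5),
        ("theta", 4.0, 7.5),
        ("alpha", 8.0, 12.0),
        ("low_beta", 13.0, 21.0),
        ("high_beta", 21.5, 30.0),
        ("gamma", 30.5, 44.0),
    )

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for name, lo, hi in self.bands:
            if not (lo < hi):
                raise ValueError(f"band {name}: need low < high")
            if lo <= prev_hi:
                raise ValueError(f"band {name} overlaps or is out of order")
            prev_hi = hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def bounds(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return lo, hi
        raise KeyError(name)

    def band_of(self, freq_hz: float) -> str | None:
        """First band whose closed interval contains ``freq_hz``, else None."""
        for n, lo, hi in self.bands:
            if lo <= freq_hz <= hi:
                return n
        return None


@dataclass
class BandCrossSpectra:
    """Per-band Hermitian channels x channels cross-spectral matrices."""

    matrices: dict[str, np.ndarray]
    n_epochs: int
    channel_labels: tuple[str, ...]

    def power(self, band: str) -> np.ndarray:
        """Per-channel band power (the real diagonal)."""
        return np.real(np.diag(self.matrices[band]))


# ---------------------------------------------------------------------------
# filtering / resampling / referencing


def _butter_bandpass_sos(low_hz: float, high_hz: float, rate_hz: float, order: int = 4):
    nyq = rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"invalid corner frequencies ({low_hz}, {high_hz}) at rate {rate_hz}"
        )
    return signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")


def bandpass(rec: EEGRecording, low_hz: float, high_hz: float) -> EEGRecording:
    """Zero-phase band-pass (forward-backward 4th-order Butterworth).

    The double pass squares the magnitude response: ~48 dB/octave roll-off
    outside the edges and no phase distortion in the passband.
    """
    sos = _butter_bandpass_sos(low_hz, high_hz, rec.rate_hz)
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def bandpass_array(x: np.ndarray, low_hz: float, high_hz: float, rate_hz: float) -> np.ndarray:
    """Zero-phase band-pass of a plain array along its last axis."""
    sos = _butter_bandpass_sos(low_hz, high_hz, rate_hz)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def resample(rec: EEGRecording, target_hz: float) -> EEGRecording:
    """Anti-aliased rational resampling to ``target_hz`` (downsampling only)."""
    if target_hz > rec.rate_hz:
        raise ValueError("upsampling not supported")
    if target_hz == rec.rate_hz:
        return replace(rec)
    frac = Fraction(target_hz / rec.rate_hz).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=out, rate_hz=rec.rate_hz * frac.numerator / frac.denominator)


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the per-sample channel mean. Idempotent."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=out, reference_state="common-average")


# ---------------------------------------------------------------------------
# epoching


def reject_artifacts(
    rec: EEGRecording,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    epoch_s: float = EPOCH_SECONDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Split into non-overlapping epochs and drop any containing a sample
    with ``|value| > amp_threshold``.

    Returns ``(epochs, keep_mask)`` where ``epochs`` is
    kept_epochs x channels x samples and ``keep_mask`` is a boolean over
    all candidate epochs (True = kept).
    """
    if not amp_threshold > 0:
        raise ValueError("amp_threshold must be positive")
    win = epoch_s * rec.rate_hz
    if abs(win - round(win)) > 1e-9:
        raise ValueError("epoch_s * rate_hz must be an integer")
    win = int(round(win))
    n_epochs = rec.n_samples // win
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    cut = rec.data[:, : n_epochs * win]
    epochs = cut.reshape(rec.n_channels, n_epochs, win).transpose(1, 0, 2)
    keep = ~(np.abs(epochs) > amp_threshold).any(axis=(1, 2))
    return epochs[keep], keep


def epoch_array(x: np.ndarray, rate_hz: float, epoch_s: float = EPOCH_SECONDS) -> np.ndarray:
    """Cut a 1-D series into non-overlapping epochs (n_epochs x samples)."""
    x = np.asarray(x, dtype=float)
    win = int(round(epoch_s * rate_hz))
    n = x.shape[-1] // win
    return x[..., : n * win].reshape(*x.shape[:-1], n, win)


# ---------------------------------------------------------------------------
# cross-spectra


def band_bins(n_fft: int, rate_hz: float, scheme: BandScheme) -> dict[str, np.ndarray]:
    """DFT bin indices per band; a bin belongs to the first band whose closed
    interval contains its center frequency."""
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate_hz)
    out: dict[str, list[int]] = {name: [] for name in scheme.names}
    for i, f in enumerate(freqs):
        b = scheme.band_of(f)
        if b is not None:
            out[b].append(i)
    return {k: np.asarray(v, dtype=int) for k, v in out.items()}


def cross_spectra(
    epochs: np.ndarray,
    rate_hz: float,
    scheme: BandScheme | None = None,
) -> BandCrossSpectra:
    """Averaged Fourier cross-spectral matrices per frequency band.

    ``epochs`` is n_epochs x channels x samples. Each epoch is Hann-windowed
    and Fourier-transformed; cross-products are averaged over epochs and over
    the DFT bins inside each band. Matrices are Hermitian positive
    semidefinite by construction, scaled so the diagonal integrates power
    density (variance is approximately recovered by summing bands).
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise ValueError("need at least one epoch of shape channels x samples")
    scheme = scheme or BandScheme()
    n_ep, n_ch, n_s = epochs.shape
    window = np.hanning(n_s)
    # normalize so that band powers sum to the signal variance (Welch scaling)
    norm = 1.0 / (n_s * (window @ window))
    coeffs = np.fft.rfft(epochs * window, axis=2)  # n_ep x n_ch x n_bins
    bins = band_bins(n_s, rate_hz, scheme)
    matrices: dict[str, np.ndarray] = {}
    for name, idx in bins.items():
        if idx.size == 0:
            raise ValueError(f"band {name} has no DFT bins at this rate/epoch length")
        c = coeffs[:, :, idx]  # n_ep x n_ch x n_bins_in_band
        # one-sided spectrum: double non-DC/non-Nyquist bins
        scale = np.where((idx == 0) | (idx == (n_s // 2 if n_s % 2 == 0 else -1)), 1.0, 2.0)
        m = np.einsum("eif,ejf,f->ij", c, np.conj(c), scale) * norm / n_ep
        matrices[name] = 0.5 * (m + m.conj().T)
    labels = tuple(f"ch{i}" for i in range(n_ch))
    return BandCrossSpectra(matrices=matrices, n_epochs=n_ep, channel_labels=labels)


def band_coherency_matrix(csd: BandCrossSpectra, band: str) -> np.ndarray:
    """Complex coherency matrix for one band."""
    m = csd.matrices[band]
    d = np.sqrt(np.real(np.diag(m)))
    with np.errstate(divide="ignore", invalid="ignore"):
        return m / np.outer(d, d)


# ---------------------------------------------------------------------------
# file input


def read_recording(path, rate_hz: float | None = None) -> EEGRecording:
    """Read an EEG recording from disk.

    ``.edf`` files are read through mne (optional dependency); anything
    else is parsed as delimited samples x channels text, optionally with a
    ``# rate_hz=... channels=...`` header line (otherwise ``rate_hz`` must
    be given and channels default to the 10-20 montage order).
    """
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return EEGRecording(
            data=raw.get_data(),
            rate_hz=float(raw.info["sfreq"]),
            channel_labels=tuple(raw.ch_names),
        )
    labels: tuple[str, ...] | None = None
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            key, _, val = token.partition("=")
            if key == "rate_hz":
                rate_hz = float(val)
            elif key == "channels":
                labels = tuple(val.split(","))
    if rate_hz is None:
        raise ValueError(f"{path}: no rate_hz header; pass rate_hz explicitly")
    data = np.loadtxt(path, delimiter="\t", comments="#").T
    if data.ndim == 1:
        data = data[None, :]
    if labels is None:
        labels = MONTAGE_10_20[: data.shape[0]]
    return EEGRecording(data=data, rate_hz=rate_hz, channel_labels=labels)


def preprocess_recording(
    rec: EEGRecording,
    low_hz: float = ANALYSIS_BAND[0],
    high_hz: float = ANALYSIS_BAND[1],
    target_hz: float = ANALYSIS_RATE,
    amp_threshold: float | None = None,
    epoch_s: float = EPOCH_SECONDS,
) -> tuple[EEGRecording, np.ndarray, np.ndarray]:
    """Full sensor-space chain: filter -> resample -> reference -> epoch.

    Returns the preprocessed continuous recording, the kept epochs and the
    epoch keep-mask. ``amp_threshold=None`` keeps all epochs.
    """
    out = bandpass(rec, low_hz, high_hz)
    if target_hz < out.rate_hz:
        out = resample(out, target_hz)
    out = common_average_reference(out)
    thresh = amp_threshold if amp_threshold is not None else np.inf
    epochs, keep = reject_artifacts(out, thresh, epoch_s)
    # keep the continuous recording trimmed to the kept epochs' concatenation
    return out, epochs, keep
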