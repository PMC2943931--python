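"""EEG spectral epoch extraction and normalization.

Continuous EEG recorded during fMRI is segmented into fixed-length epochs
placed a hemodynamic lag ahead of each scan onset, transformed to amplitude
spectra, and normalized in two stages so that only the *relative* spatial
pattern of spectral fluctuations survives:

1. the mean amplitude over (valid) epochs is removed per channel and
   frequency bin, and
2. each (epoch, bin) channel vector is scaled to unit sample variance
   across channels.

Stage 1 centres the temporal dynamics; stage 2 discards global amplitude
so that downstream covariance maps reflect topography, not overall power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import rfft
from scipy.signal.windows import tukey

__all__ = [
    "EpochWindow",
    "SpectralEpochSet",
    "extract_epochs",
    "spectral_transform",
    "normalize_spectra",
]


@dataclass(frozen=True)
class EpochWindow:
    """Placement and size of the pre-scan EEG analysis window.

    The default places a 256-sample window at 100 Hz starting 6560 ms
    before each scan marker (i.e. spanning -6560 ms to -4000 ms), which
    accounts for the hemodynamic delay between neuronal activity and the
    BOLD response it drives.

    Attributes
    ----------
    start_offset_ms:
        Distance from the epoch start to the scan marker, in ms (> 0).
    n_samples:
        Epoch length in samples.
    rate:
        Sampling rate in Hz.
    """

    start_offset_ms: float = 6560.0
    n_samples: int = 256
    rate: float = 100.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not self.start_offset_ms > self.n_samples * 1000.0 / self.rate:
            raise ValueError(
                "window must fully precede the marker: start_offset_ms must "
                f"exceed the window duration {self.n_samples * 1000.0 / self.rate:g} ms"
            )

    @property
    def start_offset_samples(self) -> int:
        return int(round(self.start_offset_ms * self.rate / 1000.0))

    @property
    def resolution_hz(self) -> float:
        """DFT bin spacing, rate / n_samples."""
        return self.rate / self.n_samples


@dataclass
class SpectralEpochSet:
    """Per-subject tensor of EEG spectral amplitudes.

    Attributes
    ----------
    amplitudes:
        (epochs, channels, bins) array of spectral amplitudes.
    bin_freqs:
        Bin centre frequencies in Hz, strictly increasing, length = bins.
    channel_labels:
        Channel names, length = channels.
    valid:
        Boolean mask, one flag per epoch (aligned to scan volumes).
    normalized:
        True once :func:`normalize_spectra` has been applied.
    """

    amplitudes: np.ndarray
    bin_freqs: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    valid: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 3:
            raise ValueError("amplitudes must be (epochs, channels, bins)")
        self.bin_freqs = np.asarray(self.bin_freqs, dtype=float)
        if self.bin_freqs.shape != (self.amplitudes.shape[2],):
            raise ValueError("bin_freqs length must match the bin axis")
        if np.any(np.diff(self.bin_freqs) <= 0):
            raise ValueError("bin_freqs must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(self.amplitudes.shape[0], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (self.amplitudes.shape[0],):
                raise ValueError("valid mask length must match the epoch axis")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.amplitudes.shape[1])]

    @property
    def n_epochs(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_channels(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def n_bins(self) -> int:
        return self.amplitudes.shape[2]


def extract_epochs(
    signal: np.ndarray,
    markers: np.ndarray,
    window: EpochWindow = EpochWindow(),
    artifact_spans: list[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut one pre-marker epoch per scan onset out of continuous EEG.

    Epoch ``i`` starts ``round(start_offset_ms * rate / 1000)`` samples
    before ``markers[i]`` and spans ``n_samples`` samples.  Epochs that run
    off the start of the recording, past its end, or that overlap an
    artifact span are kept in place but flagged invalid, so the epoch axis
    stays aligned with the scan-volume axis.

    Parameters
    ----------
    signal:
        (channels, samples) continuous EEG at ``window.rate``.
    markers:
        Sorted scan-onset sample indices.
    artifact_spans:
        Half-open sample intervals ``(start, stop)`` to exclude.

    Returns
    -------
    epochs : (n_markers, channels, n_samples) array (invalid epochs zeroed)
    valid : boolean mask per epoch
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    markers = np.asarray(markers, dtype=int)
    if markers.ndim != 1:
        raise ValueError("markers must be a 1-D index array")
    if np.any(np.diff(markers) < 0):
        raise ValueError("markers must be sorted ascending")
    spans = [(int(a), int(b)) for a, b in (artifact_spans or [])]

    n_ch, n_samp = signal.shape
    off = window.start_offset_samples
    n = window.n_samples
    epochs = np.zeros((len(markers), n_ch, n), dtype=float)
    valid = np.zeros(len(markers), dtype=bool)
    for i, m in enumerate(markers):
        start = int(m) - off
        stop = start + n
        if start < 0 or stop > n_samp:
            continue
        if any(a < stop and b > start for a, b in spans):
            continue
        epochs[i] = signal[:, start:stop]
        valid[i] = True
    return epochs, valid


def _taper(n_samples: int, taper_fraction: float) -> np.ndarray:
    # "10% Hanning" taper: a cosine ramp over the first and last
    # `taper_fraction` of the epoch, flat in between (Tukey window).
    return tukey(n_samples, alpha=2.0 * taper_fraction, sym=False)


def retained_bins(
    window: EpochWindow,
    band: tuple[float, float] = (1.0, 30.0),
    convention: str = "count75",
) -> np.ndarray:
    """DFT harmonic numbers retained for analysis.

    With the default 256-sample / 100 Hz window the spacing is
    100/256 = 0.390625 Hz.  Under the ``"count75"`` convention harmonics
    k = 3..77 (centres 1.17-30.08 Hz) are kept, giving 75 bins across the
    nominal 1-30 Hz band; ``"closed_interval"`` keeps exactly the bins
    whose centres lie inside [low, high] (74 bins at the default sizes).
    """
    low, high = band
    res = window.resolution_hz
    nyquist = window.rate / 2.0
    if high > nyquist:
        raise ValueError(f"band upper edge {high} Hz exceeds Nyquist {nyquist} Hz")
    if convention == "count75":
        k_lo = int(np.floor(low / res)) + 1  # first harmonic strictly above `low`
        k_hi = int(np.floor(high / res)) + 1  # one harmonic past `high`
    elif convention == "closed_interval":
        k_lo = int(np.ceil(low / res))
        k_hi = int(np.floor(high / res))
    else:
        raise ValueError(f"unknown bin convention {convention!r}")
    return np.arange(k_lo, k_hi + 1)


def spectral_transform(
    epochs: np.ndarray,
    window: EpochWindow = EpochWindow(),
    band: tuple[float, float] = (1.0, 30.0),
    valid: np.ndarray | None = None,
    channel_labels: list[str] | None = None,
    taper_fraction: float = 0.10,
    convention: str = "count75",
) -> SpectralEpochSet:
    """Amplitude spectra of tapered epochs, restricted to the analysis band.

    Each epoch/channel is multiplied by a cosine taper covering the first
    and last ``taper_fraction`` of the samples, DFT-transformed, and the
    modulus is retained at the harmonics selected by :func:`retained_bins`.
    Amplitudes are raw DFT moduli (no 1/N or taper-gain correction): the
    downstream normalization cancels any global scale.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (epochs, channels, samples)")
    if epochs.shape[2] != window.n_samples:
        raise ValueError("epoch length does not match window.n_samples")
    ks = retained_bins(window, band, convention)
    tapered = epochs * _taper(window.n_samples, taper_fraction)
    spec = np.abs(rfft(tapered, axis=2))[:, :, ks]
    return SpectralEpochSet(
        amplitudes=spec,
        bin_freqs=ks * window.resolution_hz,
        channel_labels=channel_labels or [],
        valid=valid,
    )


def normalize_spectra(s: SpectralEpochSet) -> SpectralEpochSet:
    """Two-stage normalization of a spectral epoch set.

    Step 1 removes, per (channel, bin), the mean over *valid* epochs.
    Step 2 divides each (epoch, bin) channel vector by its sample SD
    (ddof=1) across channels; zero-SD vectors become all zero.  Invalid
    epochs are excluded from the step-1 mean and zeroed in the output.
    """
    if s.n_channels < 2:
        raise ValueError("need at least 2 channels to normalize across channels")
    valid = s.valid
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid epochs to normalize")
    amp = s.amplitudes.copy()
    amp -= amp[valid].mean(axis=0, keepdims=True)
    sd = amp.std(axis=1, ddof=1, keepdims=True)  # across channels
    degen = (sd == 0) | (np.ptp(amp, axis=1, keepdims=True) == 0)
    amp = np.where(degen, 0.0, amp / np.where(degen, 1.0, sd))
    amp[~valid] = 0.0
    return replace(s, amplitudes=amp, normalized=True)
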