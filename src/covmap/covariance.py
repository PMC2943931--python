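"""Covariance mapping of EEG spectral dynamics against RSN dynamics.

For each subject, the normalized spectral amplitude timecourse at every
electrode and frequency bin is dot-multiplied with the activity timecourse
of every network, giving a (subjects, RSNs, bins, channels) covariance
tensor — at full scale 20 x 10 x 75 x 92 values.  One-sample t statistics
across subjects ("t-maps") summarize the consistency of each electrode's
covariance, and bin-level maps are averaged into frequency bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import RSNDynamics, _one_sample_t
from .spectra import SpectralEpochSet

__all__ = [
    "CovarianceTensor",
    "TMapSet",
    "BandPartition",
    "REFERENCE_BANDS",
    "reference_bands",
    "covariance_map",
    "covariance_tensor",
    "tmap",
    "band_average",
]


@dataclass
class CovarianceTensor:
    """(subjects, RSNs, bins-or-bands, channels) covariance values.

    ``freq_labels`` holds bin centre frequencies (Hz, floats) at bin level
    or band names (strings) after band averaging.  ``n_valid_pairs`` stores
    per subject how many epoch/volume pairs entered the dot product, for
    optional rescaling — the covariance itself is the raw dot product.
    """

    values: np.ndarray
    freq_labels: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    rsn_labels: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)
    n_valid_pairs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be (subjects, RSNs, bins, channels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariance tensor contains non-finite values")
        self.freq_labels = np.asarray(self.freq_labels)
        if self.freq_labels.shape != (self.values.shape[2],):
            raise ValueError("freq_labels must match the frequency axis")
        if self.n_valid_pairs is None:
            self.n_valid_pairs = np.zeros(self.values.shape[0], dtype=int)
        if not self.rsn_labels:
            self.rsn_labels = [f"RSN{i + 1}" for i in range(self.values.shape[1])]
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.values.shape[3])]
        if not self.subject_ids:
            self.subject_ids = [f"sub{i + 1}" for i in range(self.values.shape[0])]

    @property
    def is_band_level(self) -> bool:
        return self.freq_labels.dtype.kind in "US"


@dataclass
class TMapSet:
    """One-sample t statistics of covariance values across subjects."""

    t: np.ndarray  # (RSNs, bins-or-bands, channels)
    n_subjects: int
    freq_labels: np.ndarray
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 3:
            raise ValueError("t must be (RSNs, bins, channels)")
        if self.n_subjects < 2:
            raise ValueError("t-maps need at least 2 subjects")
        self.freq_labels = np.asarray(self.freq_labels)

    @property
    def is_band_level(self) -> bool:
        return self.freq_labels.dtype.kind in "US"


@dataclass(frozen=True)
class BandPartition:
    """Ordered, contiguous grouping of frequency bins into named bands.

    ``bounds`` are the nominal (lower-exclusive, upper-inclusive) Hz limits
    per band; ``bin_slices`` give each band's member bins as a contiguous
    half-open index range.  Every retained bin belongs to exactly one band;
    the first/last band absorb bins just outside the nominal limits (the
    retained-bin convention can place the extreme bin centres slightly past
    the nominal band edges).
    """

    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    bin_slices: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.bounds) == len(self.bin_slices)):
            raise ValueError("names, bounds and bin_slices must align")
        stop_prev = None
        for (lo, hi), (a, b) in zip(self.bounds, self.bin_slices):
            if b <= a:
                raise ValueError("every band must contain at least one bin")
            if stop_prev is not None and a != stop_prev:
                raise ValueError("bands must be contiguous and non-overlapping")
            stop_prev = b
            if hi <= lo:
                raise ValueError("band upper bound must exceed lower bound")

    @classmethod
    def from_borders(
        cls,
        names: list[str],
        borders_hz: list[float],
        bin_freqs: np.ndarray,
        lo_hz: float = 1.0,
        hi_hz: float = 30.0,
    ) -> "BandPartition":
        """Build a partition from interior band borders.

        ``borders_hz`` lists the upper (inclusive) edge of every band but
        the last; a bin belongs to the first band whose border is >= its
        centre frequency.  The last band takes everything above the final
        border, so all retained bins are covered.
        """
        if len(names) != len(borders_hz) + 1:
            raise ValueError("need exactly one more name than interior borders")
        if sorted(borders_hz) != list(borders_hz):
            raise ValueError("borders must be ascending")
        bin_freqs = np.asarray(bin_freqs, dtype=float)
        edges = [-np.inf, *borders_hz, np.inf]
        slices = []
        start = 0
        for i in range(len(names)):
            stop = int(np.searchsorted(bin_freqs, edges[i + 1], side="right"))
            slices.append((start, stop))
            start = stop
        bounds = [
            (lo_hz if i == 0 else borders_hz[i - 1],
             hi_hz if i == len(names) - 1 else borders_hz[i])
            for i in range(len(names))
        ]
        return cls(tuple(names), tuple(bounds), tuple(slices))

    @property
    def n_bands(self) -> int:
        return len(self.names)

    def member_bins(self, band: int | str) -> np.ndarray:
        if isinstance(band, str):
            band = self.names.index(band)
        a, b = self.bin_slices[band]
        return np.arange(a, b)

    def labels(self, n_bins: int) -> np.ndarray:
        """Band index per bin (length ``n_bins``)."""
        if self.bin_slices[-1][1] != n_bins:
            raise ValueError("partition does not cover the requested bin count")
        out = np.empty(n_bins, dtype=int)
        for i, (a, b) in enumerate(self.bin_slices):
            out[a:b] = i
        return out


def reference_bands(bin_freqs: np.ndarray) -> BandPartition:
    """The canonical delta..beta3 partition of the 1-30 Hz range.

    Border constants (upper edges, Hz): delta 3.5, theta1 6.25, theta2 8.2,
    alpha1 10.5, alpha2 14.0, beta1 18.75, beta2 21.88, beta3 30.0.
    """
    names = ["delta", "theta1", "theta2", "alpha1", "alpha2", "beta1", "beta2", "beta3"]
    return BandPartition.from_borders(
        names, [3.5, 6.25, 8.2, 10.5, 14.0, 18.75, 21.88], bin_freqs
    )


#: Nominal (lower-exclusive, upper-inclusive) Hz limits of the canonical bands.
REFERENCE_BANDS = {
    "delta": (1.0, 3.5),
    "theta1": (3.5, 6.25),
    "theta2": (6.25, 8.2),
    "alpha1": (8.2, 10.5),
    "alpha2": (10.5, 14.0),
    "beta1": (14.0, 18.75),
    "beta2": (18.75, 21.88),
    "beta3": (21.88, 30.0),
}


def covariance_map(spectra: SpectralEpochSet, dynamics: RSNDynamics) -> np.ndarray:
    """One subject's covariance maps, (RSNs, bins, channels).

    cov(r, f, c) = sum over valid epoch/volume pairs t of
    amplitude(t, c, f) * activity(r, t) — a plain dot product over time,
    not scaled by the number of pairs.  Epoch i is paired with volume i;
    pairs whose epoch is invalid are dropped.
    """
    if not spectra.normalized:
        raise ValueError("spectra must be normalized before covariance mapping")
    if spectra.n_epochs != dynamics.n_volumes:
        raise ValueError(
            f"pairing undefined: {spectra.n_epochs} epochs vs "
            f"{dynamics.n_volumes} volumes"
        )
    valid = spectra.valid
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid epoch/volume pairs")
    amp = spectra.amplitudes[valid]  # (T, C, F)
    act = dynamics.activity[:, valid]  # (R, T)
    return np.einsum("tcf,rt->rfc", amp, act)


def covariance_tensor(
    spectra: list[SpectralEpochSet],
    dynamics: list[RSNDynamics],
    subject_ids: list[str] | None = None,
) -> CovarianceTensor:
    """Stack per-subject covariance maps into the full tensor."""
    if len(spectra) != len(dynamics) or not spectra:
        raise ValueError("need matching, non-empty spectra and dynamics lists")
    maps = [covariance_map(s, d) for s, d in zip(spectra, dynamics)]
    return CovarianceTensor(
        values=np.stack(maps),
        freq_labels=spectra[0].bin_freqs,
        channel_labels=spectra[0].channel_labels,
        rsn_labels=dynamics[0].rsn_labels,
        subject_ids=subject_ids or [],
        n_valid_pairs=np.array([int(s.valid.sum()) for s in spectra]),
    )


def tmap(cov: CovarianceTensor) -> TMapSet:
    """Electrode-wise one-sample t against zero across subjects.

    t = mean / (SD / sqrt(n)) per (RSN, bin/band, channel).  Degenerate
    cells (SD = 0) give t = 0 when the mean is also 0 and a flagged
    +/-1e12 sentinel otherwise.
    """
    if cov.values.shape[0] < 2:
        raise ValueError("t-maps need at least 2 subjects")
    t, degen = _one_sample_t(cov.values)
    return TMapSet(
        t=t, n_subjects=cov.values.shape[0], freq_labels=cov.freq_labels,
        degenerate=degen,
    )


def band_average(cov: CovarianceTensor, partition: BandPartition) -> CovarianceTensor:
    """Unweighted mean of bin-level maps within each band, per subject/RSN/channel."""
    if cov.is_band_level:
        raise ValueError("tensor is already band-level")
    partition.labels(cov.values.shape[2])  # validates coverage
    bands = np.stack(
        [cov.values[:, :, partition.member_bins(i), :].mean(axis=2)
         for i in range(partition.n_bands)],
        axis=2,
    )
    return CovarianceTensor(
        values=bands,
        freq_labels=np.array(partition.names),
        channel_labels=cov.channel_labels,
        rsn_labels=cov.rsn_labels,
        subject_ids=cov.subject_ids,
        n_valid_pairs=cov.n_valid_pairs,
    )
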