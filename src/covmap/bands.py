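"""Frequency-band discovery by k-means clustering of per-bin t-map topographies.

Each retained frequency bin is described by the concatenated t-values of
all networks at all electrodes (at full scale 10 RSNs x 92 channels = 920
values per bin).  K-means with Euclidean distance groups bins with similar
topographies; because scalp topography changes with frequency in a
band-like way, the clusters fall (approximately) on contiguous frequency
ranges, and their transitions define empirical band borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .covariance import BandPartition, TMapSet

__all__ = ["BinFeatureMatrix", "build_features", "cluster_bins", "sweep_k"]


@dataclass
class BinFeatureMatrix:
    """Rows = frequency bins, columns = t-values over (RSN, channel) pairs."""

    features: np.ndarray
    bin_freqs: np.ndarray
    n_rsns: int
    n_channels: int

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.bin_freqs = np.asarray(self.bin_freqs, dtype=float)
        if self.features.shape != (self.bin_freqs.size, self.n_rsns * self.n_channels):
            raise ValueError("feature matrix shape inconsistent with metadata")

    def to_tmaps(self) -> np.ndarray:
        """Reshape back to (RSNs, bins, channels)."""
        n_bins = self.features.shape[0]
        return (
            self.features.reshape(n_bins, self.n_rsns, self.n_channels)
            .transpose(1, 0, 2)
        )


def build_features(tmaps: TMapSet) -> BinFeatureMatrix:
    """Concatenate bin-level t-maps into per-bin feature vectors.

    Deterministic (RSN, channel) column order; rejects band-level input —
    clustering is only meaningful over individual frequency bins.
    """
    if tmaps.is_band_level:
        raise ValueError("band-level t-maps cannot be clustered into bands")
    n_rsns, n_bins, n_channels = tmaps.t.shape
    feats = tmaps.t.transpose(1, 0, 2).reshape(n_bins, n_rsns * n_channels)
    return BinFeatureMatrix(
        features=feats,
        bin_freqs=np.asarray(tmaps.freq_labels, dtype=float),
        n_rsns=n_rsns,
        n_channels=n_channels,
    )


def _median_smooth(labels: np.ndarray, width: int = 3) -> np.ndarray:
    # window-3 median over the (frequency-ordered) label sequence,
    # edge bins replicated; repairs isolated label flips
    half = width // 2
    padded = np.concatenate([labels[:1].repeat(half), labels, labels[-1:].repeat(half)])
    return np.array(
        [int(np.median(padded[i : i + width])) for i in range(labels.size)]
    )


def _fragmentation(labels: np.ndarray) -> float:
    """Fraction of bins outside their cluster's longest contiguous run."""
    frag = 0
    for lab in np.unique(labels):
        mask = labels == lab
        # run lengths of this label
        runs: list[int] = []
        count = 0
        for m in mask:
            if m:
                count += 1
            elif count:
                runs.append(count)
                count = 0
        if count:
            runs.append(count)
        frag += mask.sum() - max(runs)
    return frag / labels.size


@dataclass
class ClusterDiagnostics:
    raw_labels: np.ndarray
    smoothed_labels: np.ndarray
    inertia: float
    fragmentation: float


def cluster_bins(
    features: BinFeatureMatrix,
    k: int,
    n_restarts: int = 100,
    seed: int = 0,
) -> tuple[BandPartition, ClusterDiagnostics]:
    """Partition frequency bins into bands by k-means on their topographies.

    K-means (Euclidean distance, k-means++ initialization, best
    within-cluster sum of squares over ``n_restarts`` runs) labels every
    bin; labels are renumbered by ascending mean member frequency, a
    single window-3 median-smoothing pass repairs isolated non-contiguous
    assignments, and band borders are placed at the remaining label
    transitions.  The raw label sequence and a fragmentation score (the
    fraction of bins outside their cluster's longest run, before
    smoothing) are reported alongside.
    """
    n_bins = features.features.shape[0]
    if not 1 <= k <= n_bins:
        raise ValueError(f"k must be in [1, {n_bins}]")
    km = KMeans(
        n_clusters=k, n_init=n_restarts, init="k-means++", random_state=seed
    ).fit(features.features)
    raw = km.labels_.copy()

    # renumber by ascending mean member frequency
    order = np.argsort(
        [features.bin_freqs[raw == lab].mean() for lab in range(k)], kind="stable"
    )
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    raw = remap[raw]

    smoothed = _median_smooth(raw) if k > 1 else raw
    changes = np.flatnonzero(np.diff(smoothed)) + 1
    starts = [0, *changes.tolist()]
    stops = [*changes.tolist(), n_bins]

    freqs = features.bin_freqs
    names, bounds, slices = [], [], []
    for i, (a, b) in enumerate(zip(starts, stops)):
        names.append(f"band{i + 1}")
        spacing = float(np.median(np.diff(freqs))) if n_bins > 1 else 1.0
        lo = freqs[0] - spacing / 2.0 if a == 0 else (freqs[a - 1] + freqs[a]) / 2.0
        hi = freqs[-1] + spacing / 2.0 if b == n_bins else (freqs[b - 1] + freqs[b]) / 2.0
        bounds.append((float(lo), float(hi)))
        slices.append((a, b))
    partition = BandPartition(tuple(names), tuple(bounds), tuple(slices))
    diag = ClusterDiagnostics(
        raw_labels=raw,
        smoothed_labels=smoothed,
        inertia=float(km.inertia_),
        fragmentation=_fragmentation(raw),
    )
    return partition, diag


def sweep_k(
    features: BinFeatureMatrix,
    k_range,
    n_restarts: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Inertia and fragmentation for a range of cluster counts.

    No automatic selection is performed: the caller inspects the table and
    picks k (the band count used elsewhere defaults to 8, matching the
    conventional delta..beta3 division).
    """
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("k_range must be non-empty")
    rows = []
    for k in ks:
        partition, diag = cluster_bins(features, k, n_restarts=n_restarts, seed=seed)
        rows.append(
            {
                "k": k,
                "inertia": diag.inertia,
                "fragmentation": diag.fragmentation,
                "n_bands": partition.n_bands,
            }
        )
    return pd.DataFrame(rows)
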