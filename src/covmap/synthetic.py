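"""Seeded generator of coupled EEG-spectra / RSN-dynamics datasets.

No raw recordings accompany the analysis this package implements, so every
stage is exercised on synthetic data with planted, known coupling
structure.  The generator emulates the study conditions: 20 subjects,
252 volumes at TR 1.98 s, 10 network timecourses per subject, 92 scalp
channels and 75 spectral bins spanning 1-30 Hz.  For each (network, band)
pair a fixed electrode topography is modulated by that network's activity
and buried in i.i.d. Gaussian noise; the downstream pipeline should then
recover the planted topographies, band borders and significance structure.

The generator works directly at the spectral level (one epoch per volume);
it does not simulate raw time-domain EEG, scanner artifacts or a
biophysical forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import BandPartition, reference_bands
from .dynamics import RSNDynamics, SpatialMap
from .spectra import EpochWindow, SpectralEpochSet, retained_bins

__all__ = [
    "CouplingSpec",
    "GroundTruth",
    "default_bin_freqs",
    "smooth_topographies",
    "default_coupling",
    "generate_rsn_dynamics",
    "generate_spectra",
    "generate_templates",
    "generate_bold",
    "generate_subject_ic_maps",
    "noise_sd_for_similarity",
]

#: Study-scale defaults: subjects, volumes, RSNs, channels, bins, TR (s).
DEFAULT_SHAPE = dict(
    n_subjects=20, n_volumes=252, n_rsns=10, n_channels=92, n_bins=75, tr=1.98
)


def default_bin_freqs(n_bins: int = 75) -> np.ndarray:
    """Bin centre frequencies of the default spectral convention (Hz)."""
    w = EpochWindow()
    freqs = retained_bins(w) * w.resolution_hz
    if n_bins != freqs.size:
        raise ValueError(f"default convention yields {freqs.size} bins, not {n_bins}")
    return freqs


@dataclass
class CouplingSpec:
    """Planted coupling between network dynamics and spectral topographies.

    Attributes
    ----------
    strengths:
        (RSNs, bands) coupling strength scalars (unitless; 0 = no coupling).
    topographies:
        (RSNs, bands, channels) electrode weight patterns, unit RMS.
    band_bins:
        Per band, the retained-bin indices it comprises (contiguous,
        non-overlapping, jointly exhaustive).
    noise_sd:
        SD of the i.i.d. Gaussian noise added to every (epoch, channel,
        bin) amplitude.
    """

    strengths: np.ndarray
    topographies: np.ndarray
    band_bins: list[np.ndarray]
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        self.topographies = np.asarray(self.topographies, dtype=float)
        if self.strengths.ndim != 2:
            raise ValueError("strengths must be (RSNs, bands)")
        if self.topographies.shape[:2] != self.strengths.shape:
            raise ValueError("topographies must be (RSNs, bands, channels)")
        if not np.all(np.isfinite(self.topographies)):
            raise ValueError("topographies must be finite")
        if not np.all(np.isfinite(self.strengths)):
            raise ValueError("strengths must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.band_bins) != self.strengths.shape[1]:
            raise ValueError("band_bins must list one index array per band")
        self.band_bins = [np.asarray(b, dtype=int) for b in self.band_bins]
        all_bins = np.concatenate(self.band_bins) if self.band_bins else np.array([])
        if np.any(all_bins < 0) or np.unique(all_bins).size != all_bins.size:
            raise ValueError("band_bins must reference distinct non-negative bins")

    @property
    def n_rsns(self) -> int:
        return self.strengths.shape[0]

    @property
    def n_bands(self) -> int:
        return self.strengths.shape[1]

    @property
    def n_channels(self) -> int:
        return self.topographies.shape[2]

    def band_of_bin(self, n_bins: int) -> np.ndarray:
        """Band index per bin; -1 for bins in no band."""
        out = np.full(n_bins, -1, dtype=int)
        for i, bins in enumerate(self.band_bins):
            if np.any(bins >= n_bins):
                raise ValueError("band_bins reference bins beyond n_bins")
            out[bins] = i
        return out


@dataclass
class GroundTruth:
    """Everything needed to audit a generated dataset."""

    coupling: CouplingSpec
    master_seed: int
    dynamics: np.ndarray  # (subjects, RSNs, volumes)
    planted_borders_hz: list[float] = field(default_factory=list)


def smooth_topographies(
    positions: np.ndarray, n_patterns: int, seed: int, width: float = 0.45
) -> np.ndarray:
    """Unit-RMS smooth electrode patterns (Gaussian bumps on the montage).

    Each pattern is a signed Gaussian bump centred at a random location on
    the (x, y) layout; smoothness makes planted maps look like scalp
    fields rather than white noise across electrodes.
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=float)
    out = np.empty((n_patterns, positions.shape[0]))
    for i in range(n_patterns):
        centre = rng.uniform(-1.0, 1.0, size=2)
        sign = rng.choice([-1.0, 1.0])
        d2 = np.sum((positions - centre) ** 2, axis=1)
        w = sign * np.exp(-d2 / (2.0 * width**2))
        out[i] = w / np.sqrt(np.mean(w**2))
    return out


def default_coupling(
    n_rsns: int = 10,
    n_channels: int = 92,
    bin_freqs: np.ndarray | None = None,
    partition: BandPartition | None = None,
    strength: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 12345,
    positions: np.ndarray | None = None,
) -> CouplingSpec:
    """Coupling spec planting one topography per (RSN, band).

    Bands default to the canonical 8-band partition of the 75 retained
    bins; all (RSN, band) pairs are coupled at the same ``strength``.
    Pass ``strength=0`` for a null dataset.
    """
    if bin_freqs is None:
        bin_freqs = default_bin_freqs()
    if partition is None:
        partition = reference_bands(bin_freqs)
    if positions is None:
        from .io import default_montage

        montage = default_montage()
        positions = montage[["x", "y"]].to_numpy()
        if positions.shape[0] != n_channels:
            # non-default channel count: spread channels on a circle
            theta = np.linspace(0, 2 * np.pi, n_channels, endpoint=False)
            r = np.sqrt(np.linspace(0.05, 1.0, n_channels))
            positions = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    topo = smooth_topographies(
        positions, n_rsns * partition.n_bands, seed
    ).reshape(n_rsns, partition.n_bands, n_channels)
    return CouplingSpec(
        strengths=np.full((n_rsns, partition.n_bands), float(strength)),
        topographies=topo,
        band_bins=[partition.member_bins(i) for i in range(partition.n_bands)],
        noise_sd=noise_sd,
    )


def generate_rsn_dynamics(
    n_subjects: int,
    n_volumes: int,
    n_rsns: int,
    ar_coefficient: float = 0.5,
    seed: int = 0,
    tr: float = 1.98,
) -> list[RSNDynamics]:
    """Per-subject first-order autoregressive Gaussian network timecourses.

    x_t = phi x_{t-1} + sqrt(1 - phi^2) eps_t with unit marginal variance,
    so the lag-1 autocorrelation equals ``ar_coefficient``.  Deterministic
    under ``seed``.
    """
    if min(n_subjects, n_volumes, n_rsns) < 1:
        raise ValueError("all counts must be >= 1")
    phi = float(ar_coefficient)
    if not np.isfinite(phi) or not 0.0 <= phi < 1.0:
        raise ValueError(f"ar_coefficient must lie in [0, 1), got {ar_coefficient!r}")
    rng = np.random.default_rng(seed)
    innov_scale = np.sqrt(1.0 - phi**2)
    out = []
    for s in range(n_subjects):
        eps = rng.standard_normal((n_rsns, n_volumes))
        x = np.empty_like(eps)
        x[:, 0] = eps[:, 0]
        for t in range(1, n_volumes):
            x[:, t] = phi * x[:, t - 1] + innov_scale * eps[:, t]
        out.append(RSNDynamics(x, tr=tr, subject_id=f"sub{s + 1}"))
    return out


def generate_spectra(
    rsn_dynamics: list[RSNDynamics],
    coupling: CouplingSpec,
    n_channels: int = 92,
    n_bins: int = 75,
    seed: int = 0,
    dropout_fraction: float = 0.0,
    bin_freqs: np.ndarray | None = None,
    channel_labels: list[str] | None = None,
) -> tuple[list[SpectralEpochSet], GroundTruth]:
    """Spectral epoch sets with planted coupling, one epoch per volume.

    amplitude(t, c, f) = sum_r strength(r, band(f)) * topography_{r,band(f)}(c)
    * dynamics_r(t) + noise.  Epoch/volume pairing is positional; if
    ``dropout_fraction`` > 0 that fraction of epochs is flagged invalid
    (masked, not deleted) per subject.
    """
    if coupling.n_channels != n_channels:
        raise ValueError(
            f"coupling defines {coupling.n_channels} channels, requested {n_channels}"
        )
    if coupling.n_rsns != rsn_dynamics[0].n_rsns:
        raise ValueError("coupling and dynamics disagree on the number of RSNs")
    band_of = coupling.band_of_bin(n_bins)
    if bin_freqs is None:
        bin_freqs = (
            default_bin_freqs(n_bins) if n_bins == 75 else np.arange(1, n_bins + 1, 1.0)
        )
    # per-bin mixing weights: (RSNs, bins, channels)
    weights = np.zeros((coupling.n_rsns, n_bins, n_channels))
    covered = band_of >= 0
    weights[:, covered, :] = (
        coupling.strengths[:, band_of[covered], None]
        * coupling.topographies[:, band_of[covered], :]
    )
    rng = np.random.default_rng(seed)
    spectra = []
    dyn_stack = []
    for dyn in rsn_dynamics:
        if dyn.n_rsns != coupling.n_rsns:
            raise ValueError("all subjects must share the coupling's RSN count")
        n_vol = dyn.n_volumes
        signal = np.einsum("rfc,rt->tcf", weights, dyn.activity)
        amp = signal + coupling.noise_sd * rng.standard_normal(
            (n_vol, n_channels, n_bins)
        )
        valid = np.ones(n_vol, dtype=bool)
        if dropout_fraction > 0:
            n_drop = int(round(dropout_fraction * n_vol))
            if n_drop:
                valid[rng.choice(n_vol, size=n_drop, replace=False)] = False
        spectra.append(
            SpectralEpochSet(
                amplitudes=amp,
                bin_freqs=bin_freqs,
                channel_labels=channel_labels or [],
                valid=valid,
            )
        )
        dyn_stack.append(dyn.activity)
    borders = [
        float((bin_freqs[b[-1]] + bin_freqs[b[-1] + 1]) / 2.0)
        for b in coupling.band_bins[:-1]
        if b[-1] + 1 < n_bins
    ]
    truth = GroundTruth(
        coupling=coupling,
        master_seed=seed,
        dynamics=np.stack(dyn_stack),
        planted_borders_hz=borders,
    )
    return spectra, truth


def generate_templates(
    n_rsns: int, grid_shape: tuple[int, int, int] = (12, 12, 8), seed: int = 0
) -> list[SpatialMap]:
    """Smooth, localized RSN template maps on a small voxel grid."""
    rng = np.random.default_rng(seed)
    grid = np.stack(
        np.meshgrid(*[np.linspace(0, 1, s) for s in grid_shape], indexing="ij"), -1
    ).reshape(-1, 3)
    maps = []
    for _ in range(n_rsns):
        centre = rng.uniform(0.15, 0.85, size=3)
        width = rng.uniform(0.12, 0.2)
        v = np.exp(-np.sum((grid - centre) ** 2, axis=1) / (2 * width**2))
        maps.append(SpatialMap(v / np.linalg.norm(v), grid_shape))
    return maps


def generate_bold(
    templates: list[SpatialMap],
    dynamics: RSNDynamics,
    amplitude: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """(voxels, volumes) BOLD series driven by the template maps."""
    tmpl = np.stack([t.values for t in templates])  # (R, V)
    if tmpl.shape[0] != dynamics.n_rsns:
        raise ValueError("one template per RSN required")
    rng = np.random.default_rng(seed)
    signal = amplitude * tmpl.T @ dynamics.activity
    return signal + noise_sd * rng.standard_normal(signal.shape)


def generate_subject_ic_maps(
    template_maps: list[SpatialMap],
    spatial_noise_sd: float = 0.02,
    sign_flip_prob: float = 0.5,
    seed: int = 0,
    n_subjects: int = 1,
) -> list[list[SpatialMap]]:
    """Per-subject IC map sets: noisy, sign-flipped, shuffled templates.

    Emulates single-subject spatial ICA output: each subject's ICs are the
    group templates plus Gaussian spatial noise, in shuffled order, with
    random sign flips standing in for the sign indeterminacy of ICA.
    """
    if not template_maps:
        raise ValueError("need at least one template")
    if spatial_noise_sd < 0:
        raise ValueError("spatial_noise_sd must be >= 0")
    grid = template_maps[0].shape
    if any(t.shape != grid for t in template_maps):
        raise ValueError("templates must share a common voxel grid")
    rng = np.random.default_rng(seed)
    subjects = []
    for _ in range(n_subjects):
        order = rng.permutation(len(template_maps))
        ics = []
        for idx in order:
            t = template_maps[idx]
            sign = -1.0 if rng.random() < sign_flip_prob else 1.0
            v = sign * (t.values + spatial_noise_sd * rng.standard_normal(t.n_voxels))
            ics.append(SpatialMap(v, grid, t.affine))
        subjects.append(ics)
    return subjects


def noise_sd_for_similarity(templates: list[SpatialMap], target: float) -> float:
    """Spatial noise SD giving an expected template-IC correlation ``target``.

    For a template with voxel variance v, corr(template, template + noise)
    is about 1 / sqrt(1 + sd^2 / v); inverting at the mean template
    variance yields the required sd.
    """
    if not 0 < target < 1:
        raise ValueError("target similarity must lie in (0, 1)")
    v = float(np.mean([t.values.var() for t in templates]))
    return float(np.sqrt(v * (1.0 / target**2 - 1.0)))
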