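"""Resting-state network (RSN) dynamics from ICA decompositions and BOLD data.

Per-subject spatial independent components (ICs) are matched to a set of
RSN template maps; the matched maps are combined into voxelwise one-sample
t-score group components (GCs); each subject's z-transformed BOLD series
is then back-projected onto the GC maps (dot product of map and momentary
BOLD image) to obtain network activity timecourses, which are finally
normalized to unit variance across networks at every volume.

Using group templates for back-projection, rather than each subject's own
IC maps, keeps individual differences in network topography (and run-to-run
ICA indeterminacy) out of the extracted dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "SpatialMap",
    "GroupComponent",
    "RSNDynamics",
    "ztransform_voxelwise",
    "match_ics_to_templates",
    "group_component",
    "threshold_map",
    "backproject",
    "normalize_across_rsns",
]

#: Sentinel stored where a one-sample t is formally infinite (zero variance,
#: nonzero mean).  Keeps arrays finite and serializable.
T_SENTINEL = 1e12


@dataclass
class SpatialMap:
    """A voxelwise map stored as a flat vector plus its grid shape."""

    values: np.ndarray
    shape: tuple[int, ...]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.shape = tuple(int(d) for d in self.shape)
        if self.values.size != int(np.prod(self.shape)):
            raise ValueError("values length must equal the product of grid dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spatial map contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.values.size


@dataclass
class GroupComponent:
    """Voxelwise one-sample t-map across subjects' assigned IC maps."""

    tmap: SpatialMap
    n_contributing: int
    template_id: str = ""
    degenerate: np.ndarray | None = None  # voxels where t hit the sentinel

    def __post_init__(self) -> None:
        if self.n_contributing < 2:
            raise ValueError("a group component needs at least 2 contributing subjects")


@dataclass
class RSNDynamics:
    """Network activity timecourses for one subject, (RSNs, volumes)."""

    activity: np.ndarray
    tr: float = 1.98
    subject_id: str = ""
    rsn_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 2:
            raise ValueError("activity must be (RSNs, volumes)")
        if not self.rsn_labels:
            self.rsn_labels = [f"RSN{i + 1}" for i in range(self.activity.shape[0])]

    @property
    def n_rsns(self) -> int:
        return self.activity.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.activity.shape[1]


def ztransform_voxelwise(bold: np.ndarray) -> np.ndarray:
    """Z-transform a (voxels, volumes) BOLD matrix voxel by voxel.

    Each voxel row is centred and scaled to unit sample SD (ddof=1).
    Rows with zero variance map to all-zero rows.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2 or bold.shape[1] < 2:
        raise ValueError("bold must be (voxels, volumes) with at least 2 volumes")
    centred = bold - bold.mean(axis=1, keepdims=True)
    sd = bold.std(axis=1, ddof=1, keepdims=True)
    # exactly-constant rows can leave a rounding-level sd; test constancy too
    degen = (sd == 0) | (np.ptp(bold, axis=1, keepdims=True) == 0)
    return np.where(degen, 0.0, centred / np.where(degen, 1.0, sd))


def _sign_invariant_corr(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """|Pearson r| over voxels and the sign that achieves it."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0, 1
    r = float(a @ b / denom)
    return abs(r), (1 if r >= 0 else -1)


@dataclass
class Assignment:
    """Result of matching one subject's ICs to the RSN templates."""

    #: template index -> IC index (templates without a match are absent)
    matches: dict[int, int]
    #: template index -> sign-invariant similarity of the matched IC
    similarity: dict[int, float]
    #: template index -> sign applied to the IC map (+1 or -1)
    sign: dict[int, int]


def match_ics_to_templates(
    ic_maps: list[SpatialMap],
    templates: list[SpatialMap],
    min_similarity: float = 0.25,
) -> Assignment:
    """Greedily assign ICs to templates by sign-invariant spatial correlation.

    The similarity score is the absolute Pearson correlation over voxels
    (ICA sign is arbitrary, so the better of +/-IC is taken).  Pairs are
    formed best-first; each template and each IC is used at most once; ties
    are broken by lower IC index.  Matches below ``min_similarity`` are
    left unassigned.  Where the best match was sign-negative the stored
    sign is -1, meaning the IC map (and its timecourse) must be flipped
    before use.
    """
    if not templates:
        raise ValueError("need at least one template")
    grid = templates[0].shape
    for m in list(ic_maps) + list(templates):
        if m.shape != grid:
            raise ValueError(f"voxel grid mismatch: {m.shape} vs {grid}")

    sim = np.zeros((len(templates), len(ic_maps)))
    sgn = np.ones_like(sim, dtype=int)
    for ti, t in enumerate(templates):
        for ii, ic in enumerate(ic_maps):
            sim[ti, ii], sgn[ti, ii] = _sign_invariant_corr(t.values, ic.values)

    matches: dict[int, int] = {}
    similarity: dict[int, float] = {}
    sign: dict[int, int] = {}
    avail_t = set(range(len(templates)))
    avail_i = set(range(len(ic_maps)))
    while avail_t and avail_i:
        best = (-1.0, None, None)
        for ti in sorted(avail_t):
            for ii in sorted(avail_i):  # ties resolved by lowest IC index
                if sim[ti, ii] > best[0]:
                    best = (sim[ti, ii], ti, ii)
        s, ti, ii = best
        if s < min_similarity:
            break
        matches[ti] = ii
        similarity[ti] = float(s)
        sign[ti] = int(sgn[ti, ii])
        avail_t.remove(ti)
        avail_i.remove(ii)
    return Assignment(matches=matches, similarity=similarity, sign=sign)


def _one_sample_t(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t against 0 along axis 0 with the degenerate-variance rule.

    SD = 0 and mean = 0 -> t = 0; SD = 0 and mean != 0 -> +/-T_SENTINEL,
    flagged degenerate.
    """
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    degenerate = (sd == 0) | (np.ptp(values, axis=0) == 0)
    mean = np.where(degenerate, values[0], mean)  # exact value for constant cells
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(degenerate, 0.0, mean / np.where(degenerate, 1.0, sd / np.sqrt(n)))
    t = np.where(degenerate & (mean != 0), np.sign(mean) * T_SENTINEL, t)
    return t, degenerate & (mean != 0)


def group_component(
    assigned_maps: list[SpatialMap], template_id: str = ""
) -> GroupComponent:
    """One-sample t-map across subjects' assigned (sign-corrected) IC maps."""
    if len(assigned_maps) < 2:
        raise ValueError("need at least 2 contributing subjects")
    grid = assigned_maps[0].shape
    if any(m.shape != grid for m in assigned_maps):
        raise ValueError("voxel grid mismatch among contributing maps")
    stack = np.stack([m.values for m in assigned_maps])
    t, degen = _one_sample_t(stack)
    return GroupComponent(
        tmap=SpatialMap(t, grid, assigned_maps[0].affine),
        n_contributing=len(assigned_maps),
        template_id=template_id,
        degenerate=degen,
    )


def threshold_map(
    gc: GroupComponent, p: float = 0.005, min_cluster: int = 10
) -> SpatialMap:
    """Display thresholding of a GC t-map: voxel p-value plus cluster extent.

    Voxels with two-sided p above the threshold are zeroed, and surviving
    clusters (6-connectivity on the 3-D grid) smaller than ``min_cluster``
    voxels are removed.  This is for reporting only; back-projection always
    uses the unthresholded map.
    """
    t = gc.tmap.values.reshape(gc.tmap.shape)
    df = gc.n_contributing - 1
    t_crit = stats.t.isf(p / 2.0, df)
    keep = np.abs(t) >= t_crit
    labels, n_lab = ndimage.label(keep)
    out = np.where(keep, t, 0.0)
    for lab in range(1, n_lab + 1):
        cluster = labels == lab
        if cluster.sum() < min_cluster:
            out[cluster] = 0.0
    return SpatialMap(out.ravel(), gc.tmap.shape, gc.tmap.affine)


def backproject(gc: GroupComponent | SpatialMap, bold_z: np.ndarray) -> np.ndarray:
    """Project a BOLD series onto a group-component map.

    activity(t) = sum_v map(v) * bold_z(v, t) — the dot product of the
    (unthresholded) GC t-map with every momentary BOLD image.
    """
    weights = gc.tmap.values if isinstance(gc, GroupComponent) else gc.values
    bold_z = np.asarray(bold_z, dtype=float)
    if bold_z.ndim != 2 or bold_z.shape[0] != weights.size:
        raise ValueError(
            f"grid mismatch: map has {weights.size} voxels, "
            f"BOLD has shape {bold_z.shape}"
        )
    return weights @ bold_z


def normalize_across_rsns(
    stacked: np.ndarray, tr: float = 1.98, subject_id: str = "", rsn_labels=None
) -> RSNDynamics:
    """Scale each volume's column to unit sample variance across RSNs.

    Columns with zero SD become all zero.  Requires at least 2 RSNs —
    variance across networks is undefined otherwise.
    """
    stacked = np.asarray(stacked, dtype=float)
    if stacked.ndim != 2 or stacked.shape[0] < 2:
        raise ValueError("need a (RSNs, volumes) matrix with at least 2 RSNs")
    sd = stacked.std(axis=0, ddof=1, keepdims=True)
    degen = (sd == 0) | (np.ptp(stacked, axis=0, keepdims=True) == 0)
    act = np.where(degen, 0.0, stacked / np.where(degen, 1.0, sd))
    return RSNDynamics(act, tr=tr, subject_id=subject_id, rsn_labels=rsn_labels or [])
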