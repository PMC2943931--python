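"""Global randomization statistics for multichannel covariance maps.

Two families of tests, both operating on whole electrode maps rather than
single channels, so no correction for multiple testing across electrodes
is needed:

* the **topographic consistency test** asks whether the across-subject
  mean map deviates from a flat zero topography.  The statistic is the
  root-mean-square (RMS, global field power) across channels of the mean
  map; the null distribution is built by shuffling each subject's values
  among electrodes, which preserves per-subject variance but destroys any
  spatial structure shared across subjects.

* **TANOVA** (topographic analysis of variance) asks whether maps differ
  between conditions of a repeated-measures design.  The statistic is the
  mean over conditions of the RMS of (condition-mean map - grand-mean
  map); the null permutes each subject's maps across conditions.

p-values use the add-one rule p = (1 + #{null >= observed}) / (1 + n_perm),
counting ties as exceedances, so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariance import BandPartition, CovarianceTensor

__all__ = [
    "RandTestResult",
    "consistency_test",
    "tanova_oneway",
    "tanova_twofactor",
    "run_battery",
]

#: Number of permutations processed per vectorized block (memory bound).
_CHUNK = 250


@dataclass
class RandTestResult:
    """Observed statistic, permutation null sample and p-value of one test."""

    observed: float
    null: np.ndarray
    p: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")
        if self.null.shape != (self.n_perm,):
            raise ValueError("null sample length must equal n_perm")


def _rms(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=axis))


def _p_value(observed: float, null: np.ndarray) -> float:
    return (1.0 + int(np.sum(null >= observed))) / (1.0 + null.size)


def _consistency_stat(maps: np.ndarray) -> float:
    """RMS across channels of the across-subject mean map."""
    return float(_rms(maps.mean(axis=0)))


def consistency_test(
    maps: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> RandTestResult:
    """Topographic consistency test of (subjects, channels) maps.

    Under the null hypothesis each subject's map has no spatial structure
    in common with the others, so shuffling values among electrodes
    independently per subject leaves the statistic's distribution
    unchanged.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2 or maps.shape[1] < 2:
        raise ValueError("need a (subjects >= 2, channels >= 2) map array")
    rng = np.random.default_rng(seed)
    observed = _consistency_stat(maps)
    null = np.empty(n_perm)
    for start in range(0, n_perm, _CHUNK):
        m = min(_CHUNK, n_perm - start)
        block = np.broadcast_to(maps, (m, *maps.shape)).copy()
        rng.permuted(block, axis=2, out=block)
        null[start : start + m] = _rms(block.mean(axis=1), axis=-1)
    return RandTestResult(observed, null, _p_value(observed, null), n_perm, seed)


def _tanova_stat(maps: np.ndarray) -> np.ndarray:
    """Mean over levels of RMS of (level mean - grand mean).

    ``maps`` is (..., subjects, levels, channels); the statistic is
    computed over the trailing three axes, preserving leading axes.
    """
    level_means = maps.mean(axis=-3)  # (..., levels, channels)
    grand = level_means.mean(axis=-2, keepdims=True)
    return _rms(level_means - grand, axis=-1).mean(axis=-1)


def _permute_levels(maps: np.ndarray, rng: np.random.Generator, m: int) -> np.ndarray:
    """m copies of (subjects, levels, channels) with levels shuffled per subject."""
    s, l, c = maps.shape
    keys = rng.random((m, s, l))
    idx = np.argsort(keys, axis=2)
    return np.take_along_axis(
        np.broadcast_to(maps, (m, s, l, c)), idx[..., None], axis=2
    )


def tanova_oneway(
    maps: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> RandTestResult:
    """One-factor repeated-measures TANOVA on (subjects, levels, channels) maps."""
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3 or maps.shape[0] < 2 or maps.shape[1] < 2:
        raise ValueError("need a (subjects >= 2, levels >= 2, channels) map array")
    if not np.all(np.isfinite(maps)):
        raise ValueError("design is incomplete (non-finite cells)")
    rng = np.random.default_rng(seed)
    observed = float(_tanova_stat(maps))
    null = np.empty(n_perm)
    for start in range(0, n_perm, _CHUNK):
        m = min(_CHUNK, n_perm - start)
        block = _permute_levels(maps, rng, m)  # (m, S, L, C)
        null[start : start + m] = _tanova_stat(block)
    return RandTestResult(observed, null, _p_value(observed, null), n_perm, seed)


def _subject_residuals(maps: np.ndarray) -> np.ndarray:
    """Per-subject residuals from that subject's additive two-factor model.

    cell(s, a, b) - rowmean(s, a) - colmean(s, b) + grandmean(s), per channel.
    """
    row = maps.mean(axis=2, keepdims=True)  # over B
    col = maps.mean(axis=1, keepdims=True)  # over A
    grand = maps.mean(axis=(1, 2), keepdims=True)
    return maps - row - col + grand


def tanova_twofactor(
    maps: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> dict[str, RandTestResult]:
    """Two-factor repeated-measures TANOVA, (subjects, A, B, channels) maps.

    Main effects collapse (mean) the other factor and run the one-way
    scheme.  The interaction removes each subject's additive model (cell
    minus row effect minus column effect plus grand mean, per subject and
    channel) and tests the residual cell means; its null independently
    permutes, within each subject, the A levels and the B levels of the
    residual array.  Row/column permutations preserve the zero-sum
    constraints that double-centering imposes on the residuals, so the
    null statistic is built from arrays with exactly the structure of the
    observed one — shuffling residuals freely across all cells breaks
    those constraints and is measurably anticonservative.  The three
    p-values are estimated independently (seeds derived from ``seed``).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4 or maps.shape[0] < 2 or maps.shape[1] < 2 or maps.shape[2] < 2:
        raise ValueError("need a complete (subjects, A >= 2, B >= 2, channels) design")
    if not np.all(np.isfinite(maps)):
        raise ValueError("design is incomplete (non-finite cells)")
    s_a, s_b, s_i = np.random.SeedSequence(seed).spawn(3)

    res_a = tanova_oneway(maps.mean(axis=2), n_perm, _seed_int(s_a))
    res_b = tanova_oneway(maps.mean(axis=1), n_perm, _seed_int(s_b))

    s, a, b, c = maps.shape
    resid = _subject_residuals(maps)  # (S, A, B, C)
    rng = np.random.default_rng(_seed_int(s_i))
    observed = float(_tanova_stat(resid.reshape(s, a * b, c)))
    null = np.empty(n_perm)
    for start in range(0, n_perm, _CHUNK):
        m = min(_CHUNK, n_perm - start)
        idx_a = np.argsort(rng.random((m, s, a)), axis=2)
        idx_b = np.argsort(rng.random((m, s, b)), axis=2)
        block = np.broadcast_to(resid, (m, s, a, b, c))
        block = np.take_along_axis(block, idx_a[..., None, None], axis=2)
        block = np.take_along_axis(block, idx_b[:, :, None, :, None], axis=3)
        null[start : start + m] = _tanova_stat(block.reshape(m, s, a * b, c))
    res_i = RandTestResult(
        observed, null, _p_value(observed, null), n_perm, _seed_int(s_i)
    )
    return {"A": res_a, "B": res_b, "interaction": res_i}


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def run_battery(
    cov_bands: CovarianceTensor,
    n_perm: int = 5000,
    seed: int = 0,
    partition: BandPartition | None = None,
) -> pd.DataFrame:
    """The full statistics battery on a band-averaged covariance tensor.

    Runs, with independent seeds fanned out from ``seed``:

    * one topographic consistency test per (RSN, band) map — at full scale
      10 x 8 = 80 tests;
    * the overall two-factor TANOVA with RSN and band as repeated-measures
      factors (three p-values);
    * one one-way TANOVA over RSNs per band.

    Returns a tidy table with columns (test, rsn, band, statistic, p,
    n_perm, seed).
    """
    if not cov_bands.is_band_level:
        raise ValueError("run_battery expects a band-averaged tensor")
    x = cov_bands.values  # (S, R, B, C)
    n_sub, n_rsn, n_band, _ = x.shape
    band_names = [str(b) for b in cov_bands.freq_labels]
    rsn_names = cov_bands.rsn_labels
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.spawn(n_rsn * n_band + 1 + n_band))

    rows = []
    for r in range(n_rsn):
        for b in range(n_band):
            s = _seed_int(next(seeds))
            res = consistency_test(x[:, r, b, :], n_perm, s)
            rows.append(
                dict(test="consistency", rsn=rsn_names[r], band=band_names[b],
                     statistic=res.observed, p=res.p, n_perm=n_perm, seed=s)
            )
    s = _seed_int(next(seeds))
    overall = tanova_twofactor(x, n_perm, s)
    for key, label in [("A", "tanova_main_rsn"), ("B", "tanova_main_band"),
                       ("interaction", "tanova_interaction")]:
        res = overall[key]
        rows.append(
            dict(test=label, rsn="all", band="all", statistic=res.observed,
                 p=res.p, n_perm=n_perm, seed=res.seed)
        )
    for b in range(n_band):
        s = _seed_int(next(seeds))
        res = tanova_oneway(x[:, :, b, :], n_perm, s)
        rows.append(
            dict(test="tanova_rsn_within_band", rsn="all", band=band_names[b],
                 statistic=res.observed, p=res.p, n_perm=n_perm, seed=s)
        )
    return pd.DataFrame(rows)
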