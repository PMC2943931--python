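"""File round-trips: montages, timecourses, tensors, maps, result tables.

Formats follow the conventions of the surrounding stack: electrode
montages and activity timecourses as TSV, covariance tensors and spectral
epoch sets as HDF5 with axis labels, spatial maps as NIfTI (real data) or
flat TSV (synthetic grids), statistics tables as TSV.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .covariance import CovarianceTensor
from .dynamics import RSNDynamics, SpatialMap
from .spectra import SpectralEpochSet

__all__ = [
    "default_montage",
    "read_montage",
    "write_dynamics_tsv",
    "read_dynamics_tsv",
    "write_spectra_h5",
    "read_spectra_h5",
    "write_covariance_h5",
    "read_covariance_h5",
    "write_map_nifti",
    "read_map_nifti",
    "write_results",
]


def default_montage() -> pd.DataFrame:
    """The packaged 92-channel synthetic layout (label, x, y)."""
    ref = importlib.resources.files("covmap.data") / "montage92.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_montage(path)


def read_montage(path) -> pd.DataFrame:
    """Read an electrode montage TSV with columns label, x, y."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"label", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"montage must have columns {sorted(required)}")
    if df[["x", "y"]].isna().any().any():
        raise ValueError("montage contains malformed coordinate rows")
    dup = df["label"][df["label"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate channel label(s): {', '.join(map(str, dup))}")
    return df


def write_dynamics_tsv(dyn: RSNDynamics, path) -> None:
    """One row per RSN, one column per volume."""
    df = pd.DataFrame(
        dyn.activity, index=dyn.rsn_labels,
        columns=[f"vol{i + 1}" for i in range(dyn.n_volumes)],
    )
    df.to_csv(path, sep="\t", index_label="rsn")


def read_dynamics_tsv(path, tr: float = 1.98, subject_id: str = "") -> RSNDynamics:
    df = pd.read_csv(path, sep="\t", index_col="rsn", float_precision="round_trip")
    return RSNDynamics(
        df.to_numpy(), tr=tr, subject_id=subject_id, rsn_labels=list(df.index)
    )


def write_spectra_h5(s: SpectralEpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("amplitudes", data=s.amplitudes)
        f.create_dataset("bin_freqs", data=s.bin_freqs)
        f.create_dataset("valid", data=s.valid)
        f.create_dataset(
            "channel_labels", data=np.array(s.channel_labels, dtype="S")
        )
        f.attrs["normalized"] = bool(s.normalized)


def read_spectra_h5(path) -> SpectralEpochSet:
    with h5py.File(path, "r") as f:
        return SpectralEpochSet(
            amplitudes=f["amplitudes"][()],
            bin_freqs=f["bin_freqs"][()],
            channel_labels=[x.decode() for x in f["channel_labels"][()]],
            valid=f["valid"][()].astype(bool),
            normalized=bool(f.attrs["normalized"]),
        )


def write_covariance_h5(cov: CovarianceTensor, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=cov.values)
        f.create_dataset("freq_labels", data=np.asarray(cov.freq_labels, dtype="S")
                         if cov.is_band_level else cov.freq_labels)
        f.attrs["band_level"] = bool(cov.is_band_level)
        f.create_dataset("channel_labels", data=np.array(cov.channel_labels, dtype="S"))
        f.create_dataset("rsn_labels", data=np.array(cov.rsn_labels, dtype="S"))
        f.create_dataset("subject_ids", data=np.array(cov.subject_ids, dtype="S"))
        f.create_dataset("n_valid_pairs", data=cov.n_valid_pairs)


def read_covariance_h5(path) -> CovarianceTensor:
    with h5py.File(path, "r") as f:
        freq = f["freq_labels"][()]
        if f.attrs["band_level"]:
            freq = np.array([x.decode() for x in freq])
        return CovarianceTensor(
            values=f["values"][()],
            freq_labels=freq,
            channel_labels=[x.decode() for x in f["channel_labels"][()]],
            rsn_labels=[x.decode() for x in f["rsn_labels"][()]],
            subject_ids=[x.decode() for x in f["subject_ids"][()]],
            n_valid_pairs=f["n_valid_pairs"][()],
        )


def write_map_nifti(m: SpatialMap, path) -> None:
    affine = m.affine if m.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(m.values.reshape(m.shape), affine), str(path))


def read_map_nifti(path) -> SpatialMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return SpatialMap(data.ravel(), data.shape, img.affine)


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each named table as ``<name>.tsv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths
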