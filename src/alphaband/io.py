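"""HDF5/CSV persistence for pipeline artifacts.

Layout of the HDF5 store (one file per run):

    /grid/positions, /grid/adjacency
    /subjects/<id>/epochs            (attrs: sampling_rate, space)
    /forward/gain
    /inverse/weights                 (attrs: regularization)
    /spectra/<id>                    (attrs: freqs, normalized)
    /peaks/f_p                       (subjects x sources, NaN = missing)

Cohort tables, band powers, cluster tables and the regression battery are
written as plain CSV next to the store.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .beamformer import Leadfield, SpatialFilter
from .cohort import EpochArray, SourceGrid
from .group_stats import ClusterTestResult
from .spectral import PowerSpectrum

__all__ = [
    "save_grid", "load_grid", "save_epochs", "load_epochs",
    "save_leadfield", "load_leadfield", "save_filter", "load_filter",
    "save_spectrum", "load_spectrum", "list_subjects",
    "save_peaks", "load_peaks", "cluster_table",
]


def save_grid(h5: h5py.File, grid: SourceGrid) -> None:
    grp = h5.require_group("grid")
    for name in ("positions", "adjacency"):
        if name in grp:
            del grp[name]
    grp.create_dataset("positions", data=grid.positions)
    grp.create_dataset("adjacency", data=grid.adjacency)
    grp.attrs["spacing"] = grid.spacing


def load_grid(h5: h5py.File) -> SourceGrid:
    grp = h5["grid"]
    return SourceGrid(positions=grp["positions"][()],
                      spacing=float(grp.attrs["spacing"]),
                      adjacency=grp["adjacency"][()].astype(bool))


def save_epochs(h5: h5py.File, subject_id: str, epochs: EpochArray) -> None:
    grp = h5.require_group(f"subjects/{subject_id}")
    if "epochs" in grp:
        del grp["epochs"]
    ds = grp.create_dataset("epochs", data=epochs.data)
    ds.attrs["sampling_rate"] = epochs.sampling_rate
    ds.attrs["space"] = epochs.space


def load_epochs(h5: h5py.File, subject_id: str) -> EpochArray:
    ds = h5[f"subjects/{subject_id}/epochs"]
    return EpochArray(data=ds[()], sampling_rate=float(ds.attrs["sampling_rate"]),
                      space=str(ds.attrs["space"]))


def list_subjects(h5: h5py.File, group: str = "subjects") -> list[str]:
    return sorted(h5[group].keys()) if group in h5 else []


def save_leadfield(h5: h5py.File, lf: Leadfield) -> None:
    grp = h5.require_group("forward")
    if "gain" in grp:
        del grp["gain"]
    grp.create_dataset("gain", data=lf.gain)


def load_leadfield(h5: h5py.File) -> Leadfield:
    return Leadfield(gain=h5["forward/gain"][()])


def save_filter(h5: h5py.File, filt: SpatialFilter) -> None:
    grp = h5.require_group("inverse")
    if "weights" in grp:
        del grp["weights"]
    ds = grp.create_dataset("weights", data=filt.weights)
    ds.attrs["regularization"] = filt.regularization


def load_filter(h5: h5py.File) -> SpatialFilter:
    ds = h5["inverse/weights"]
    return SpatialFilter(weights=ds[()],
                         regularization=float(ds.attrs["regularization"]))


def save_spectrum(h5: h5py.File, spectrum: PowerSpectrum) -> None:
    grp = h5.require_group("spectra")
    sid = spectrum.subject_id or "unknown"
    if sid in grp:
        del grp[sid]
    ds = grp.create_dataset(sid, data=spectrum.power)
    ds.attrs["freqs"] = spectrum.freqs
    ds.attrs["normalized"] = spectrum.normalized


def load_spectrum(h5: h5py.File, subject_id: str) -> PowerSpectrum:
    ds = h5[f"spectra/{subject_id}"]
    return PowerSpectrum(freqs=ds.attrs["freqs"][()], power=ds[()],
                         normalized=bool(ds.attrs["normalized"]),
                         subject_id=subject_id)


def save_peaks(h5: h5py.File, f_p: np.ndarray, subject_ids: list[str]) -> None:
    grp = h5.require_group("peaks")
    for name in ("f_p", "subject_ids"):
        if name in grp:
            del grp[name]
    grp.create_dataset("f_p", data=f_p)
    grp.create_dataset("subject_ids", data=np.array(subject_ids, dtype="S"))


def load_peaks(h5: h5py.File) -> tuple[np.ndarray, list[str]]:
    grp = h5["peaks"]
    sids = [s.decode() for s in grp["subject_ids"][()]]
    return grp["f_p"][()], sids


def cluster_table(results: dict[tuple[str, str], ClusterTestResult]) -> pd.DataFrame:
    """Flatten contrast results into a cluster table (one cluster per row)."""
    rows = []
    for pair, res in results.items():
        contrast = f"{pair[0]} vs {pair[1]}"
        if not res.clusters:
            rows.append({"contrast": contrast, "cluster": None, "size": 0,
                         "mass": np.nan, "p_value": np.nan, "significant": False})
        for k, (members, mass, p) in enumerate(res.clusters):
            rows.append({
                "contrast": contrast, "cluster": k, "size": len(members),
                "mass": mass, "p_value": p,
                "significant": bool(p <= 0.05),
                "sources": " ".join(map(str, members)),
            })
    return pd.DataFrame(rows)


def write_csv(frame: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path
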