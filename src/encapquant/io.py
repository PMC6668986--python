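"""File I/O for spectrum images, density maps, micrographs and curves.

HDF5 layout for cubes: ``/coreloss``, ``/lowloss``,
``/energy_axis_eV`` (core loss), ``/lowloss_energy_axis_eV``,
``/pixel_size_nm`` and optionally ``/ground_truth`` (the generating
areal-density map); generation parameters live in root attributes.
Micrographs are 16-bit grayscale TIFF with a CSV ground-truth table;
curves are 2-column CSV with a header.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import tifffile

from .eels import ArealDensityMap
from .synthetic import SpectrumImage

__all__ = [
    "save_cube",
    "load_cube",
    "save_density_map",
    "load_density_map",
    "save_micrograph",
    "load_micrograph",
]


def save_cube(path, cube: SpectrumImage, ground_truth: np.ndarray | None = None) -> None:
    """Write a DualEELS spectrum image (and optional ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("coreloss", data=cube.coreloss, compression="gzip")
        f.create_dataset("lowloss", data=cube.lowloss, compression="gzip")
        f.create_dataset("energy_axis_eV", data=cube.coreloss_axis_ev)
        f.create_dataset("lowloss_energy_axis_eV", data=cube.lowloss_axis_ev)
        f.create_dataset("pixel_size_nm", data=cube.pixel_size_nm)
        if ground_truth is not None:
            f.create_dataset("ground_truth", data=ground_truth, compression="gzip")
        for key, val in cube.metadata.items():
            try:
                f.attrs[key] = val if val is not None else "none"
            except TypeError:
                f.attrs[key] = json.dumps(val)


def load_cube(path) -> tuple[SpectrumImage, np.ndarray | None]:
    """Read a spectrum image written by :func:`save_cube`.

    Returns the cube and the ground-truth map if present.
    """
    with h5py.File(path, "r") as f:
        cube = SpectrumImage(
            coreloss=f["coreloss"][...].astype(float),
            lowloss=f["lowloss"][...].astype(float),
            coreloss_axis_ev=f["energy_axis_eV"][...].astype(float),
            lowloss_axis_ev=f["lowloss_energy_axis_eV"][...].astype(float),
            pixel_size_nm=float(f["pixel_size_nm"][()]),
            metadata=dict(f.attrs),
        )
        truth = f["ground_truth"][...].astype(float) if "ground_truth" in f else None
    return cube, truth


def save_density_map(path, dmap: ArealDensityMap) -> None:
    """Write an areal-density map to HDF5 (/N, /N_err, /model_label)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("N", data=dmap.n)
        f.create_dataset("N_err", data=dmap.n_err)
        f.create_dataset("N_err_stat", data=dmap.n_err_stat)
        f.create_dataset("model_label", data=dmap.background_model.astype("S16"))
        f.create_dataset("valid", data=dmap.valid)
        f.create_dataset("pixel_size_nm", data=dmap.pixel_size_nm)
        f.attrs["sigma_rel_uncertainty"] = dmap.sigma_rel_uncertainty
        f.attrs["failure_reasons"] = json.dumps(
            {f"{i},{j}": r for (i, j), r in dmap.failure_reasons.items()}
        )


def load_density_map(path) -> ArealDensityMap:
    with h5py.File(path, "r") as f:
        reasons = {
            tuple(int(x) for x in k.split(",")): v
            for k, v in json.loads(f.attrs.get("failure_reasons", "{}")).items()
        }
        return ArealDensityMap(
            n=f["N"][...].astype(float),
            n_err=f["N_err"][...].astype(float),
            n_err_stat=f["N_err_stat"][...].astype(float),
            pixel_size_nm=float(f["pixel_size_nm"][()]),
            background_model=f["model_label"][...].astype("U16"),
            valid=f["valid"][...].astype(bool),
            failure_reasons=reasons,
            sigma_rel_uncertainty=float(f.attrs["sigma_rel_uncertainty"]),
        )


def save_micrograph(path, image: np.ndarray, truth: pd.DataFrame | None = None) -> None:
    """Write a micrograph as 16-bit grayscale TIFF (+ CSV ground truth).

    The float image is clipped to the uint16 range; ground truth goes
    to ``<path>.truth.csv`` when given.
    """
    img16 = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, img16)
    if truth is not None:
        truth.to_csv(str(path) + ".truth.csv", index=False)


def load_micrograph(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)
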