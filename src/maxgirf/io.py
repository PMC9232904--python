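"""HDF5 container formats for acquisitions, GIRFs and images.

Dataset schema (version 1)::

    /kspace            (N_i, N_c, N_k) complex   raw or demodulated samples
    /gradients         (N_i, N_k, 3) T/m         logical frame
    /trajectory        (N_i, N_k, 3) rad/m       logical frame (nominal)
    /times_s           (N_k,)
    /geometry/rotation (3, 3)
    /geometry/offset   (3,)
    /coilmaps          (N_c, N) complex
    /deltaf_Hz         (N,)        optional
    /ground_truth      (N,)        optional (simulations)
    attrs: schema_version, B0_T, gamma_rad_s_T, raster_s, dwell_s, t0_s,
           grid_shape, grid_fov_m, config_json

GIRF schema: /freq_Hz plus /self/{x,y,z} complex transfer samples and
optional /b0cross/{x,y,z} (stored but never applied).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import h5py
import numpy as np

from .encoding import CoilMaps, KSpaceData
from .geometry import GradientSet, ScanGeometry, SpatialGrid, Trajectory
from .girf import GirfModel

__all__ = [
    "DatasetBundle",
    "write_dataset",
    "read_dataset",
    "write_girf",
    "read_girf",
    "write_gradients",
    "read_gradients",
    "write_image",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Malformed or incompatible container file."""


@dataclass
class DatasetBundle:
    data: KSpaceData
    gradients: GradientSet
    trajectory: Trajectory
    geom: ScanGeometry
    grid: SpatialGrid
    coilmaps: CoilMaps
    deltaf_Hz: Optional[np.ndarray] = None
    ground_truth: Optional[np.ndarray] = None
    config: Optional[dict] = None


def write_dataset(
    path,
    data: KSpaceData,
    gradients: GradientSet,
    trajectory: Trajectory,
    geom: ScanGeometry,
    grid: SpatialGrid,
    coilmaps: CoilMaps,
    deltaf_Hz: Optional[np.ndarray] = None,
    ground_truth: Optional[np.ndarray] = None,
    config: Optional[dict] = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["B0_T"] = geom.B0
        f.attrs["gamma_rad_s_T"] = geom.gamma
        f.attrs["raster_s"] = gradients.raster_s
        f.attrs["dwell_s"] = data.dwell_s
        f.attrs["t0_s"] = gradients.t0_s
        f.attrs["grid_shape"] = np.asarray(grid.shape)
        f.attrs["grid_fov_m"] = np.asarray(grid.fov_m)
        f.attrs["config_json"] = json.dumps(config or {})
        f.create_dataset("kspace", data=data.samples)
        f.create_dataset("gradients", data=gradients.samples)
        f.create_dataset("trajectory", data=trajectory.k_samples)
        f.create_dataset("times_s", data=trajectory.times_s)
        g = f.create_group("geometry")
        g.create_dataset("rotation", data=geom.rotation_LtoP)
        g.create_dataset("offset", data=geom.offset_P)
        f.create_dataset("coilmaps", data=coilmaps.maps)
        if deltaf_Hz is not None:
            f.create_dataset("deltaf_Hz", data=np.asarray(deltaf_Hz))
        if ground_truth is not None:
            f.create_dataset("ground_truth", data=np.asarray(ground_truth))


def read_dataset(path) -> DatasetBundle:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema version {version}")
        for name in ("kspace", "gradients", "trajectory", "geometry", "coilmaps"):
            if name not in f:
                raise SchemaError(f"missing mandatory dataset /{name}")
        kspace = f["kspace"][()]
        grads = f["gradients"][()]
        traj = f["trajectory"][()]
        times = f["times_s"][()]
        if kspace.shape[-1] != traj.shape[1] or kspace.shape[0] != traj.shape[0]:
            raise SchemaError("inconsistent N_k/N_i between /kspace and /trajectory")
        geom = ScanGeometry(
            rotation_LtoP=f["geometry/rotation"][()],
            offset_P=f["geometry/offset"][()],
            B0=float(f.attrs["B0_T"]),
            gamma=float(f.attrs["gamma_rad_s_T"]),
        )
        shape = tuple(int(v) for v in f.attrs["grid_shape"])
        fov = tuple(float(v) for v in f.attrs["grid_fov_m"])
        grid = SpatialGrid.make(shape, fov)
        coil = CoilMaps(f["coilmaps"][()])
        if coil.maps.shape[1] != grid.n_voxels:
            raise SchemaError("coil maps do not match the stored grid shape")
        bundle = DatasetBundle(
            data=KSpaceData(kspace, dwell_s=float(f.attrs["dwell_s"])),
            gradients=GradientSet(
                grads, raster_s=float(f.attrs["raster_s"]), frame="logical",
                t0_s=float(f.attrs["t0_s"]),
            ),
            trajectory=Trajectory(traj, times_s=times, frame="logical"),
            geom=geom,
            grid=grid,
            coilmaps=coil,
            deltaf_Hz=f["deltaf_Hz"][()] if "deltaf_Hz" in f else None,
            ground_truth=f["ground_truth"][()] if "ground_truth" in f else None,
            config=json.loads(f.attrs["config_json"]) if "config_json" in f.attrs else None,
        )
    return bundle


def write_girf(path, girf: GirfModel) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("freq_Hz", data=girf.freq_Hz)
        g = f.create_group("self")
        for i, axis in enumerate("xyz"):
            g.create_dataset(axis, data=girf.transfer[i])
        if girf.b0_cross is not None:
            b = f.create_group("b0cross")
            for i, axis in enumerate("xyz"):
                b.create_dataset(axis, data=girf.b0_cross[i])


def read_girf(path) -> GirfModel:
    with h5py.File(path, "r") as f:
        if "freq_Hz" not in f or "self" not in f:
            raise SchemaError("GIRF file must contain /freq_Hz and /self/{x,y,z}")
        freq = f["freq_Hz"][()]
        transfer = np.stack([f[f"self/{axis}"][()] for axis in "xyz"])
        b0 = None
        if "b0cross" in f:
            b0 = np.stack([f[f"b0cross/{axis}"][()] for axis in "xyz"])
    return GirfModel(freq_Hz=freq, transfer=transfer, b0_cross=b0)


def write_gradients(path, gradients: GradientSet, geom: Optional[ScanGeometry] = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["raster_s"] = gradients.raster_s
        f.attrs["frame"] = gradients.frame
        f.attrs["t0_s"] = gradients.t0_s
        f.create_dataset("gradients", data=gradients.samples)
        if geom is not None:
            g = f.create_group("geometry")
            g.create_dataset("rotation", data=geom.rotation_LtoP)
            g.create_dataset("offset", data=geom.offset_P)
            f.attrs["B0_T"] = geom.B0
            f.attrs["gamma_rad_s_T"] = geom.gamma


def read_gradients(path) -> GradientSet:
    with h5py.File(path, "r") as f:
        return GradientSet(
            f["gradients"][()],
            raster_s=float(f.attrs["raster_s"]),
            frame=str(f.attrs["frame"]),
            t0_s=float(f.attrs.get("t0_s", 0.0)),
        )


def write_image(path, image: np.ndarray, shape, metrics: Optional[dict] = None,
                config: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["grid_shape"] = np.asarray(shape)
        f.attrs["metrics_json"] = json.dumps(metrics or {})
        f.attrs["config_json"] = json.dumps(config or {})
        f.create_dataset("image", data=np.asarray(image))
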