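"""File formats: NIfTI volumes, HDF5 signal sets, YAML configs, JSON sidecars.

Flow fields and reconstructions are written as one NIfTI file per component
(affine encodes the voxel size and origin, in millimeters per NIfTI
convention) with a JSON sidecar holding geometry, condition and provenance
metadata.  Complex signal sets go to HDF5 (one dataset per segment plus the
configuration).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .grids import GridSpec
from .pcmri_encode import AcquisitionConfig, ComplexSignalSet, EncodingScheme
from .recon import ReconResult
from .synthetic_flow import (
    FlowCondition,
    FluidProperties,
    FlowField,
    PhantomGeometry,
)

__all__ = [
    "save_flow_field",
    "load_flow_field",
    "save_recon",
    "load_recon",
    "save_signals",
    "load_signals",
    "load_yaml",
    "save_yaml",
]

_M_TO_MM = 1e3


def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.diag([grid.voxel_size * _M_TO_MM] * 3 + [1.0])
    center0 = (np.array(grid.origin) + 0.5 * grid.voxel_size) * _M_TO_MM
    aff[:3, 3] = center0
    return aff


def _save_nii(volume: np.ndarray, grid: GridSpec, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), _affine(grid))
    nib.save(img, str(path))


def _load_nii(path: Path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    aff = img.affine
    voxel = float(aff[0, 0]) / _M_TO_MM
    origin = tuple(aff[:3, 3] / _M_TO_MM - 0.5 * voxel)
    data = np.asarray(img.get_fdata())
    return data, GridSpec(shape=data.shape, voxel_size=voxel, origin=origin)


_COMPONENTS = ("x", "y", "z")


def save_flow_field(flow: FlowField, directory: str | Path) -> list[Path]:
    """Write a flow field as NIfTI components plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i, c in enumerate(_COMPONENTS):
        p = directory / f"mean_velocity_{c}.nii"
        _save_nii(flow.mean_velocity[i], flow.grid, p)
        written.append(p)
        p = directory / f"ivsd_{c}.nii"
        _save_nii(flow.ivsd[i], flow.grid, p)
        written.append(p)
    p = directory / "lumen_mask.nii"
    _save_nii(flow.lumen_mask.astype(float), flow.grid, p)
    written.append(p)
    sidecar = {
        "grid": flow.grid.to_dict(),
        "geometry": flow.geometry.to_dict(),
        "fluid": {
            "density": flow.fluid.density,
            "dynamic_viscosity": flow.fluid.dynamic_viscosity,
            "temperature": flow.fluid.temperature,
        },
        "condition": None if flow.condition is None else flow.condition.to_dict(),
    }
    p = directory / "flow_field.json"
    p.write_text(json.dumps(sidecar, indent=2))
    written.append(p)
    return written


def load_flow_field(directory: str | Path) -> FlowField:
    directory = Path(directory)
    sidecar = json.loads((directory / "flow_field.json").read_text())
    grid = GridSpec.from_dict(sidecar["grid"])
    geometry = PhantomGeometry.from_dict(sidecar["geometry"])
    fluid = FluidProperties(**sidecar["fluid"])
    condition = (
        None if sidecar["condition"] is None else FlowCondition(**sidecar["condition"])
    )
    mean_velocity = np.zeros((3, *grid.shape))
    ivsd = np.zeros((3, *grid.shape))
    for i, c in enumerate(_COMPONENTS):
        mean_velocity[i], _ = _load_nii(directory / f"mean_velocity_{c}.nii")
        ivsd[i], _ = _load_nii(directory / f"ivsd_{c}.nii")
    mask, _ = _load_nii(directory / "lumen_mask.nii")
    return FlowField(
        grid=grid,
        geometry=geometry,
        fluid=fluid,
        condition=condition,
        mean_velocity=mean_velocity,
        ivsd=ivsd,
        lumen_mask=mask > 0.5,
    )


def save_recon(recon: ReconResult, directory: str | Path) -> list[Path]:
    """Write magnitude + 3 velocity components as NIfTI with a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    p = directory / "magnitude.nii"
    _save_nii(recon.magnitude, recon.grid, p)
    written.append(p)
    for i, c in enumerate(_COMPONENTS):
        p = directory / f"velocity_{c}.nii"
        _save_nii(recon.velocity[i], recon.grid, p)
        written.append(p)
    sidecar = {
        "grid": recon.grid.to_dict(),
        "venc": recon.venc,
        "orientation": recon.orientation,
        "provenance": recon.provenance,
    }
    p = directory / "recon.json"
    p.write_text(json.dumps(sidecar, indent=2))
    written.append(p)
    return written


def load_recon(directory: str | Path) -> ReconResult:
    """Load a reconstruction (possibly produced externally) from NIfTI."""
    directory = Path(directory)
    sidecar = json.loads((directory / "recon.json").read_text())
    grid = GridSpec.from_dict(sidecar["grid"])
    magnitude, _ = _load_nii(directory / "magnitude.nii")
    velocity = np.zeros((3, *grid.shape))
    for i, c in enumerate(_COMPONENTS):
        velocity[i], _ = _load_nii(directory / f"velocity_{c}.nii")
    return ReconResult(
        magnitude=magnitude,
        velocity=velocity,
        venc=float(sidecar["venc"]),
        grid=grid,
        orientation=sidecar.get("orientation", "COR"),
        provenance=sidecar.get("provenance", {}),
    )


def save_signals(signals: ComplexSignalSet, path: str | Path) -> Path:
    """Write a complex signal set (segments + config) to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for i, vol in enumerate(signals.segments):
            f.create_dataset(f"segments/{i}", data=vol)
        f.create_dataset("scheme/kv", data=np.asarray(signals.scheme.segments))
        f.attrs["config"] = json.dumps(signals.config.to_dict())
        f.attrs["grid"] = json.dumps(signals.grid.to_dict())
        f.attrs["provenance"] = json.dumps(signals.provenance)
    return path


def load_signals(path: str | Path) -> ComplexSignalSet:
    with h5py.File(path, "r") as f:
        n = len(f["segments"])
        segments = [np.asarray(f[f"segments/{i}"]) for i in range(n)]
        kv = np.asarray(f["scheme/kv"])
        config = AcquisitionConfig.from_dict(json.loads(f.attrs["config"]))
        grid = GridSpec.from_dict(json.loads(f.attrs["grid"]))
        provenance = json.loads(f.attrs["provenance"])
    scheme = EncodingScheme(segments=tuple(tuple(row) for row in kv))
    return ComplexSignalSet(
        segments=segments, scheme=scheme, config=config, grid=grid, provenance=provenance
    )


def load_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_yaml(data: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(data, f, sort_keys=False)
    return path
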