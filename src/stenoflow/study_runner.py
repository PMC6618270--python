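"""Study orchestration: the trajectory x orientation x flow-rate matrix.

Runs generate -> acquire -> reconstruct -> quantify for every configured
scan and collects maximum velocity, total TKE, flow-rate profiles and
centerline profiles into a report, together with a simple scan-duration
model (readouts * TR * averages) and the printed-protocol timing ratios.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import protocols, quantify
from .pcmri_encode import AcquisitionConfig, acquire
from .recon import offset_correction, velocity_from_phase
from .synthetic_flow import (
    FluidProperties,
    FlowField,
    JetParameters,
    PhantomGeometry,
    TurbulenceParameters,
    build_geometry,
    default_grid,
    flow_condition,
    mean_velocity_field,
    static_offset_field,
    turbulence_field,
)

__all__ = [
    "ScanSpec",
    "StudyConfig",
    "StudyReport",
    "run_matrix",
    "scan_time_model",
    "export_report",
    "load_report",
]

logger = logging.getLogger("stenoflow.study")

#: Default flow rates of the evaluation matrix (m^3/s): the two
#: turbulence-mapped rates plus the increased-flow and stenotic-flow cases.
DEFAULT_FLOW_RATES = (10e-6, 20e-6, 56e-6, 112e-6)


@dataclass(frozen=True)
class ScanSpec:
    """One scan of the evaluation matrix."""

    name: str
    trajectory: str
    orientation: str
    venc_cm_s: float
    flow_rate: float  # m^3/s
    purpose: str = "velocity"  # "velocity" or "turbulence"
    noise_sigma: float = 0.0
    averages: int = 1
    displacement: bool = True
    oversample: int = 2

    def __post_init__(self) -> None:
        if self.purpose not in ("velocity", "turbulence"):
            raise ValueError(f"purpose must be velocity|turbulence, got {self.purpose}")


@dataclass
class StudyConfig:
    """The full study: scan list, phantom, fluid and analysis settings."""

    scans: list[ScanSpec]
    seed: int = 0
    geometry: PhantomGeometry = field(default_factory=build_geometry)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    voxel_size: float = 1.5e-3
    offset_amplitude: float = 0.0  # m/s; > 0 enables pump-off correction
    jet_params: JetParameters = field(default_factory=JetParameters)
    tke_params: TurbulenceParameters = field(default_factory=TurbulenceParameters)
    flow_rate_planes_d: tuple = tuple(np.arange(-1.5, 7.01, 0.5))
    centerline_x_d: tuple = tuple(np.arange(-1.5, 7.01, 0.25))

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValueError("study needs at least one scan")
        names = [s.name for s in self.scans]
        if len(set(names)) != len(names):
            raise ValueError("scan names must be unique")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "scans": [s.__dict__ for s in self.scans],
                "seed": self.seed,
                "geometry": self.geometry.to_dict(),
                "voxel_size": self.voxel_size,
                "offset_amplitude": self.offset_amplitude,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Per-scan quantification results plus profiles and provenance."""

    table: pd.DataFrame
    profiles: dict  # scan name -> {"flow_rate": {...}, "centerline_speed": {...}}
    provenance: dict
    errors: dict  # scan name -> error message, for scans that failed

    def to_json(self) -> str:
        payload = {
            "table": self.table.to_dict(orient="records"),
            "profiles": self.profiles,
            "provenance": self.provenance,
            "errors": self.errors,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=float)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        payload = json.loads(text)
        return cls(
            table=pd.DataFrame(payload["table"]),
            profiles=payload["profiles"],
            provenance=payload["provenance"],
            errors=payload["errors"],
        )


def scan_time_model(readouts: int, tr: float, averages: int = 1) -> float:
    """Scan duration (s) as readouts * TR * averages."""
    if readouts <= 0 or tr <= 0 or averages <= 0:
        raise ValueError("readouts, tr and averages must all be positive")
    return readouts * tr * averages


def _scan_seed(global_seed: int, index: int) -> int:
    return (global_seed * 1009 + index * 101 + 17) % (2**31)


def run_matrix(config: StudyConfig) -> StudyReport:
    """Execute the full evaluation matrix.

    Deterministic under the global seed; a failing scan is reported in
    ``errors`` without aborting the rest of the matrix.
    """
    geometry = config.geometry
    grid = default_grid(geometry, voxel_size=config.voxel_size)
    seg = quantify.segment_lumen(geometry, grid)
    flow_cache: dict[float, FlowField] = {}
    rows = []
    profiles: dict[str, dict] = {}
    errors: dict[str, str] = {}

    for i, scan in enumerate(config.scans):
        t0 = time.perf_counter()
        seed = _scan_seed(config.seed, i)
        try:
            row = _run_scan(config, scan, geometry, grid, seg, flow_cache, seed, profiles)
            rows.append(row)
            logger.info("scan %s done in %.2f s", scan.name, time.perf_counter() - t0)
        except Exception as exc:  # pragma: no cover - defensive per-scan isolation
            errors[scan.name] = f"{type(exc).__name__}: {exc}"
            rows.append({"scan": scan.name, "error": str(exc)})
            logger.warning("scan %s failed: %s", scan.name, exc)

    table = pd.DataFrame(rows)
    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "scan_seeds": {s.name: _scan_seed(config.seed, i) for i, s in enumerate(config.scans)},
        "units": {
            "max_velocity": "m/s",
            "total_tke": "J",
            "flow_rate": "m^3/s",
            "centerline_speed": "m/s",
        },
    }
    return StudyReport(table=table, profiles=profiles, provenance=provenance, errors=errors)


def _get_flow(config: StudyConfig, geometry, grid, flow_rate: float) -> FlowField:
    cond = flow_condition(flow_rate, geometry, config.fluid)
    mean = mean_velocity_field(geometry, cond, grid, config.jet_params, config.fluid)
    return turbulence_field(
        geometry, cond, grid, config.tke_params, base=mean,
        jet_params=config.jet_params, fluid=config.fluid,
    )


def _run_scan(config, scan, geometry, grid, seg, flow_cache, seed, profiles) -> dict:
    if scan.flow_rate not in flow_cache:
        flow_cache[scan.flow_rate] = _get_flow(config, geometry, grid, scan.flow_rate)
    flow = flow_cache[scan.flow_rate]

    acq = AcquisitionConfig.from_protocol(
        scan.trajectory,
        scan.orientation,
        scan.venc_cm_s,
        noise_sigma=scan.noise_sigma,
        averages=scan.averages,
        displacement=scan.displacement,
        oversample=scan.oversample,
        seed=seed,
    )
    offsets = None
    if config.offset_amplitude > 0:
        offsets = static_offset_field(grid, config.offset_amplitude, seed=seed + 1)

    signals = acquire(flow, offsets, acq)
    rec = velocity_from_phase(signals)

    if offsets is not None:
        still = FlowField(
            grid=grid,
            geometry=geometry,
            fluid=config.fluid,
            condition=None,
            mean_velocity=np.zeros((3, *grid.shape)),
            ivsd=np.zeros((3, *grid.shape)),
            lumen_mask=flow.lumen_mask,
        )
        pump_off = velocity_from_phase(
            acquire(still, offsets, replace(acq, seed=seed + 2))
        )
        rec = offset_correction(rec, pump_off)

    row: dict = {
        "scan": scan.name,
        "trajectory": scan.trajectory,
        "orientation": scan.orientation,
        "venc_cm_s": scan.venc_cm_s,
        "flow_rate": scan.flow_rate,
        "purpose": scan.purpose,
        "seed": seed,
    }
    row["max_velocity"] = quantify.max_velocity(rec, seg)
    if scan.purpose == "turbulence":
        ivsd, info = quantify.ivsd_from_magnitude(signals)
        tmap = quantify.tke_from_ivsd(
            ivsd, config.fluid.density, grid, n_clamped=info["n_clamped"]
        )
        row["total_tke"] = quantify.total_tke(tmap, seg, geometry)
        row["ivsd_clamped_voxels"] = info["n_clamped"]
    frp = quantify.flow_rate_profile(
        rec, seg, np.asarray(config.flow_rate_planes_d), geometry
    )
    speed_prof = quantify.centerline_profile(
        rec.speed(), grid, geometry, np.asarray(config.centerline_x_d), label="speed"
    )
    profiles[scan.name] = {
        "flow_rate": {
            "x_diameters": list(map(float, frp.x_diameters)),
            "values": list(map(float, frp.flow_rate)),
        },
        "centerline_speed": {
            "x_diameters": list(map(float, speed_prof.x_diameters)),
            "values": list(map(float, speed_prof.values)),
        },
    }
    protocol = protocols.protocol_entry(scan.trajectory, scan.orientation, scan.venc_cm_s)
    row["modeled_scan_time"] = scan_time_model(
        protocol["readouts"], protocol["tr"], scan.averages
    )
    row["printed_scan_time"] = protocol["scan_time"]
    return row


def export_report(report: StudyReport, directory: str | Path) -> dict:
    """Write CSV tables, profile CSVs, a JSON summary, a run log and a manifest.

    Returns the manifest (relative path -> description).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    report.table.to_csv(directory / "report.csv", index=False)
    manifest["report.csv"] = "per-scan quantification table"

    (directory / "summary.json").write_text(report.to_json())
    manifest["summary.json"] = "full report (table, profiles, provenance) as JSON"

    prof_dir = directory / "profiles"
    prof_dir.mkdir(exist_ok=True)
    for name, profs in report.profiles.items():
        for kind, data in profs.items():
            p = prof_dir / f"{name}_{kind}.csv"
            pd.DataFrame(
                {"x_diameters": data["x_diameters"], kind: data["values"]}
            ).to_csv(p, index=False)
            manifest[str(p.relative_to(directory))] = f"{kind} profile for scan {name}"

    log_lines = [
        f"config hash: {report.provenance.get('config_hash')}",
        f"global seed: {report.provenance.get('seed')}",
        f"scans: {len(report.table)}",
        f"failed: {sorted(report.errors)}",
    ]
    (directory / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    manifest["run_log.txt"] = "run log"

    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_report(directory: str | Path) -> StudyReport:
    """Reload an exported report from its JSON summary."""
    return StudyReport.from_json((Path(directory) / "summary.json").read_text())
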