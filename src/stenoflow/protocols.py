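"""Benchmark scan-protocol parameters.

Printed parameters of the in vitro stack-of-spirals versus Cartesian 3D
PC-MRI comparison that this package emulates (1.5 T system, 33 mT/m,
180 T/m/s; 1.5 mm isotropic voxels).  Each entry is one scan at one VENC:
timings in seconds, VENC in cm/s.  Scan times and readout counts are used
as printed constants for scan-duration modeling and timing-ratio checks;
they are not re-derived from the trajectory design.
"""

from __future__ import annotations

import numpy as np

__all__ = ["PROTOCOLS", "protocol_entry", "cor_scan_time_ratio", "scan_time_seconds"]


def _mmss(minutes: int, seconds: int) -> float:
    return 60.0 * minutes + seconds


def _rows(trajectory, orientation, readouts, matrix, interleaves, per_venc):
    rows = []
    for venc, scan_time, te_ms, tr_ms in per_venc:
        rows.append(
            {
                "trajectory": trajectory,
                "orientation": orientation,
                "venc_cm_s": venc,
                "scan_time": scan_time,
                "readouts": readouts,
                "te": te_ms * 1e-3,
                "tr": tr_ms * 1e-3,
                "matrix": matrix,
                "voxel_size": 1.5e-3,
                "interleaves": interleaves,
            }
        )
    return rows


PROTOCOLS = (
    _rows(
        "stack_of_spirals", "COR", 285, (112, 112, 15), 15,
        [
            (10, _mmss(1, 36), 5.9, 14.1),
            (35, _mmss(1, 21), 3.7, 11.9),
            (70, _mmss(1, 16), 3.0, 11.2),
            (150, _mmss(0, 49), 2.4, 10.5),
            (300, _mmss(0, 48), 2.1, 10.3),
        ],
    )
    + _rows(
        "stack_of_spirals", "TRA", 1224, (96, 96, 80), 12,
        [
            (10, _mmss(11, 40), 5.9, 14.5),
            (35, _mmss(8, 44), 3.7, 12.3),
            (70, _mmss(5, 34), 2.9, 11.5),
            (150, _mmss(2, 40), 2.3, 10.9),
            (300, _mmss(2, 34), 1.9, 10.5),
        ],
    )
    + _rows(
        "stack_of_spirals", "OBL", 1224, (96, 96, 80), 15,
        [
            (150, _mmss(2, 40), 2.3, 10.9),
            (300, _mmss(2, 34), 1.9, 10.5),
        ],
    )
    + _rows(
        "cartesian", "COR", 1634, (112, 112, 15), None,
        [
            (10, _mmss(7, 31), 8.1, 11.4),
            (35, _mmss(5, 51), 5.5, 8.9),
            (70, _mmss(5, 29), 4.9, 8.2),
            (150, _mmss(3, 31), 4.5, 7.9),
            (300, _mmss(3, 29), 4.5, 7.8),
        ],
    )
    + _rows(
        "cartesian", "TRA", 4284, (80, 80, 80), None,
        [
            (10, _mmss(22, 31), 8.2, 11.6),
            (35, _mmss(18, 14), 5.7, 9.1),
            (70, _mmss(16, 43), 4.9, 8.3),
            (150, _mmss(6, 48), 4.5, 7.9),
            (300, _mmss(6, 41), 4.3, 7.7),
        ],
    )
    + _rows(
        "cartesian", "OBL", 4284, (80, 80, 80), None,
        [
            (150, _mmss(6, 48), 4.5, 7.9),
            (300, _mmss(6, 41), 4.3, 7.7),
        ],
    )
)


def protocol_entry(trajectory: str, orientation: str, venc_cm_s: float) -> dict:
    """Look up the protocol row for one scan; raises if absent."""
    for row in PROTOCOLS:
        if (
            row["trajectory"] == trajectory
            and row["orientation"] == orientation
            and abs(row["venc_cm_s"] - venc_cm_s) < 1e-9
        ):
            return dict(row)
    raise KeyError(
        f"no protocol entry for {trajectory}/{orientation} at VENC {venc_cm_s} cm/s"
    )


def scan_time_seconds(trajectory: str, orientation: str, venc_cm_s: float) -> float:
    """Printed scan duration (s) for one protocol entry."""
    return protocol_entry(trajectory, orientation, venc_cm_s)["scan_time"]


def cor_scan_time_ratio() -> float:
    """Mean spiral/Cartesian scan-time ratio over the coronal VENC settings."""
    vencs = [10, 35, 70, 150, 300]
    ratios = [
        scan_time_seconds("stack_of_spirals", "COR", v)
        / scan_time_seconds("cartesian", "COR", v)
        for v in vencs
    ]
    return float(np.mean(ratios))
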