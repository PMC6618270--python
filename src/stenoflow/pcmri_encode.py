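"""Multi-point phase-contrast MRI signal simulation.

Simulates the complex signals of a referenced four-point velocity-encoded
acquisition of a :class:`~stenoflow.synthetic_flow.FlowField`:

* velocity maps to signal phase through the first-moment sensitivity
  ``kv = pi / VENC`` (rad per m/s);
* intravoxel velocity dispersion (IVSD), modeled as a per-axis Gaussian
  velocity distribution, attenuates the magnitude by
  ``exp(-kv_a^2 sigma_a^2 / 2)`` per axis;
* displacement (spatial misregistration) artifacts arise because position
  along each encoding axis is encoded at a different time than the echo:
  signal from a spin moving at ``v`` appears shifted by ``v_a (TE - t_enc,a)``
  along axis ``a``.  Cartesian readouts encode the frequency axis at the
  echo and the phase/slice axes early; stack-of-spirals readouts start at
  the k-space center, encoding both in-plane axes at the (shorter) echo
  with only the through-plane axis early;
* complex Gaussian noise and coherent signal averaging.

Scan orientations (COR/TRA/OBL) are rotations between the encoding frame
(frequency, phase, slice) and the phantom frame (axial flow = axis 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .grids import GridSpec
from .synthetic_flow import FlowField

__all__ = [
    "GAMMA_BAR",
    "AcquisitionConfig",
    "EncodingScheme",
    "ComplexSignalSet",
    "SpiralReadout",
    "orientation_rotation",
    "kv_from_venc",
    "encoding_scheme",
    "voxel_signal",
    "displacement_shift",
    "acquire",
    "add_noise",
    "spiral_readout_timing",
]

#: Proton gyromagnetic ratio over 2*pi (Hz/T).
GAMMA_BAR = 42.576e6

_TRAJECTORIES = ("cartesian", "stack_of_spirals")
_ORIENTATIONS = ("COR", "TRA", "OBL")

_SQ2 = 1.0 / np.sqrt(2.0)

# Columns map encoding axes (frequency, phase, slice) to phantom axes
# (axial flow, transverse y, transverse z).
_ROTATIONS = {
    # frequency (and spiral readout) along the flow direction, in-plane.
    "COR": np.eye(3),
    # slice (through-plane) encoding along the flow direction.
    "TRA": np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
    # frequency and slice encoding both at 45 degrees to the flow.
    "OBL": np.array(
        [[_SQ2, 0.0, -_SQ2], [0.0, 1.0, 0.0], [_SQ2, 0.0, _SQ2]]
    ),
}


def orientation_rotation(orientation: str) -> np.ndarray:
    """Rotation matrix whose columns are the encoding axes in phantom coordinates."""
    try:
        return _ROTATIONS[orientation].copy()
    except KeyError:
        raise ValueError(
            f"unknown orientation {orientation!r}; expected one of {_ORIENTATIONS}"
        ) from None


def kv_from_venc(venc: float) -> float:
    """First-moment encoding sensitivity (rad/(m/s)): phase pi at v = VENC."""
    if not venc > 0:
        raise ValueError(f"venc must be positive, got {venc}")
    return np.pi / venc


@dataclass(frozen=True)
class EncodingScheme:
    """Referenced four-point scheme: kv = 0 plus kv along each encoding axis."""

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        refs = [s for s in self.segments if np.allclose(s, 0.0)]
        if len(refs) != 1:
            raise ValueError("encoding scheme must contain exactly one reference segment")

    @property
    def reference_index(self) -> int:
        for i, s in enumerate(self.segments):
            if np.allclose(s, 0.0):
                return i
        raise AssertionError("unreachable: validated in __post_init__")


def encoding_scheme(venc: float) -> EncodingScheme:
    """Simple referenced four-point encoding for one VENC."""
    kv = kv_from_venc(venc)
    return EncodingScheme(
        segments=(
            (0.0, 0.0, 0.0),
            (kv, 0.0, 0.0),
            (0.0, kv, 0.0),
            (0.0, 0.0, kv),
        )
    )


@dataclass(frozen=True)
class AcquisitionConfig:
    """One PC-MRI scan: encoding, timing, trajectory, orientation, noise.

    ``axis_encoding_times`` (s, encoding-frame order frequency/phase/slice)
    may override the trajectory defaults.  ``early_encoding_time`` is the
    effective spatial-encoding time of axes encoded right after excitation.
    ``noise_sigma`` is the complex-noise standard deviation per channel as a
    fraction of the mean lumen magnitude; ``oversample`` is the spin-packet
    density per axis used for displacement splatting.
    """

    venc: float
    te: float
    tr: float
    trajectory: str = "cartesian"
    orientation: str = "COR"
    matrix: tuple[int, int, int] | None = None
    averages: int = 1
    noise_sigma: float = 0.0
    seed: int = 0
    oversample: int = 2
    displacement: bool = True
    axis_encoding_times: tuple[float, float, float] | None = None
    early_encoding_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.venc > 0:
            raise ValueError(f"venc must be positive, got {self.venc}")
        if not 0 < self.te < self.tr:
            raise ValueError(f"need 0 < te < tr, got te={self.te}, tr={self.tr}")
        if self.trajectory not in _TRAJECTORIES:
            raise ValueError(
                f"unknown trajectory {self.trajectory!r}; expected one of {_TRAJECTORIES}"
            )
        if self.orientation not in _ORIENTATIONS:
            raise ValueError(
                f"unknown orientation {self.orientation!r}; expected one of {_ORIENTATIONS}"
            )
        if self.averages < 1:
            raise ValueError(f"averages must be >= 1, got {self.averages}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.oversample < 1:
            raise ValueError(f"oversample must be >= 1, got {self.oversample}")
        for t in self.encoding_times():
            if not 0.0 <= t <= self.te:
                raise ValueError(
                    f"axis encoding times must lie in [0, te], got {self.encoding_times()}"
                )

    def encoding_times(self) -> np.ndarray:
        """Per-axis spatial-encoding times (s) in encoding-frame order.

        Cartesian: frequency axis at the echo, phase and slice early.
        Stack of spirals: both in-plane axes at the echo, through-plane early.
        With ``displacement=False`` all axes are encoded at the echo, which
        disables the artifact entirely.
        """
        if not self.displacement:
            return np.full(3, self.te)
        if self.axis_encoding_times is not None:
            return np.asarray(self.axis_encoding_times, dtype=float)
        t0 = self.early_encoding_time
        if self.trajectory == "cartesian":
            return np.array([self.te, t0, t0])
        return np.array([self.te, self.te, t0])

    def rotation(self) -> np.ndarray:
        return orientation_rotation(self.orientation)

    def to_dict(self) -> dict:
        d = {
            "venc": self.venc,
            "te": self.te,
            "tr": self.tr,
            "trajectory": self.trajectory,
            "orientation": self.orientation,
            "matrix": None if self.matrix is None else list(self.matrix),
            "averages": self.averages,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "oversample": self.oversample,
            "displacement": self.displacement,
            "axis_encoding_times": None
            if self.axis_encoding_times is None
            else list(self.axis_encoding_times),
            "early_encoding_time": self.early_encoding_time,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        d = dict(d)
        if d.get("matrix") is not None:
            d["matrix"] = tuple(d["matrix"])
        if d.get("axis_encoding_times") is not None:
            d["axis_encoding_times"] = tuple(d["axis_encoding_times"])
        return cls(**d)

    @classmethod
    def from_protocol(
        cls, trajectory: str, orientation: str, venc_cm_s: float, **overrides
    ) -> "AcquisitionConfig":
        """Build a config from the benchmark protocol table (TE/TR per VENC)."""
        from .protocols import protocol_entry

        entry = protocol_entry(trajectory, orientation, venc_cm_s)
        kwargs = dict(
            venc=venc_cm_s / 100.0,
            te=entry["te"],
            tr=entry["tr"],
            trajectory=trajectory,
            orientation=orientation,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class ComplexSignalSet:
    """One complex volume per velocity-encoding segment, plus provenance."""

    segments: list[np.ndarray]  # complex volumes, one per encoding segment
    scheme: EncodingScheme  # kv vectors in the encoding frame
    config: AcquisitionConfig
    grid: GridSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.segments}
        if len(shapes) != 1:
            raise ValueError("all segment volumes must share one shape")
        if len(self.segments) != len(self.scheme.segments):
            raise ValueError("segment count must match the encoding scheme")

    @property
    def reference(self) -> np.ndarray:
        return self.segments[self.scheme.reference_index]

    def directional_segments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(kv vector, volume) for the non-reference segments, scheme order."""
        out = []
        for kv, vol in zip(self.scheme.segments, self.segments):
            if not np.allclose(kv, 0.0):
                out.append((np.asarray(kv, dtype=float), vol))
        return out


def voxel_signal(mean_velocity, ivsd, kv, s0=1.0) -> np.ndarray:
    """Complex signal of a Gaussian intravoxel velocity distribution.

    ``S = s0 * exp(i kv . u) * exp(-sum_a kv_a^2 sigma_a^2 / 2)``.
    All vector arguments have the axis as the leading dimension and
    broadcast over any trailing spatial dimensions.
    """
    u = np.asarray(mean_velocity, dtype=float)
    sig = np.asarray(ivsd, dtype=float)
    kv = np.asarray(kv, dtype=float)
    if np.any(sig < 0):
        raise ValueError("ivsd must be non-negative")
    kv_b = kv.reshape((3,) + (1,) * (u.ndim - 1))
    phase = np.sum(kv_b * u, axis=0)
    atten = np.exp(-0.5 * np.sum(kv_b**2 * sig**2, axis=0))
    return s0 * atten * np.exp(1j * phase)


def displacement_shift(velocity, axis_encoding_times, te: float) -> np.ndarray:
    """Apparent spatial shift (m) per axis: ``v_a * (te - t_enc,a)``.

    ``velocity`` and the returned shift are in the encoding frame; an axis
    encoded at the echo shifts by zero.
    """
    t = np.asarray(axis_encoding_times, dtype=float)
    if np.any(t < 0) or np.any(t > te):
        raise ValueError(f"encoding times must lie in [0, te], got {t}")
    v = np.asarray(velocity, dtype=float)
    delay = (te - t).reshape((3,) + (1,) * (v.ndim - 1))
    return v * delay


def _sample_trilinear(volume: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear sampling of a volume at index-space coordinates (3, n)."""
    return map_coordinates(volume, coords, order=1, mode="nearest")


def _splat_trilinear(
    volume: np.ndarray, positions: np.ndarray, values: np.ndarray, grid: GridSpec
) -> None:
    """Deposit complex values at physical positions with trilinear weights.

    Positions outside the grid lose the out-of-bounds weight fraction
    (signal moved off the field of view).
    """
    f = positions / grid.voxel_size - np.array(grid.origin) / grid.voxel_size - 0.5
    i0 = np.floor(f).astype(np.int64)
    w = f - i0
    shape = grid.shape
    for dx in (0, 1):
        wx = w[:, 0] if dx else 1.0 - w[:, 0]
        ix = i0[:, 0] + dx
        for dy in (0, 1):
            wy = w[:, 1] if dy else 1.0 - w[:, 1]
            iy = i0[:, 1] + dy
            for dz in (0, 1):
                wz = w[:, 2] if dz else 1.0 - w[:, 2]
                iz = i0[:, 2] + dz
                inside = (
                    (ix >= 0)
                    & (ix < shape[0])
                    & (iy >= 0)
                    & (iy < shape[1])
                    & (iz >= 0)
                    & (iz < shape[2])
                )
                if not np.any(inside):
                    continue
                np.add.at(
                    volume,
                    (ix[inside], iy[inside], iz[inside]),
                    values[inside] * (wx * wy * wz)[inside],
                )


def acquire(
    flow: FlowField,
    offsets: np.ndarray | None,
    config: AcquisitionConfig,
) -> ComplexSignalSet:
    """Simulate a referenced four-point PC-MRI acquisition of a flow field.

    Each lumen voxel is split into ``oversample^3`` spin packets that carry
    the voxel's mean velocity and IVSD.  Per encoding segment, each packet's
    complex signal (velocity phase plus static-offset phase, Gaussian IVSD
    attenuation) is deposited at its displaced position with trilinear
    weights, complex noise is added per signal average, and averages are
    combined coherently.

    ``offsets`` is an optional (3, nx, ny, nz) static velocity-offset field
    in phantom axes; the acquired image grid equals the flow grid (a
    configured ``matrix`` must match it).
    """
    grid = flow.grid
    if config.matrix is not None and tuple(config.matrix) != tuple(grid.shape):
        raise ValueError(
            f"config matrix {config.matrix} does not match the flow grid {grid.shape}"
        )
    if offsets is not None and offsets.shape != (3, *grid.shape):
        raise ValueError("offset field must have shape (3, nx, ny, nz) on the flow grid")

    scheme = encoding_scheme(config.venc)
    rot = config.rotation()
    t_enc = config.encoding_times()

    mask = flow.lumen_mask
    idx = np.argwhere(mask)
    n_vox = idx.shape[0]
    o = config.oversample
    # Sub-voxel packet offsets (units of voxels), same for every voxel.
    sub = (np.arange(o) + 0.5) / o - 0.5
    off_grid = np.stack(np.meshgrid(sub, sub, sub, indexing="ij"), axis=-1).reshape(-1, 3)
    n_pack = off_grid.shape[0]

    centers = (idx + 0.5) * grid.voxel_size + np.array(grid.origin)
    u = flow.mean_velocity[:, mask].T  # (n_vox, 3), phantom frame
    sig = flow.ivsd[:, mask].T
    if offsets is not None:
        u_tot = u + offsets[:, mask].T
    else:
        u_tot = u
    s0 = 1.0 / n_pack

    displace = config.displacement and np.any(config.te - t_enc != 0.0)
    if displace:
        # Spin packets sample the velocity/IVSD fields at sub-voxel
        # positions (trilinear), so the intravoxel velocity spread shows up
        # as a spread of displacements and phases.  Each packet is deposited
        # at its parent voxel center plus its own shift: a static object is
        # imaged without blur, a moving one is misregistered.
        pos = (centers[:, None, :] + off_grid[None, :, :] * grid.voxel_size).reshape(-1, 3)
        frac = (pos - np.array(grid.origin)) / grid.voxel_size - 0.5
        coords = frac.T  # (3, n) index-space coordinates of packet samples
        u_pack = np.stack(
            [_sample_trilinear(flow.mean_velocity[a], coords) for a in range(3)], axis=1
        )
        # Turbulence is defined per voxel; packets inherit the parent
        # voxel's IVSD rather than interpolating it.
        sig_pack = np.repeat(sig, n_pack, axis=0)
        if offsets is not None:
            u_tot_pack = u_pack + np.stack(
                [_sample_trilinear(offsets[a], coords) for a in range(3)], axis=1
            )
        else:
            u_tot_pack = u_pack
        v_enc = u_pack @ rot  # R^T u per packet
        shift_enc = v_enc * (config.te - t_enc)[None, :]
        shift = shift_enc @ rot.T
        pos_eff = np.repeat(centers, n_pack, axis=0) + shift

    volumes = []
    for kv_enc in scheme.segments:
        kv_ph = rot @ np.asarray(kv_enc, dtype=float)
        vol = np.zeros(grid.shape, dtype=complex)
        if n_vox:
            if displace:
                phase = u_tot_pack @ kv_ph
                atten = np.exp(-0.5 * (sig_pack**2) @ (kv_ph**2))
                vals = s0 * atten * np.exp(1j * phase)
                _splat_trilinear(vol, pos_eff, vals, grid)
            else:
                # No misregistration: every packet of a voxel carries the
                # voxel's values, so the deposit is the exact voxel signal.
                phase = u_tot @ kv_ph
                atten = np.exp(-0.5 * (sig**2) @ (kv_ph**2))
                vol[mask] = atten * np.exp(1j * phase)
        volumes.append(vol)

    signals = ComplexSignalSet(
        segments=volumes,
        scheme=scheme,
        config=config,
        grid=grid,
        provenance={
            "flow_rate": None if flow.condition is None else flow.condition.volume_flow_rate,
            "geometry": flow.geometry.to_dict(),
            "density": flow.fluid.density,
        },
    )
    if config.noise_sigma > 0:
        signals = add_noise(signals, config.noise_sigma, config.seed, flow.lumen_mask)
    return signals


def add_noise(
    signal_set: ComplexSignalSet,
    noise_sigma: float,
    seed: int,
    lumen_mask: np.ndarray | None = None,
) -> ComplexSignalSet:
    """Add complex Gaussian noise, combining ``averages`` draws coherently.

    ``noise_sigma`` scales the per-average noise standard deviation (each of
    the real and imaginary channels) relative to the mean lumen magnitude of
    the reference segment; coherent averaging reduces it by sqrt(averages).
    """
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    if noise_sigma == 0:
        return signal_set
    ref_mag = np.abs(signal_set.reference)
    if lumen_mask is not None and np.any(lumen_mask):
        scale = float(np.mean(ref_mag[lumen_mask]))
    else:
        scale = float(np.mean(ref_mag[ref_mag > 0])) if np.any(ref_mag > 0) else 1.0
    sigma_abs = noise_sigma * scale
    n_avg = signal_set.config.averages
    rng = np.random.default_rng(seed)
    noisy = []
    for vol in signal_set.segments:
        noise = rng.standard_normal((n_avg, *vol.shape, 2))
        mean_noise = noise.mean(axis=0)
        noisy.append(vol + sigma_abs * (mean_noise[..., 0] + 1j * mean_noise[..., 1]))
    return ComplexSignalSet(
        segments=noisy,
        scheme=signal_set.scheme,
        config=signal_set.config,
        grid=signal_set.grid,
        provenance={**signal_set.provenance, "noise_sigma": noise_sigma, "seed": seed},
    )


@dataclass
class SpiralReadout:
    """A slew- and amplitude-constrained Archimedean spiral interleave."""

    time_step: float  # s
    readout_duration: float  # s
    kmax: float  # 1/m (cycles per meter)
    kmax_reached: bool
    k: np.ndarray  # (n, 2), cycles/m
    gradient: np.ndarray  # (n, 2), T/m
    message: str = ""


def spiral_readout_timing(
    fov: float,
    matrix: int,
    interleaves: int,
    gmax: float = 33e-3,
    smax: float = 180.0,
    time_step: float = 4e-6,
    max_duration: float = 50e-3,
) -> SpiralReadout:
    """Design one interleave of an interleaved Archimedean spiral readout.

    The trajectory ``k(theta) = c * theta * (cos theta, sin theta)`` with
    ``c = interleaves / (2 pi fov)`` keeps the radial spacing of the
    interleaved set at the full-FOV Nyquist limit.  The angular velocity is
    integrated greedily under the gradient-amplitude (``gmax``, T/m) and
    slew-rate (``smax``, T/m/s) limits until ``kmax = matrix / (2 fov)`` is
    reached (or ``max_duration`` elapses, reported explicitly).
    """
    if interleaves < 1:
        raise ValueError(f"interleaves must be >= 1, got {interleaves}")
    if not (fov > 0 and matrix > 0 and gmax > 0 and smax > 0):
        raise ValueError("fov, matrix, gmax and smax must all be positive")
    c = interleaves / (2.0 * np.pi * fov)
    kmax = matrix / (2.0 * fov)
    theta_end = kmax / c

    def grad(theta: float, omega: float) -> np.ndarray:
        dk = c * omega * np.array(
            [np.cos(theta) - theta * np.sin(theta), np.sin(theta) + theta * np.cos(theta)]
        )
        return dk / GAMMA_BAR

    theta = 0.0
    omega = 0.0
    g = np.zeros(2)
    ks = [np.zeros(2)]
    gs = [g.copy()]
    n_max = int(np.ceil(max_duration / time_step))
    reached = False
    for _ in range(n_max):
        # Tangential slew bound: the largest angular accel/decel per step.
        delta = GAMMA_BAR * smax * time_step / (c * np.hypot(1.0, theta))

        def feasible(om: float) -> bool:
            th = theta + om * time_step
            gn = grad(th, om)
            if np.hypot(*gn) > gmax:
                return False
            return np.hypot(*(gn - g)) / time_step <= smax

        hi = omega + delta
        lo = max(0.0, omega - delta)
        if feasible(hi):
            omega_new = hi
        elif not feasible(lo):
            # Rotation alone exceeds the slew budget: decelerate as hard
            # as the tangential allowance permits (best effort).
            omega_new = lo
        else:
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                if feasible(mid):
                    lo = mid
                else:
                    hi = mid
            omega_new = lo
        theta += omega_new * time_step
        omega = omega_new
        g = grad(theta, omega)
        ks.append(c * theta * np.array([np.cos(theta), np.sin(theta)]))
        gs.append(g.copy())
        if theta >= theta_end:
            reached = True
            break
    duration = (len(ks) - 1) * time_step
    msg = "" if reached else (
        f"kmax {kmax:.1f} 1/m not reached within {max_duration * 1e3:.1f} ms "
        f"under gmax={gmax} T/m, smax={smax} T/m/s"
    )
    return SpiralReadout(
        time_step=time_step,
        readout_duration=duration,
        kmax=kmax,
        kmax_reached=reached,
        k=np.array(ks),
        gradient=np.array(gs),
        message=msg,
    )
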