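"""Synthetic stenotic-jet flow phantom.

Generates the ground truth that the acquisition simulator images: a straight
rigid pipe with an axisymmetric area-reduction stenosis, steady water flow at
a configurable volume flow rate, a post-stenotic jet surrounded by backflow,
and a turbulent shear layer expressed as a per-voxel intravoxel velocity
standard deviation (IVSD) field.

The mean-velocity model is parametric, not a Navier-Stokes solution: an
upstream Poiseuille profile, a plug-like (super-Gaussian) jet through and
beyond the throat with entrainment-driven widening and exponential
centerline decay, and a weak recirculating annulus between jet and wall.
Every transverse plane is normalized so that the discrete through-plane
flux equals the prescribed flow rate exactly (continuity).

The turbulence model places IVSD in the shear-layer annulus and jet core
downstream of the throat and rescales the field so that its volume-integrated
turbulent kinetic energy matches a prescribed total (J).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import GridSpec

__all__ = [
    "FluidProperties",
    "WATER_23C",
    "PhantomGeometry",
    "FlowCondition",
    "FlowField",
    "JetParameters",
    "TurbulenceParameters",
    "build_geometry",
    "default_grid",
    "reynolds_number",
    "nominal_jet_speed",
    "flow_condition",
    "mean_velocity_field",
    "turbulence_field",
    "static_offset_field",
    "default_total_tke",
]


@dataclass(frozen=True)
class FluidProperties:
    """Fluid constants: density (kg/m^3) and dynamic viscosity (kg/(m s))."""

    density: float = 997.0
    dynamic_viscosity: float = 8.899e-4
    temperature: float = 23.0  # deg C, metadata only

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if not self.dynamic_viscosity > 0:
            raise ValueError(
                f"dynamic_viscosity must be positive, got {self.dynamic_viscosity}"
            )


#: Water at 23 degrees C, the working fluid of the in vitro phantom.
WATER_23C = FluidProperties()


@dataclass(frozen=True)
class PhantomGeometry:
    """Straight rigid pipe with an axisymmetric cosine-tapered stenosis.

    The stenosis center defines the axial origin; the normalized axial
    coordinate is X = x / inner_diameter. Severity is defined by lumen
    *area* reduction, so the minimum radius is ``R * sqrt(1 - area_reduction)``.
    """

    inner_diameter: float = 14.6e-3  # m
    area_reduction: float = 0.75  # fraction of area removed at the throat
    stenosis_center: float = 0.0  # m; defines X = 0
    stenosis_length: float = field(default=None)  # m; default 1 diameter

    def __post_init__(self) -> None:
        if not self.inner_diameter > 0:
            raise ValueError(f"inner_diameter must be positive, got {self.inner_diameter}")
        if not 0.0 <= self.area_reduction < 1.0:
            raise ValueError(
                f"area_reduction must lie in [0, 1), got {self.area_reduction}"
            )
        if self.stenosis_length is None:
            object.__setattr__(self, "stenosis_length", self.inner_diameter)
        if not self.stenosis_length > 0:
            raise ValueError(
                f"stenosis_length must be positive, got {self.stenosis_length}"
            )

    @property
    def radius(self) -> float:
        """Unconstricted lumen radius (m)."""
        return self.inner_diameter / 2.0

    @property
    def unconstricted_area(self) -> float:
        """Unconstricted lumen cross-section (m^2)."""
        return np.pi * self.radius**2

    @property
    def minimum_radius(self) -> float:
        """Lumen radius at the throat (m): R * sqrt(1 - area_reduction)."""
        return self.radius * np.sqrt(1.0 - self.area_reduction)

    @property
    def minimum_area(self) -> float:
        """Lumen cross-section at the throat (m^2)."""
        return np.pi * self.minimum_radius**2

    def radius_profile(self, x):
        """Lumen radius (m) at axial position ``x`` (m, scalar or array).

        Cosine taper from the full radius to the throat radius over the
        stenosis length, centered on ``stenosis_center``; the full radius
        is recovered outside the stenosis.
        """
        x = np.asarray(x, dtype=float)
        xi = x - self.stenosis_center
        half = self.stenosis_length / 2.0
        taper = 0.5 * (1.0 + np.cos(np.pi * xi / half))  # 1 at center, 0 at edges
        taper = np.where(np.abs(xi) <= half, taper, 0.0)
        r = self.radius - (self.radius - self.minimum_radius) * taper
        return r if r.ndim else float(r)

    def x_to_diameters(self, x):
        """Convert axial position (m) to the normalized coordinate X."""
        return (np.asarray(x, dtype=float) - self.stenosis_center) / self.inner_diameter

    def diameters_to_x(self, X):
        """Convert normalized axial coordinate X to meters."""
        return self.stenosis_center + np.asarray(X, dtype=float) * self.inner_diameter

    def to_dict(self) -> dict:
        return {
            "inner_diameter": self.inner_diameter,
            "area_reduction": self.area_reduction,
            "stenosis_center": self.stenosis_center,
            "stenosis_length": self.stenosis_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomGeometry":
        return cls(**{k: float(v) for k, v in d.items()})


def build_geometry(
    inner_diameter: float = 14.6e-3,
    area_reduction: float = 0.75,
    stenosis_length: float | None = None,
) -> PhantomGeometry:
    """Construct the phantom geometry.

    Parameters are in SI units; ``stenosis_length`` defaults to one inner
    diameter. Raises ``ValueError`` for non-physical inputs.
    """
    return PhantomGeometry(
        inner_diameter=inner_diameter,
        area_reduction=area_reduction,
        stenosis_length=stenosis_length,
    )


@dataclass(frozen=True)
class FlowCondition:
    """Steady flow condition: prescribed flow rate plus derived numbers."""

    volume_flow_rate: float  # m^3/s
    reynolds_number: float  # rho * (Q/A) * D / mu, unconstricted section
    nominal_jet_speed: float  # Q / A_min, plug-flow estimate (m/s)

    def to_dict(self) -> dict:
        return {
            "volume_flow_rate": self.volume_flow_rate,
            "reynolds_number": self.reynolds_number,
            "nominal_jet_speed": self.nominal_jet_speed,
        }


def reynolds_number(
    flow_rate: float, geometry: PhantomGeometry, fluid: FluidProperties = WATER_23C
) -> float:
    """Pipe Reynolds number rho * V * D / mu with V = Q / A (unconstricted)."""
    if flow_rate < 0:
        raise ValueError(f"flow_rate must be non-negative, got {flow_rate}")
    mean_speed = flow_rate / geometry.unconstricted_area
    return fluid.density * mean_speed * geometry.inner_diameter / fluid.dynamic_viscosity


def nominal_jet_speed(flow_rate: float, geometry: PhantomGeometry) -> float:
    """Plug-flow jet speed estimate Q / A_min (m/s)."""
    if flow_rate < 0:
        raise ValueError(f"flow_rate must be non-negative, got {flow_rate}")
    return flow_rate / geometry.minimum_area


def flow_condition(
    flow_rate: float, geometry: PhantomGeometry, fluid: FluidProperties = WATER_23C
) -> FlowCondition:
    """Bundle a flow rate with its derived Reynolds number and jet speed."""
    return FlowCondition(
        volume_flow_rate=float(flow_rate),
        reynolds_number=reynolds_number(flow_rate, geometry, fluid),
        nominal_jet_speed=nominal_jet_speed(flow_rate, geometry),
    )


@dataclass
class FlowField:
    """Voxelized ground-truth flow: mean velocity, IVSD and lumen mask.

    ``mean_velocity`` and ``ivsd`` are shaped (3, nx, ny, nz) in phantom
    axes (axis 0 of the grid is the principal flow direction). Both vanish
    outside ``lumen_mask``.
    """

    grid: GridSpec
    geometry: PhantomGeometry
    fluid: FluidProperties
    condition: FlowCondition | None
    mean_velocity: np.ndarray
    ivsd: np.ndarray
    lumen_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(self.grid.shape)
        if self.mean_velocity.shape != (3, *shape):
            raise ValueError("mean_velocity must have shape (3, nx, ny, nz)")
        if self.ivsd.shape != (3, *shape):
            raise ValueError("ivsd must have shape (3, nx, ny, nz)")
        if self.lumen_mask.shape != shape:
            raise ValueError("lumen_mask must match the grid shape")
        if np.any(self.ivsd < 0):
            raise ValueError("ivsd must be non-negative everywhere")

    def plane_flux(self, index: int) -> float:
        """Discrete through-plane flux (m^3/s) at axial voxel plane ``index``."""
        pixel_area = self.grid.voxel_size**2
        return float(np.sum(self.mean_velocity[0, index]) * pixel_area)

    def tke_field(self) -> np.ndarray:
        """Per-voxel turbulent kinetic energy density (J/m^3)."""
        return 0.5 * self.fluid.density * np.sum(self.ivsd**2, axis=0)

    def total_tke(self) -> float:
        """Volume-integrated TKE (J) over the full grid."""
        return float(np.sum(self.tke_field()) * self.grid.voxel_volume)


def default_grid(
    geometry: PhantomGeometry,
    voxel_size: float = 1.5e-3,
    x_range_d: tuple[float, float] = (-2.0, 8.0),
    cross_extent: float | None = None,
) -> GridSpec:
    """Default acquisition-matched grid: 1.5 mm isotropic, X in [-2, 8] D.

    The transverse extent defaults to the lumen diameter plus a margin wide
    enough to hold displaced jet signal.
    """
    d = geometry.inner_diameter
    x_lo = geometry.diameters_to_x(x_range_d[0])
    x_hi = geometry.diameters_to_x(x_range_d[1])
    nx = int(np.ceil((x_hi - x_lo) / voxel_size))
    if cross_extent is None:
        cross_extent = d + 16 * voxel_size  # ~8 voxels of margin per side
    nyz = int(np.ceil(cross_extent / voxel_size))
    half = nyz * voxel_size / 2.0
    return GridSpec(shape=(nx, nyz, nyz), voxel_size=voxel_size, origin=(x_lo, -half, -half))


def _lumen_mask(geometry: PhantomGeometry, grid: GridSpec) -> np.ndarray:
    x, y, z = grid.center_mesh()
    r = np.sqrt(y**2 + z**2)
    radius = geometry.radius_profile(x[:, 0, 0])[:, None, None]
    return r <= radius


@dataclass(frozen=True)
class JetParameters:
    """Shape parameters of the parametric post-stenotic jet.

    All lengths are in units of the inner diameter D.

    core_length_d:
        Potential-core length; the centerline speed is held until this
        distance downstream of the throat before decaying.
    decay_length_d:
        e-folding length of the centerline-speed decay beyond the core.
    spread_rate:
        Linear jet-radius growth per unit axial distance (dimensionless).
    backflow_fraction:
        Peak recirculation speed as a fraction of the local jet centerline
        speed; 0 disables backflow.
    profile_power:
        Exponent of the super-Gaussian radial profile exp(-(r/rj)^p); a
        smooth converging-diverging constriction produces a plug-like jet
        (contraction coefficient near one), so the default is a flat
        profile with a soft shoulder.
    """

    core_length_d: float = 1.5
    decay_length_d: float = 2.0
    spread_rate: float = 0.08
    backflow_fraction: float = 0.2
    profile_power: float = 6.0
    plug_radius_factor: float = 1.15


def jet_radius(
    geometry: PhantomGeometry, jet_params: JetParameters, x_diameters: float
) -> float:
    """Jet shoulder radius (m) at X diameters downstream of the throat.

    The emerging plug carries roughly the throat area (contraction
    coefficient near one for a smooth constriction), so its super-Gaussian
    shoulder starts at ``plug_radius_factor * minimum_radius`` and widens
    linearly with the entrainment spread rate, capped below the wall.
    """
    r0 = jet_params.plug_radius_factor * geometry.minimum_radius
    r = r0 + jet_params.spread_rate * max(x_diameters, 0.0) * geometry.inner_diameter
    return min(r, 0.95 * geometry.radius)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def mean_velocity_field(
    geometry: PhantomGeometry,
    condition: FlowCondition,
    grid: GridSpec | None = None,
    jet_params: JetParameters = JetParameters(),
    fluid: FluidProperties = WATER_23C,
) -> FlowField:
    """Generate the mean (time-averaged) velocity field of the stenotic jet.

    Upstream of the stenosis the axial profile is parabolic (Poiseuille).
    Through and past the throat a plug-like jet forms, widening and decaying
    downstream, surrounded by a recirculating annulus. Transverse mean
    components are neglected. Each axial plane is rescaled so its discrete
    flux equals the prescribed flow rate exactly.
    """
    if grid is None:
        grid = default_grid(geometry)
    if geometry.inner_diameter / grid.voxel_size < 4:
        raise ValueError(
            "grid too coarse: fewer than 4 voxels across the lumen diameter"
        )
    mask = _lumen_mask(geometry, grid)
    x = grid.axis_centers(0)
    y = grid.axis_centers(1)[None, :, None]
    z = grid.axis_centers(2)[None, None, :]
    r = np.sqrt(y**2 + z**2)  # (1, ny, nz)

    Q = condition.volume_flow_rate
    R = geometry.radius
    A = geometry.unconstricted_area
    D = geometry.inner_diameter
    X = geometry.x_to_diameters(x)  # normalized axial coordinate
    half_len_d = geometry.stenosis_length / 2.0 / D

    # Poiseuille profile (same at every plane; normalization fixes flux).
    u_pois = 2.0 * (Q / A) * np.clip(1.0 - (r / R) ** 2, 0.0, None)  # (1, ny, nz)

    p = jet_params.profile_power
    u = np.zeros((grid.shape[0], grid.shape[1], grid.shape[2]))
    for i, Xi in enumerate(X):
        if Xi <= -half_len_d:
            u[i] = u_pois[0]
            continue
        r_j = jet_radius(geometry, jet_params, Xi)
        core = np.exp(-((r[0] / r_j) ** p))
        # Recirculating annulus between the jet shoulder and the wall.
        if jet_params.backflow_fraction > 0 and Xi > 0 and r_j < 0.9 * R:
            r_b = 0.5 * (r_j + R)
            w_b = max((R - r_j) / 4.0, 1e-6)
            back = -jet_params.backflow_fraction * np.exp(-(((r[0] - r_b) / w_b) ** 2))
        else:
            back = 0.0
        jet = core + back
        # Fade the jet back into a developed parabolic profile downstream.
        decay_start = jet_params.core_length_d
        fade = np.exp(-max(Xi - decay_start, 0.0) / jet_params.decay_length_d)
        profile = fade * jet + (1.0 - fade) * u_pois[0] / max(u_pois.max(), 1e-30)
        if Xi < 0:
            # Taper region: blend Poiseuille into the jet profile.
            s = _smoothstep((Xi + half_len_d) / half_len_d)
            profile = (1.0 - s) * u_pois[0] / max(u_pois.max(), 1e-30) + s * jet
        u[i] = profile
    u = np.where(mask, u, 0.0)

    # Enforce continuity: rescale every plane to the prescribed flux.
    if Q == 0.0:
        u = np.zeros_like(u)
    else:
        pixel_area = grid.voxel_size**2
        flux = u.sum(axis=(1, 2)) * pixel_area
        if np.any(np.abs(flux) < 1e-15 * abs(Q)):
            raise ValueError("degenerate plane with zero flux; refine the grid")
        u *= (Q / flux)[:, None, None]

    mean_velocity = np.zeros((3, *grid.shape))
    mean_velocity[0] = u
    ivsd = np.zeros_like(mean_velocity)
    return FlowField(
        grid=grid,
        geometry=geometry,
        fluid=fluid,
        condition=condition,
        mean_velocity=mean_velocity,
        ivsd=ivsd,
        lumen_mask=mask,
    )


#: Calibration anchors for the default total post-stenotic TKE (J) at the
#: two turbulence-mapped flow rates; other rates scale quadratically with Q.
_TKE_ANCHORS = {10e-6: 2.08e-5, 20e-6: 9.56e-5}


def default_total_tke(flow_rate: float) -> float:
    """Default total TKE target (J) for a flow rate (m^3/s).

    Uses measured anchors at 10 and 20 mL/s; elsewhere scales the 20 mL/s
    anchor with the square of the flow rate (turbulence intensity tracks
    the jet speed).
    """
    for q, t in _TKE_ANCHORS.items():
        if abs(flow_rate - q) <= 1e-3 * q:
            return t
    return _TKE_ANCHORS[20e-6] * (flow_rate / 20e-6) ** 2


@dataclass(frozen=True)
class TurbulenceParameters:
    """Shape and budget of the synthetic turbulence (IVSD) field.

    total_tke:
        Volume-integrated turbulent kinetic energy target (J). When None,
        a default is derived from the flow condition.
    peak_location_d:
        Axial location (diameters downstream of the throat) of the
        turbulence-intensity peak.
    axial_width_d:
        Gaussian width (diameters) of the axial intensity envelope; the
        envelope is truncated to X in [0, extent_d].
    extent_d:
        Downstream extent (diameters) beyond which the IVSD is zero.
    core_fraction:
        Relative intensity of jet-core turbulence versus the shear layer.
    shear_width_fraction:
        Radial thickness of the shear-layer annulus as a fraction of the
        throat radius.  The default spreads the TKE budget widely enough
        that the peak TKE density stays near ten times the cross-scan RMSE
        of the benchmark data (a few Pa at Re 1000, tens of Pa at Re 2000).
    anisotropy:
        Relative IVSD magnitudes per phantom axis; (1, 1, 1) is isotropic.
    """

    total_tke: float | None = None
    peak_location_d: float = 2.0
    axial_width_d: float = 2.0
    extent_d: float = 6.0
    core_fraction: float = 0.35
    shear_width_fraction: float = 0.6
    anisotropy: tuple[float, float, float] = (1.0, 1.0, 1.0)


def turbulence_field(
    geometry: PhantomGeometry,
    condition: FlowCondition,
    grid: GridSpec | None = None,
    tke_params: TurbulenceParameters = TurbulenceParameters(),
    base: FlowField | None = None,
    jet_params: JetParameters = JetParameters(),
    fluid: FluidProperties = WATER_23C,
) -> FlowField:
    """Fill the IVSD field of a stenotic flow.

    IVSD is concentrated in the post-stenotic shear-layer annulus (tracking
    the widening jet edge) plus a weaker jet-core contribution, confined to
    X in [0, extent_d]. The field is rescaled so the volume integral of
    rho/2 * sum(IVSD_i^2) equals the TKE target exactly.

    When ``base`` is given (a mean-velocity FlowField on the same grid) the
    returned field carries its mean velocity; otherwise the mean velocity
    field is generated first.
    """
    target = tke_params.total_tke
    if target is None:
        target = default_total_tke(condition.volume_flow_rate)
    if not target > 0:
        raise ValueError(f"total TKE target must be positive, got {target}")

    if base is None:
        base = mean_velocity_field(geometry, condition, grid, jet_params, fluid)
    grid = base.grid
    mask = base.lumen_mask

    x = grid.axis_centers(0)
    X = geometry.x_to_diameters(x)
    y = grid.axis_centers(1)[None, :, None]
    z = grid.axis_centers(2)[None, None, :]
    r = np.sqrt(y**2 + z**2)[0]  # (ny, nz)
    D = geometry.inner_diameter
    r_j0 = geometry.minimum_radius

    env = np.exp(-0.5 * ((X - tke_params.peak_location_d) / tke_params.axial_width_d) ** 2)
    env = np.where((X >= 0.0) & (X <= tke_params.extent_d), env, 0.0)

    mag = np.zeros(grid.shape)
    for i, Xi in enumerate(X):
        if env[i] == 0.0:
            continue
        r_j = jet_radius(geometry, jet_params, Xi)
        w_s = max(tke_params.shear_width_fraction * r_j0, 0.5 * grid.voxel_size)
        shear = np.exp(-(((r - r_j) / w_s) ** 2))
        core = tke_params.core_fraction * np.exp(-((r / r_j) ** 2))
        mag[i] = env[i] * (shear + core)
    mag = np.where(mask, mag, 0.0)

    a = np.asarray(tke_params.anisotropy, dtype=float)
    if np.any(a < 0) or not np.any(a > 0):
        raise ValueError(f"anisotropy must be non-negative with a positive entry, got {a}")
    a = a / np.sqrt(np.mean(a**2))  # unit RMS so the budget is direction-neutral
    ivsd = a[:, None, None, None] * mag[None]

    # Rescale so the integrated TKE hits the target exactly.
    tke = 0.5 * fluid.density * np.sum(ivsd**2, axis=0)
    total = float(np.sum(tke) * grid.voxel_volume)
    if total <= 0:
        raise ValueError("generated turbulence field is empty; check the grid extent")
    ivsd *= np.sqrt(target / total)

    return replace(base, ivsd=ivsd)


def static_offset_field(
    grid: GridSpec,
    amplitude: float = 0.05,
    smoothness: float = 15e-3,
    seed: int = 0,
) -> np.ndarray:
    """Slowly varying background velocity-offset field (3, nx, ny, nz), m/s.

    Emulates residual eddy-current/phase offsets that the pump-off scan is
    acquired to remove: Gaussian-correlated noise with spatial correlation
    length ``smoothness`` (m), scaled so the largest offset magnitude equals
    ``amplitude`` (m/s). Deterministic under ``seed``.
    """
    if amplitude < 0:
        raise ValueError(f"amplitude must be non-negative, got {amplitude}")
    if amplitude == 0:
        return np.zeros((3, *grid.shape))
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((3, *grid.shape))
    sigma_vox = max(smoothness / grid.voxel_size, 1e-6)
    smooth = np.stack([gaussian_filter(c, sigma=sigma_vox, mode="nearest") for c in raw])
    peak = np.max(np.abs(smooth))
    if peak == 0:
        return smooth
    return smooth * (amplitude / peak)
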