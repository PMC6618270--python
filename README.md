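# stenoflow

Simulation and quantification of turbulence and velocity in stenotic flow
with three-dimensional, three-directional phase-contrast MRI (4D flow MRI),
comparing stack-of-spirals and Cartesian acquisitions.

Stenotic flow — a high-velocity jet with backflow and a turbulent shear
layer — is hard ground for PC-MRI: turbulence destroys signal through
intravoxel phase dispersion, and fast spins are spatially misregistered
because each image axis encodes position at a different time than the echo.
Spiral readouts start at the k-space center and reach a much shorter echo
time (TE), which should roughly halve the misregistration and cut scan time
several-fold. `stenoflow` provides a tested, desk-scale model of this
comparison for method developers and students of 4D flow MRI:

* a **synthetic flow phantom**: a 14.6 mm rigid pipe with a 75% area-reduction
  stenosis carrying steady water flow (10–112 mL/s, Re ≈ 1000–11000), with a
  parametric jet/backflow mean-velocity field that satisfies continuity
  exactly and a ground-truth intravoxel velocity standard deviation (IVSD)
  field with a prescribed total turbulent kinetic energy;
* a **PC-MRI signal simulator**: referenced four-point velocity encoding
  (kv = π/VENC), Gaussian-IVSD magnitude loss, trajectory-dependent
  displacement artifacts (Cartesian vs stack-of-spirals encoding times,
  COR/TRA/OBL orientations), complex noise and signal averaging, plus a
  slew/amplitude-constrained Archimedean spiral readout designer;
* **reconstruction**: phase-difference velocity maps with pump-off offset
  correction (aliasing surfaced, not unwrapped);
* **quantification**: IVSD from signal loss, per-voxel TKE

      TKE = ρ/2 · (IVSD_X² + IVSD_Y² + IVSD_Z²)   [J/m³ ≡ Pa],

  total TKE integrated over X ∈ [0, 6] diameters downstream of the throat,
  Gaussian-smoothed maximum velocity, through-plane flow-rate profiles,
  centerline interpolation, regridding and cross-scan RMSE;
* a **study runner** that executes the trajectory × orientation × flow-rate
  matrix deterministically and exports CSV/JSON/NIfTI reports, with a
  scan-duration model over the published protocol table.

## Worked example

```python
import numpy as np
import stenoflow as sf

geometry = sf.build_geometry()                   # 14.6 mm pipe, 75% stenosis
condition = sf.flow_condition(20e-6, geometry)   # 20 mL/s -> Re ~ 2000
flow = sf.turbulence_field(geometry, condition)  # ground-truth u + IVSD

config = sf.AcquisitionConfig.from_protocol(
    "stack_of_spirals", "TRA", venc_cm_s=35,     # turbulence-mapping VENC
    noise_sigma=1/30, averages=3, seed=7,
)
signals = sf.acquire(flow, None, config)
recon = sf.velocity_from_phase(signals)

seg = sf.segment_lumen(geometry, flow.grid)
ivsd, info = sf.ivsd_from_magnitude(signals)
tmap = sf.tke_from_ivsd(ivsd, 997.0, flow.grid, info["n_clamped"])

print(f"Reynolds number:        {condition.reynolds_number:.0f}")
print(f"nominal jet speed:      {condition.nominal_jet_speed:.2f} m/s")
print(f"generator total TKE:    {flow.total_tke():.3e} J")
print(f"estimated total TKE:    {sf.total_tke(tmap, seg, geometry):.3e} J")
print(f"peak TKE density:       {np.nanmax(tmap.tke[seg.mask]):.1f} Pa")
prof = sf.flow_rate_profile(recon, seg, [-1.5, 7.0], geometry)
print(f"flow rate at X=-1.5/7:  {1e6*prof.flow_rate[0]:.1f} / {1e6*prof.flow_rate[1]:.1f} mL/s")
```

prints

```
Reynolds number:        1954
nominal jet speed:      0.48 m/s
generator total TKE:    9.560e-05 J
estimated total TKE:    9.943e-05 J
peak TKE density:       24.5 Pa
flow rate at X=-1.5/7:  19.7 / 19.6 mL/s
```

The generator placed 9.56·10⁻⁵ J of turbulent kinetic energy in the
post-stenotic region; the simulated low-VENC scan at SNR 30 recovers it
within a few percent, and the flow rate measured away from the jet matches
the pump setting of 20 mL/s within noise. X is the axial distance from the
stenosis center in pipe diameters.

A command-line interface mirrors the library
(`stenoflow simulate | acquire | recon | quantify | study | report`);
`stenoflow study --out results/` runs a small scan matrix and writes the
report tables and profiles.

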