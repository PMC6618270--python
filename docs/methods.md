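# Methods

`stenoflow` is a desk-scale model of an in vitro comparison between
stack-of-spirals and Cartesian three-dimensional, three-directional
phase-contrast MRI (PC-MRI) of stenotic flow. It has four layers: a synthetic
flow phantom, a multi-point complex-signal simulator, a phase-difference
reconstruction, and the quantification chain (turbulent kinetic energy,
maximum velocity, flow rate, centerline profiles, cross-scan RMSE). This note
records the models, their assumptions, the defaults and why, and what the
synthetic data does and does not establish.

## The phantom and flow model

The phantom is a straight rigid pipe (inner diameter D = 14.6 mm) with an
axisymmetric, cosine-tapered constriction of length 1 D removing 75% of the
lumen area, so the throat radius is R·√(1−0.75) = 3.65 mm. Severity is
defined by area, not diameter. The working fluid is water at 23 °C
(ρ = 997 kg/m³, μ = 8.899·10⁻⁴ kg m⁻¹ s⁻¹). The normalized axial coordinate
X counts diameters downstream of the throat; the principal flow direction is
+X. Steady flow rates of 10, 20, 56 and 112 mL/s give pipe Reynolds numbers
ρ(Q/A)D/μ of ≈ 977, 1954, 5471 and 10941 and plug-flow jet speeds Q/A_min of
≈ 0.24, 0.48, 1.34 and 2.68 m/s.

The mean velocity field is parametric, not a Navier–Stokes solution:

* upstream: Poiseuille profile carrying Q;
* through and beyond the throat: a plug-like super-Gaussian jet
  u ∝ exp(−(r/r_j)⁶). A smooth converging–diverging constriction has a
  contraction coefficient near one, so the emerging plug carries roughly the
  throat area: the shoulder radius starts at 1.15·r_min and widens linearly
  (entrainment spread rate 0.08 per unit length) — with this choice the jet
  peak is ~1.2× the plug-flow speed, consistent with measured stenotic maxima
  slightly above nominal;
* a recirculating annulus between jet shoulder and wall (peak backflow 20% of
  the local centerline speed) — the jet in this geometry is surrounded by
  backflow across a turbulent shear layer;
* a potential core of 1.5 D, exponential centerline decay (e-folding 2 D)
  relaxing to a developed parabolic profile.

Transverse mean-velocity components are neglected. Every axial voxel plane is
rescaled so its discrete through-plane flux equals Q exactly; continuity
therefore holds to machine precision on the generation grid, and flow-rate
quantification closes exactly in the noise-free, displacement-free limit.

Turbulence is represented as a per-voxel intravoxel velocity standard
deviation (IVSD) field, concentrated in the shear-layer annulus that tracks
the jet shoulder plus a weaker jet-core term (35%), with a Gaussian axial
envelope (peak at X = 2, width 2 D) truncated to X ∈ [0, 6]. The field is
rescaled so that the volume integral of ρ/2·Σᵢ IVSDᵢ² equals a prescribed
total (J) exactly. Default totals are anchored to bench measurements at the
two turbulence-mapped rates — 2.08·10⁻⁵ J at 10 mL/s and 9.56·10⁻⁵ J at
20 mL/s — and scale with Q² elsewhere. The spatial spread is calibrated so
the peak TKE density is a few Pa at Re ≈ 1000 and a few tens of Pa at
Re ≈ 2000, matching the benchmark's observation that cross-scan RMSE
(≈ 0.4–3.2 Pa) was about a tenth of the maximum TKE; a much more concentrated
field would drive the low-VENC scan into deep signal-loss saturation.
IVSD anisotropy is configurable per axis; the default is isotropic, and total
TKE (the trace of the velocity covariance) is invariant under the encoding
rotation either way.

Static velocity offsets (eddy-current-like) are modeled as Gaussian-correlated
random fields with a 15 mm correlation length, scaled to a chosen peak
amplitude (default 0.05 m/s), deterministic under a seed.

## Signal model and acquisition simulation

A referenced four-point encoding is assumed: one segment with kv = 0 and one
per encoding axis with |kv| = π/VENC (phase π at v = VENC). For a Gaussian
intravoxel velocity distribution with mean u and per-axis spread σ, the voxel
signal is

    S = s₀ · exp(i kv·u) · exp(−Σₐ kvₐ² σₐ² / 2),

so turbulence attenuates magnitude and mean velocity sets phase. The scan
orientations map encoding axes (frequency, phase, slice) onto phantom axes:
COR puts the frequency/readout axis along the flow, TRA the slice axis, OBL
rotates frequency and slice 45° to the flow.

Displacement (spatial misregistration) is modeled in the image domain:
position along axis a is encoded at time t_enc,a, so signal from spins moving
at v appears shifted by vₐ·(TE − t_enc,a). Cartesian readouts encode the
frequency axis at the echo and the phase/slice axes effectively at excitation
(t_enc = 0 by default, configurable); a stack of spirals starts its readout
at the k-space center, so both in-plane axes are encoded at its (shorter)
echo and only the through-plane axis early. The artifact magnitude is then
proportional to TE for axes encoded early, which is what makes the spiral
sequence's half-length TE halve the misregistration. No Bloch/k-space
simulation is performed; this captures the TE-proportional mechanism at desk
scale.

Each lumen voxel is split into 2³ spin packets. Packets sample the
mean-velocity field trilinearly at sub-voxel positions — so a sheared voxel
produces a spread of displacements and phases (a broadened point-spread
function for moving spins) — but inherit their parent voxel's IVSD (the
ground-truth turbulence is defined per voxel) and deposit at the parent voxel
center plus their own shift with trilinear splatting. A static object is
therefore imaged exactly (no splat blur), total deposited signal is conserved
up to what leaves the field of view, and the noise-free displacement-free
acquisition inverts exactly. Complex Gaussian noise is added per channel
relative to the mean lumen magnitude; signal averages are combined
coherently (noise ∝ 1/√averages). Ghosting, off-resonance, relaxation,
concomitant gradients and SENSE are out of scope.

The spiral readout designer integrates an Archimedean interleave
k(θ) = c·θ·e^{iθ} (c chosen for full-FOV Nyquist spacing across interleaves)
greedily under gradient-amplitude (33 mT/m) and slew-rate (180 T/m/s) limits
until k_max = matrix/(2·FOV). The discrete controller tolerates a few percent
first-order overshoot of the slew limit at its accelerate/decelerate
transitions (shrinking with the 4 µs time step). It justifies the encoding-
time defaults and scan-time ordering; it does not claim to reproduce the
printed interleave durations (8.5 ms designed vs 5.5 ms printed at 15
interleaves), which enter only as printed constants in timing-ratio checks.

## Reconstruction and quantification

Velocity is reconstructed per direction as arg(S_d·conj(S₀))/kv, rotated to
phantom axes; magnitude is |S₀|. No unwrapping is applied: components outside
(−VENC, +VENC] alias, as expected for low-VENC turbulence scans of a jet.
Offset correction subtracts a spatially smoothed pump-off velocity map; the
smoothing is magnitude-weighted (normalized convolution) so background voxels
without signal do not drag the estimate near the lumen wall, and constants
are preserved exactly.

IVSD is inverted from magnitude loss, σ_d = √(2 ln(|S₀|/|S_d|))/kv, clamped
to zero where noise makes |S_d| ≥ |S₀| (the clamped count is reported) and
flagged missing where the reference is empty. Per-voxel TKE is
ρ/2·(σx²+σy²+σz²) in J/m³ (numerically Pa); total TKE integrates over the
true-radius segmentation between X = 0 and X = 6 (mask and window
configurable) and is reported in J. Because Σσ_d² measured along any
orthonormal encoding triad equals the trace of the velocity covariance, total
TKE is orientation-consistent by construction.

Maximum velocity is the peak of the Gaussian-smoothed speed inside the
segmentation. "Five voxels wide" is read as total kernel support, σ = 5/4 =
1.25 voxels: with the inner diameter spanning 9.7 voxels and the throat
radius 2.4 voxels, a kernel whose FWHM were 5 voxels would halve a stenotic
jet's peak, which is inconsistent with bench maxima landing at the nominal
jet speed; width and σ are configurable. Flow rate sums the axial velocity
over masked pixels of a cross-sectional plane (planes snapped to the nearest
voxel plane); centerline profiles are trilinear; regridding between scan
grids is trilinear with out-of-FOV voxels flagged missing and excluded from
the RMSE.

## Numerical choices and degenerate inputs

Zero flow rate yields an identically zero field (the per-plane normalization
is skipped). Grids coarser than 4 voxels across the lumen are rejected.
Anisotropy vectors are RMS-normalized so the TKE budget is direction-neutral.
σ inversion uses a floor of 1e−300 on magnitudes to avoid divide-by-zero
before flagging. The displacement-free acquisition path bypasses splatting
entirely and is exact by construction. Per-scan seeds in the study runner are
derived deterministically from the global seed; identical configurations
reproduce byte-identical reports.

## Problem sizes

The default grid is 1.5 mm isotropic (the benchmark voxel size), X ∈ [−2, 8]
diameters with a 39 mm transverse field of view: 98×26×26 voxels, ~7100 lumen
voxels, ~57 000 spin packets per segment. One four-segment acquisition takes
well under a second on one core; the full test suite and the acceptance
script each run in seconds. Stochastic estimates in the acceptance script
average 3 seeds at a noise level of 1/30 of the lumen magnitude with 3–5
signal averages, mirroring the benchmark's SNR-boosting averaging.

## What the synthetic data does not show

The phantom flow is a parametric stand-in, not CFD: jet shape, backflow
amplitude and turbulence geometry are plausible but not validated against the
bench or LES fields, so voxel-level agreement with the benchmark's absolute
TKE maps or its exact maximum velocities is not claimed — recovery tests
establish that the *pipeline* is unbiased with respect to its own ground
truth, that scan pairs agree across trajectory and orientation, and that
displacement scales with TE; they do not validate the hemodynamics.
Pulsatile flow, non-Newtonian rheology, partial-volume effects of a
signal-free wall, susceptibility and view-to-view ghosting are all absent.
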