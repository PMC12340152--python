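# Methods

This note documents the models implemented in `liquidstem`, the
conventions and parameter choices behind them, what the synthetic data
does and does not emulate, and the package's known limitations.

## Conventions

Volumes are numpy arrays in (z, y, x) order, 0-based, image origin at the
top-left array corner. The tilt axis is the image y axis; positive tilt
follows the right-hand rule about y, implemented as a rotation of the
specimen in the (z, x) plane while the beam stays along z. Angles are
degrees at every public interface and radians internally. Lengths are nm
throughout the simulation stack; the eucentric model itself is
unit-agnostic (stage practice uses µm, the simulations here use nm).
Shift vectors follow numpy (row, col) order.

## Eucentric model and fit

The displacement of a feature at lateral offset y_A and height z_A from
the tilt axis, with stage error-motion radius R and free baseline a0, is

    a(θ) = a0 + R(1 − sin θ) + y_A(1 − cos θ) + z_A sin θ.

The error-motion form reduces exactly to the ideal-stage form at
R = a0 = 0; we adopted this additive composition as the only reading under
which that reduction holds. The model is linear in {1, 1−cos θ, sin θ}
with coefficients (a0 + R, y_A, z_A − R), so the fit is ordinary
(unweighted) linear least squares — no iterative optimizer is needed, and
noise-free data is recovered to machine precision. The constant basis
function conflates a0 and R: R is therefore only reported with a0 pinned
to 0, a documented identifiability limitation of the model itself. The
fitted displacement is the image-x component (perpendicular to the tilt
axis); the y component of measured shifts is carried for diagnostics but
excluded, since the model predicts no motion along the tilt axis.

Parameter sensitivity: over a ±20° calibration ramp, (1 − cos θ) ≤ 0.06
while |sin θ| ≤ 0.34, so y_A is constrained ~6× more weakly than z_A by
the same measurement noise. Wider ramps tighten y_A quickly.

## Predictive drift controller

The recurrence (c_0 = a_0 = 0)

    c_n = c_{n−1} − d_n,   a_n = a_{n−1} + c_n,   r_n = a_n + c_n

emits an *incremental* beam shift r_n, accumulated into the applied
correction B_n = B_{n−1} + r_n; frame n+1 is acquired at position
p_{n+1} = D_{n+1} + B_n, where D is the true cumulative drift. This
incremental reading is the design choice that makes the closed-loop
algebra work out: for constant-rate drift the full controller gives
p_n = 0 for all n ≥ 2 (exactly — a property test verifies it over random
slopes), a correction-only loop (r_n = −d_n) diverges linearly, and
correction+memory (r_n = c_n) tracks with a constant one-slope lag.
Expanding the recurrence gives the identity r_n = a_{n−1} + 2c_{n−1} −
2d_n, which is also property-tested; an alternative expansion with
d_{n−1} in place of d_n is inconsistent with the recurrence and was not
used. All accumulators run in pixels; conversion to physical units is a
single multiplication by the pixel size at the controller boundary.

Drift scenarios: linear (constant slope), segment-wise linear (slope
changes at breakpoints; the controller re-settles within 3 frames of each
break), quadratic (D_n = c·n², default c = 0.02 px/frame², chosen to span
the qualitative square-law regime), and zero. Process noise is i.i.d.
uniform on [−0.5, 0.5] px added to each per-frame increment — the noisy
regime under which corrected positions occasionally exceed the ±1 px
acceptable zone but stay inside it >80% of frames.

Shift estimation defaults to phase correlation: frames are demeaned,
Hann-windowed (demeaning first, otherwise the DC term swamps the
correlation peak on smooth low-contrast frames), and refined to subpixel
precision by upsampled cross-correlation (factor 50, ~0.02 px). Feature
matching (SIFT keypoints, cross-checked ratio-test matches, median
displacement) is available as the alternative backend; it raises on
feature-poor frames rather than returning a low-confidence number.

Focus is scored as the variance of a Laplacian of a Gaussian-filtered
image (pre-filter σ = 1 px, 3×3 Laplacian); the score decreases strictly
with defocus blur and is 0 for a constant image. Astigmatism is the
ellipticity of the half-power contour of the smoothed log power spectrum,
measured by second moments of the contour region: ratio ≥ 1 and
major-axis angle. Closed-loop focus/astigmatism *correction* is out of
scope; only the metrics are provided.

## Virtual microscope

Projections are parallel-beam line integrals: the volume is rotated in
(z, x) by −θ (linear interpolation) and summed along z. Voxel density is
attenuation per voxel of path, so a noise-free projection is the plain
z-sum. Dose-limited noise draws pixel counts from Poisson with mean
N₀·exp(−line integral), N₀ = I·t/e electrons per pixel (Beer–Lambert,
detector gain 1 count/electron; bright/annular-dark-field contrast
inversion is not modelled). The eucentric offset shifts the projection
along x by a(θ)/pixel-size; drift adds a (row, col) offset. The SART
reconstruction uses this same projector, so reconstruction tests isolate
algorithmic error from geometry mismatch.

Phantoms:

* **beads** — solid spheres (CSR or Thomas cluster process) with centers
  and radius as ground truth; `thickness_nm` confines centers to a slab
  around the mid-plane, the membrane-supported geometry that keeps content
  near the eucentric plane. This matters for closed-loop acquisition:
  content spread through depth parallaxes between consecutive tilt
  angles, the shift estimator reports that parallax as drift, and the
  anticipating controller integrates the error. A tracked ROI at the
  eucentric plane is an operating assumption of the real instrument, and
  the simulations respect it.
* **gel** — solid matrix minus non-overlapping spherical pores, radii
  uniform in a given range (default diameters 5–30 nm), pores added until
  the analytic pore volume reaches the target porosity; the voxelized
  porosity must land within 20% relative of the target.
* **bacterium** — helical spirillum body (cytoplasm density 0.3), a chain
  of dense magnetosomes (1.0) strung along the backbone, and off-chain
  storage-granule inclusions (0.6); everything annotated.
* **calibration** — an axisymmetric texture (density a function of y and
  radius about the tilt axis only), for which tilting changes nothing but
  the imposed displacement; used to validate the renderer/calibration
  round trip without content parallax.

Sphere placement uses bounded rejection sampling (1000 retries per
object); infeasible packings raise rather than silently overlap, and an
`allow_overlap` flag exists for dense bead phantoms.

Hydration follows the Magnus form of the dew curve,
P_sat(T) = 6.1094·exp(17.625·T/(T + 243.04)) hPa for T ∈ [−40, 60] °C
(constants fixed so tests are exact). The regime is condensation above
P_sat + tol, evaporation below P_sat − tol, else stable (tol default
0.1 hPa, the pressure-regulation tolerance of the operating point
8.0 hPa / 1 °C). The guard only gates acquisition — water-layer thickness
physics and electron-scattering transparency are out of scope.

## Quantification

**SART**: per-angle updates x ← x + λ·BP((b − Ax) ⊘ ray-sums), λ = 0.25,
non-negativity clipped after every angle, angles swept in acquisition
order, 15 iterations by default; optional FISTA (Nesterov) extrapolation
between sweeps. Frames holding Poisson counts are converted to line
integrals by −log(counts/N₀) with counts clipped at 1.

**FSC**: shells one reference-voxel frequency unit wide; correlation
Re⟨AB*⟩/√(⟨|A|²⟩⟨|B|²⟩) per shell. Resolution at a criterion is the
reciprocal of the first crossing, linearly interpolated between shell
centers; a curve that never crosses returns the Nyquist-limited value
with a flag. No masking or apodization by default. Null statistics: with
n Fourier samples per shell the no-signal FSC has variance ≈ 2/n
(Hermitian symmetry), so low-order shells of small volumes fluctuate well
beyond ±0.2; tests and the acceptance script restrict null assertions to
shells with ≥ 450 samples, where 0.2 lies beyond 3σ.

**Bead detection**: Laplacian-of-Gaussian blob detection at scales
bracketing the expected radius (σ = r/√3 ± 40%), then intensity-centroid
refinement in a local window; centers returned in nm.

**g(r)**: translational edge correction — each pair weighted by
V/∏(Lᵢ − |Δᵢ|) — with λ² → n(n−1)/V² normalization so CSR gives g → 1;
periodic boundaries available for synthetic exactness. r_max is capped at
half the shortest box edge. The production estimator is verified exactly
(1e−15) against an O(n²) explicit-loop oracle. The CSR envelope is the
pointwise min/max of g over 99 uniform realizations by default (19 is the
minimum accepted, the 5% pointwise level of a one-sided max test); global
rank envelopes are out of scope.

**Pore sizes**: local thickness — each pore voxel gets the diameter of
the largest inscribed sphere containing it. Computed exactly on radii
quantized down to 0.5 voxel: for each level r (descending), the covered
set is the exact Euclidean dilation (via distance transform) of
{EDT ≥ r} by a ball of radius r. Downward quantization makes the map
monotone under dilation of the mask by construction. The histogram is
pore-volume-weighted with bins in nm; total porosity is the pore-voxel
fraction.

**Volume change**: 100·(V_b − V_a)/V_a on segmented voxel masks
(negative = shrinkage), with the linear-equivalent isotropic change
100·((V_b/V_a)^{1/3} − 1) reported alongside, since a volumetric and a
linear reading of a printed shrinkage percentage differ by ~3×.
Segmentation thresholds are the caller's responsibility.

## Problem sizes and study conditions

The simulated studies run at desk scale, chosen once: 64³ voxel volumes
(2 nm voxels, 128 nm box), 25-bead slab phantoms, ±60° plans at 2° (61
frames) for end-to-end runs, 15 SART iterations, 99-realization
envelopes on 250-point patterns, and 100-seed Monte Carlo for noisy
calibration recovery. Beam defaults reproduce the documented ESEM
operating point (8.72 pA backed out of the 9 e⁻·nm⁻² per-image dose at
5 µs dwell and 5.5 nm pixels — the current itself is an input the
instrument does not print). Two bookkeeping discrepancies in the source
operating figures are noted and not reproduced: a −60..60° @ 0.5° closed
plan has 241 angles (242 images implies one extra frame), and an
active-dwell dose rate at the 1 µs/1024² operating point computes to
58 e⁻·nm⁻²·s⁻¹ (a printed 40 implies overhead-inclusive timing; the rate
here is defined on active dwell only, which reproduces the 1.1 figure at
the other operating point).

## What passing tests do and do not show

The phantoms exercise geometry, statistics and the control loop with
exactly known ground truth, Poisson-limited noise, and drift processes
with clean functional forms. They do not emulate charging, beam damage,
contrast inversion between thick and thin regions, membrane flutter,
focus drift coupling, or water-layer thickness variation — so green tests
demonstrate correctness of the algorithms under their stated models, not
instrument-grade robustness. Experimental resolutions and
shrinkage/expansion figures from real tomograms are not reproducible
without the raw data and are covered by property tests on constructed
volumes instead.
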