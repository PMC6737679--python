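# Methods

This note documents the models, numerical choices and known
limitations of `breastdeform`, in the order of the pipeline.

## Synthetic cohort

The cohort sampler draws five latent variables per subject — age,
breast volume, whole-breast percent density, local percent density and
the reported shear-wave stiffness — from a single multivariate normal
with configurable means, SDs and pairwise correlations. Defaults:

| variable | mean ± SD | source of default |
|---|---|---|
| age | 51.7 ± 13.5 y | mean printed; SD from the 24–78 y range (range/4) |
| breast volume | 584.4 ± 170.4 cm³ | printed |
| FGT volume | 72.7 ± 31.3 cm³ | printed (derived, see below) |
| whole percent density | 13.1 ± 5.8 % | printed |
| local percent density | 30 ± 15 % | chosen: case reports run ~2× whole density |
| stiffness | 2.3 ± 0.8 m/s | printed |
| ROI depth | 1.41 ± 0.38 cm | printed |

FGT volume is not an independent latent: the record must satisfy
`whole_density = 100 · FGT / volume`, so `FGT := density·volume/100`.
Its mean is then `(μ_d μ_v + ρ σ_d σ_v)/100`, which forces the
volume–density correlation: `ρ = (100 μ_FGT − μ_d μ_v)/(σ_d σ_v) =
−0.390` with the defaults. A negative value is also the physiological
expectation (smaller breasts tend to be denser). Correlations supplied
by the study are used directly (age–density −0.56, age–stiffness 0.29,
volume–stiffness −0.14, whole-density–stiffness −0.09,
local-density–stiffness −0.12); the remaining pairs are completed by a
product rule through whole density (age–local = −0.28, volume–local =
−0.195) and the matrix is projected to the PSD cone by eigenvalue
clipping (`nearest_psd`; the default matrix is already positive
definite, minimum eigenvalue 0.284, so the projection is the identity).

Marginals are untruncated normals except: stiffness is clipped below at
0.1 m/s, densities are clipped into [0, 100] % and ROI depth below at
0.05 cm. The density clip fires on ~1.2 % of draws and moves the mean
by +0.02 percentage points — negligible against every tolerance used.

**Stiffness repeats.** Each subject carries k ∈ {3, 4, 5} repeats
(probabilities 0.7/0.15/0.15 — most patients were measured at three
locations). The reported stiffness is one specific ROI's measurement,
so the multivariate-normal draw *is* the reported value; the other
repeats are generated around it as `s·(1+ε)`, ε ~ N(0, σ_i). The
per-subject target CV is gamma-distributed (shape 2, mean 12.7 %),
giving the right-skewed spread seen in practice (roughly 1–40 %). σ_i
is inflated by `(1 + 1/(4k))` (small-sample bias of the sample SD) and
by `1/sqrt(1 − 1/k)` (the reported repeat carries no noise), so the
cohort-mean sample CV matches the configured mean in expectation. The
reported repeat is selected by a per-repeat "dense-tissue appearance"
score tied to local density and independent of the measurement noise;
because the selection is noise-independent it does not bias the
reported stiffness. Modeling the reported value as the latent (rather
than as a noisy repeat of a latent) keeps the configured correlations
unattenuated; with the alternative all stiffness correlations would
shrink by ~11 % from repeat-noise inflation of the variance.

## Phantom

The breast is a hemiellipsoid (default semiaxes 60 × 70 × 60 mm,
≈ 528 cm³) seated on a posterior chest slab. The fibroglandular core is
a concentric ellipsoid centred a quarter of the anterior semiaxis in
front of the chest wall, scaled by bisection until the FGT voxel
fraction is within 0.5 points of the target density; the core is capped
at 0.85× the breast semiaxes so a subcutaneous fat rim always remains
(targets above ≈ 60 % therefore raise an error naming the achievable
range). Intensities are piecewise constant (fat 400, FGT 150, chest
180 — a T1-weighted-like contrast with bright fat), multiplied by a
smooth degree-2 polynomial bias field (default ±20 %) and degraded with
additive Gaussian noise. Voxel centers sit at (i + ½)h so that flat
interfaces never coincide with the sampling lattice (otherwise the
base layer double-counts half a voxel layer and the analytic-volume
check drifts by ~2 %). The nipple is the anterior-most surface voxel
on the mid-sagittal slice.

What the phantom does **not** emulate: Rician noise, coil-profile
shapes beyond a low-order polynomial, lobulated FGT texture, skin, or
pectoral muscle anatomy. Passing segmentation tests on phantoms shows
the algorithmic chain is correct, not that it matches clinical
variability.

## Segmentation

Foreground is intensity above 10 % of the robust maximum, reduced to
the largest connected component. The chest is removed either with a
supplied 3D mask or by propagating a mid-slice chest boundary: per
lateral column the chest extends to a boundary depth, each slice
initialized from its neighbour, sweeping superiorly and inferiorly.

Bias correction fits a degree-2 polynomial to **class-residual**
log-intensities: each outer iteration (5 total) classifies current
intensities with fuzzy C-means, fits the polynomial to
`log I − log c_class`, and divides it out. A plain fit to log-intensity
would absorb the dark fibroglandular core into the "bias" and destroy
the tissue contrast — with the coupled fit the recovered field
correlates > 0.99 with the ground-truth field on biased phantoms.

Fuzzy C-means runs on intensities with c = 2 classes and fuzzifier
m = 2; centers are initialized at evenly spaced quantiles, so the
algorithm is deterministic. Convergence: max center shift below 1e-4 of
the intensity range, at most 200 sweeps. FGT voxels are those whose
winning membership belongs to the darker class on T1-weighted-like
data (`fat_is_bright=True`; the polarity is configurable). The whole
chain is invariant to positive rescaling of the image.

## Meshing

The breast surface comes from marching cubes at level 0.5 on the
one-voxel-smoothed mask (raw binary isosurfaces overestimate area by
~10 % through staircasing). The interior is tetrahedralized by Delaunay
over coarsened surface vertices plus a jittered interior lattice at the
target edge length (default 8 mm → ≈ 7000 elements on a 530 cm³
breast), culling tetrahedra whose centroids fall outside the surface;
containment uses a voxelized flood fill from the domain border.
Slivers (altitude < 0.15× target edge) are removed — they carry
near-zero volume but would collapse the explicit solver's stable time
step. Each element is labeled fat/FGT by majority vote of the voxel
labels at its vertices and centroid, counting only sample points inside
the breast mask. Nodes within ~⅓ edge length of the posterior chest
plane are fixed. Mesh volume agrees with the enclosed surface volume to
~2–3 % at the default resolution and changes < 1 % under edge halving.

## Finite-element solver

Total-Lagrangian formulation on linear tetrahedra with the compressible
neo-Hookean energy `Ψ = μ/2 (J^{-2/3} I₁ − 3) + K/2 (J−1)²`, second
Piola–Kirchhoff stress `S = μ J^{-2/3}(I − I₁/3 C⁻¹) + K J(J−1) C⁻¹`
(verified against finite differences of Ψ to 1e-10). Static equilibrium
under the gravity body force is reached by dynamic relaxation:
central-difference integration with lumped mass, mass-proportional
damping near-critical for the estimated lowest shear mode, a linear
load ramp over the first 1500 steps, and a CFL time step
`Δt = 0.3 · h_min / c_p` from the smallest element altitude and the
fastest dilatational wave speed. Convergence requires the peak residual
force below 1e-4 of the total gravity load **and** the peak nodal speed
below 1e-6 m/s. The integration loop is compiled with numba; the
element arithmetic is duplicated in plain numpy and the two routes are
asserted equal in the tests. Element inversion (det F ≤ 0) aborts the
solve with the element index.

**Material constants.** The study's printed 3400 Pa (fat) and
50 000 Pa (fibroglandular) are taken, per their wording, as **bulk
moduli** K, with Poisson ratio ν = 0.45 by default and shear modulus
derived as `μ = 3K(1−2ν)/(2(1+ν))`. This reading is documented
prominently because the cited elastography literature may intend
Young's moduli: with K fixed at a few kPa, gravity-scale stresses
(~100 Pa mean tension in a hanging breast) produce a few percent of
*physical* volumetric strain regardless of ν, so "near-incompressible"
behaviour is impossible under this reading. `MaterialParams.from_youngs`
provides the alternative parameterization (E printed, K = E/(3(1−2ν))),
under which ν = 0.49 gives genuine near-incompressibility; the
volume-preservation verification (< 2 % change under prone gravity)
runs in that regime. Density is 1000 kg/m³ for both tissues and
g = 9.81 m/s²; neither is printed in the study.

Verification: a slender fixed-base column under self-weight matches the
closed form `ρgL²/(2E)` within the 5 % verification tolerance; displacements scale as 1/E in the
small-strain limit; the solution field is equivariant under rigid
rotation of mesh, load and boundary to 1e-6 (with tightened
tolerances, since the default stopping rule leaves a ~1e-5 convergence
tail).

## Gravity pipeline

The unloaded shape is estimated by fixed-point iteration: from
candidate rest nodes X_k, simulate prone gravity to x_k and update
`X_{k+1} = X_k + α (X_obs − x_k)` (α = 1 with backtracking — halved
after three consecutive residual increases, failure below α = 0.05).
The iteration stops when the residual falls below 0.5 mm; on the
phantom the residuals decrease strictly and the recovered rest shape
reproduces a synthetic truth to better than the 0.5 mm tolerance.

"Breast depth" is operationalized as the distance (cm) from the chest
plane to the anterior-most node within 8 mm of the nipple's sagittal
line — the geometry of a supine ultrasound probe placement. Depth is
monotone non-increasing in the supine load factor λ, so the
ultrasound-matching stop condition is implemented as bisection on
λ ∈ [0, 1] to |depth − target| < 0.05 cm, each iterate a fully
converged static solve warm-started from the previous one. If full
inverse gravity still leaves the breast deeper than the target, λ = 1
is returned with a warning rather than extrapolating beyond 1 g. An
alternative reading of the original procedure — truncating a single
transient simulation when the depth first matches — would make the
result depend on damping and step size; the bisection formulation
targets the same condition with a well-defined static state.

Label warping maps each voxel center of the deformed volume through
the containing deformed tetrahedron's barycentric coordinates back to
the source configuration and samples the nearest-neighbour label. The
mesh surface and the voxel mask disagree by up to a voxel, so source
sampling uses a nearest-label fill; the rasterized warped volume then
matches the deformed mesh volume to < 3 %, and the warped FGT fraction
matches the prone fraction to < 3 points.

## ROI and local density

The elastography window (default 1.0 × 0.5 cm, not printed in the
study) is placed on the sagittal slice containing the nipple, centred
laterally on the nipple line, its top edge at the measured depth below
the skin along the gravity axis. Local percent density is the FGT
fraction of the **whole** box — non-breast voxels count in the
denominator, exactly as an area ratio read off an ultrasound window.
The measurement is 2D (single slice) by default, matching the "area"
definition; a volumetric variant is a trivial extension of
`local_percent_density` over multiple slices but is not enabled.
Whether the original "central slice" was sagittal or axial is not
stated; sagittal is the default and the axis is configurable.

## Statistics

Pearson's product–moment r with banding on |r|: < 0.3 none, 0.3–0.5
weak, 0.5–0.7 moderate, ≥ 0.7 strong. The banding rule is stated for
unsigned r in the source convention yet negative correlations are
discussed; |r| is the only reading under which a −0.56 association is
"moderate", so |r| it is. CV is `100·SD(n−1)/mean`. No multiple-testing
correction is applied (none was in the study design being emulated).
The cohort report (means ± SD, ranges, the five correlations, CV bins
at 10 %/20 %) is deterministic given the cohort table and invariant to
row order.

## Problem sizes and runtimes

Defaults are desk-scale by design: the test phantom is 48×40×48 at
2.5 mm (≈ 212 cm³ breast, ≈ 2000 elements at 9 mm edges), a converged
gravity solve takes a few seconds on one CPU, the full zero-gravity +
bisection chain under a minute, and the n = 5000 cohort with its report
under a second. The full-size default phantom (72×56×72 at 2 mm,
≈ 7000 elements) runs the same chain in a few minutes.

## Known limitations

- No skin membrane, no circumferential chest-wall stretching, no
  contact mechanics: the deformation is a two-tissue gravity model.
- Homogeneous isotropic neo-Hookean tissue; no Mooney–Rivlin or
  fiber-reinforced alternatives.
- Explicit dynamic relaxation only; no implicit Newton solver (large
  stiffness ratios simply cost more steps).
- The Delaunay-lattice mesher is deterministic and dependency-light but
  produces lower element quality than a dedicated mesher; quality is
  reported (minimum dihedral angle, minimum altitude) rather than
  optimized.
- The density-score rule selecting the reported stiffness repeat is a
  modeling choice; the emulated study states only that the densest ROI
  was used.
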