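# breastdeform

Breast MRI is acquired prone (the patient face down, the breast hanging
under gravity); ultrasound elastography is acquired supine. Relating a
stiffness measurement made at some depth under the skin on ultrasound
to the tissue seen on MRI therefore requires deforming the MR volume
from the prone to the supine configuration. `breastdeform` implements
that workflow end to end for researchers studying the relationship
between **shear-wave breast stiffness** (m/s) and **percent breast
density** (the volumetric fraction of fibroglandular tissue, FGT):

1. **Synthetic data** — breast MR phantoms with known tissue ground
   truth, and synthetic 20-subject-style cohorts whose moments and
   pairwise correlations are configurable (no patient data required).
2. **Segmentation** — chest exclusion, bias-field correction coupled to
   the tissue classification, fuzzy C-means fat/FGT separation, and
   whole-breast percent density `PD = 100 · V_FGT / V_breast`.
3. **Meshing** — marching-cubes surface extraction and Delaunay-based
   tetrahedralization with per-element tissue labels and a fixed
   posterior (chest-wall) boundary.
4. **FEM solver** — total-Lagrangian explicit dynamics with a
   neo-Hookean material,
   `Ψ = μ/2 (J^{-2/3} I₁ − 3) + K/2 (J − 1)²`,
   solved quasi-statically by damped dynamic relaxation. Default bulk
   moduli: fat 3400 Pa, fibroglandular tissue 50 000 Pa.
5. **Gravity pipeline** — fixed-point estimation of the unloaded
   (zero-gravity) shape from the prone mesh, then inverse-gravity
   loading with bisection on the load factor until the simulated breast
   depth matches the depth observed on ultrasound; the voxel labels are
   warped through the mesh displacement field.
6. **ROI density** — the elastography window (default 1.0 × 0.5 cm) is
   placed on the nipple slice of the deformed volume at the measured
   depth from skin, and local percent density is the FGT fraction of
   the box.
7. **Statistics** — Pearson correlations with the banding rule
   (|r| < 0.3 none, < 0.5 weak, < 0.7 moderate, ≥ 0.7 strong), the
   per-subject coefficient of variation of repeated stiffness
   measurements, and a cohort report.

## Worked example: cohort statistics

```bash
breastdeform simulate cohort --n 5000 --seed 1 --out cohort.csv
breastdeform correlate --cohort cohort.csv --out report.json
```

The report for this seed contains:

```
stiffness:              2.28 ± 0.79 m/s
breast_volume:        587.76 ± 169.16 cm³
fgt_volume:            74.04 ± 33.85 cm³
whole_percent_density: 13.25 ± 5.79 %
roi_depth:              1.41 ± 0.37 cm
r(stiffness~age)                   =  0.284  [none]
r(stiffness~breast_volume)         = -0.128  [none]
r(stiffness~whole_percent_density) = -0.109  [none]
r(stiffness~local_percent_density) = -0.139  [none]
r(whole_percent_density~age)       = -0.562  [moderate]
mean CV = 12.3 %   (2849 subjects < 10 %, 1260 in 10–20 %, 891 > 20 %)
```

i.e. the generator reproduces a cohort in which breast stiffness is
essentially uncorrelated with whole-breast or local density, while
density falls moderately with age.

## Worked example: phantom deformation

```python
from breastdeform import (PhantomSpec, generate_phantom, segment_breast,
                          mesh_from_masks, MaterialParams, run_gravity_pipeline,
                          warp_labels, measure_local_density)

spec = PhantomSpec(grid_shape=(48, 40, 48), voxel_size_mm=2.5,
                   breast_semiaxes_mm=(45, 50, 45), chest_slab_mm=15,
                   target_percent_density=13.1, seed=3)
ph = generate_phantom(spec)
seg = segment_breast(ph.image, ph.chest_mask)
# -> breast volume 212.1 cm^3, FGT 28.8 cm^3, density 13.6%

mesh = mesh_from_masks(seg.breast_mask, seg.fgt_mask, ph.image,
                       ph.chest_plane_y_mm, ph.nipple_location_mm,
                       target_edge_mm=9.0)
# -> mesh: 491 nodes, 2070 tets

stages = run_gravity_pipeline(mesh, MaterialParams(), target_depth_cm=4.5,
                              chest_plane_y_mm=ph.chest_plane_y_mm)
# -> depths {'prone': 4.87, 'zero_gravity': 4.65, 'supine': 4.52} cm,
#    stopped at load factor lambda = 0.75

labels = warp_labels(mesh, stages.prone_nodes, stages.supine_nodes,
                     ph.fgt_mask, ph.breast_mask, ph.image)
nip = stages.supine_nodes[mesh.nipple_node]
local = measure_local_density(labels, nip, depth_from_skin_cm=1.41)
# -> local percent density in the 1.0 x 0.5 cm ROI: 86.7%
```

The breast sags 2–3 mm anteriorly under prone gravity at these
stiffnesses; the bisection stops once the simulated supine breast depth
at the nipple line is within 0.05 cm of the requested ultrasound depth.
The high local density is expected: the ROI at 1.4 cm under the nipple
sits inside the phantom's retroareolar fibroglandular core.

An end-to-end multi-subject run (phantom → segmentation → mesh →
deformation → ROI measurement → cohort report) is available as
`breastdeform run --n 2 --seed 0 --out out/`.

## Conventions

World coordinates are in mm with +x right (sagittal slice axis),
+y anterior and +z superior; prone gravity acts along +y (away from
the chest wall) and supine gravity along −y, both configurable. Depths
and ROI sizes are user-facing in cm; the solver works internally in SI
units. See `docs/methods.md` for the model details, parameter choices
and limitations.
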