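# cquant

Scriptable cardiovascular image quantification: the computational cores of
an interactive cardiac-imaging workbench, reimplemented as a Python library
with a `cquant` command line. It covers four pipelines used in cardiac
MRI/CT research:

- **Motion & strain** — cubic B-spline free-form deformation (FFD)
  registration of image frames (multi-level lattice, sum-of-squared-
  differences similarity, gradient descent), mesh tracking, and the
  Green–Lagrange strain tensor **E** = ½(**F**ᵀ**F** − **I**) with
  circumferential/longitudinal strains, local area change, and AHA-style
  16-segment deformation curves.
- **LGE scar quantification** — maximum-intensity projection of a
  late-gadolinium-enhancement scan along surface-mesh normals (3 mm
  outward, 1 mm inward), image-intensity-ratio (IIR) normalisation by the
  blood-pool mean, threshold-based scar burden and area, peri-vein
  corridor gap counting for pulmonary-vein-isolation assessment, and
  pre/post-ablation map comparison (area-weighted Dice).
- **Wall thickness** — the Laplace equation Δu = 0 solved on the wall
  voxel grid with Dirichlet conditions u=0 (endocardium) / u=1
  (epicardium); thickness is the length of the bidirectional streamline of
  ∇u/‖∇u‖ through each wall voxel, sampled back to mesh vertices.
- **Vessel clipping** — medial-radius field (maximal inscribed sphere),
  centerlines from distal seeds to the chamber centre by medially-weighted
  Dijkstra, ostium detection from the rise of the cross-sectional area
  profile, and automatic / semi-automatic / manual finite-disk truncation
  returning rim loops and vessel metrics.

No clinical data is required: `cquant.phantoms` generates every input with
analytic ground truth (slab and spherical-shell walls, chamber-with-veins
blood pools, LGE-like volumes with planted hyper-enhanced patches, B-spline
motion sequences), and the test suite validates each pipeline against
closed forms.

## Worked example

Run the end-to-end scar workflow on the built-in two-vein chamber phantom:

```sh
cquant pipeline --phantom --out-dir run
```

prints (abridged):

```json
{
 "planted_scar_fraction": 0.0854,
 "scar_burden_percent": 9.08,
 "scar_area_mm2": 528.8,
 "veins": [
  {"vein": 0, "opening_area_mm2": 80.5,
   "equivalent_diameter_mm": 10.12, "vessel_length_mm": 16.4},
  {"vein": 1, "opening_area_mm2": 48.5,
   "equivalent_diameter_mm": 7.86, "vessel_length_mm": 12.4}
 ],
 "gaps": [
  {"rim": 0, "n_gaps": 1, "gap_fraction": 1.0, "loop_length_mm": 35.8},
  {"rim": 1, "n_gaps": 1, "gap_fraction": 1.0, "loop_length_mm": 27.8}
 ]
}
```

Reading this: the workflow segmented the phantom blood pool by region
growing, extracted its surface, automatically detected and clipped both
vein ostia (opening areas close to the analytic πr² = 78.5 and
50.3 mm²), projected the synthetic LGE volume onto the clipped surface and
thresholded it at IIR 1.2 — recovering a scar burden of 9.1% against a
planted patch of 8.5% of the surface. The planted patch does not touch
either vein, so each peri-vein corridor is one full-circumference gap
(`gap_fraction` 1.0): in an ablation context, neither vein is encircled by
lesion. Re-running the same command reproduces the report byte for byte;
`run/report.json` embeds the configuration and artefact hashes.

The library mirrors the CLI one-to-one, e.g.:

```python
from cquant import phantoms, thickness

shell = phantoms.make_spherical_shell(r_in=10, r_out=15, spacing=0.5)
pot = thickness.solve_laplace(shell)        # u(r) matches the harmonic
field = thickness.integrate_thickness(pot)  # ~5 mm everywhere
```

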