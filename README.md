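# chitonarmor

Parametric modeling, morphometrics, tessellation and bending kinematics of
chiton girdle-scale armor.

Chitons protect the flexible girdle around their shell plates with hundreds
of small, almost purely aragonitic scales: each has a diamond-footprint
prismatic base embedded in soft tissue and a hook-like dorsal cap that
leans over the scale in front.  The array is both protective (complete
dorsal coverage; scales jam against each other under concave bending) and
flexible (free convex bending; scale rotation in the soft regime).  This
package is for researchers in biomechanics and bio-inspired structural
design who want to generate such scales parametrically, measure them,
tile them into printable armor panels, and analyze the
orientation-dependent interlocking mechanism.

## The model in brief

A scale is generated from **17 parameters** positioning **20 markers** on
three principal sections — the filleted diamond BASE (4 parameters: W, L,
two fillet radii), the sagittal YZ silhouette (10 parameters: inclination
β, inflection height h₁, apex height H, imbrication α, hook tip placement
and curve shaping), and the transverse XZ crown profile (3 parameters).
Cubic splines through the markers scaffold a three-zone sweep (prismatic
base → elbow → hook flap) that lofts into a watertight mesh.

The measured descriptor set is the standard one for these scales: base
width/length W, L; heights h₁, h₂, H = h₁ + h₂; imbrication angle α
(interior angle at the inflection between the downward basal edge and the
hook axis); inclination angle β (posterior basal edge vs. base plane);
projection areas A₁ (hook overhang), A₂, A_total = A₁ + A₂; volume V and
volume centroid.  The convention α + β < 180° is the overlap-capability
condition: the hook axis points below the horizontal by 180° − α − β and
can cover the neighbor in front.

Armor panels place identical or size-graded scales on a diamond mosaic
with a prescribed wall gap d (printed prototypes: L = 10 mm, d = 0.5 mm,
embedded height h₁ = 4.1 mm), build a socketed substrate slab, and export
rigid-scale / flexible-substrate STL pairs for multi-material printing.
Bending wraps the panel midsurface onto a cylinder at orientation φ to the
hook axis and reports the scale–scale contact graph and the interlocking
onset curvature κ*(φ).

## Worked example

```python
import chitonarmor as ca

preset = ca.load_preset("rhyssoplax_canariensis")
mesh = ca.loft_scale(preset.params, n_sections=64, n_profile=64)
rec = ca.measure(mesh)
print(f"H/L={rec.H_L:.3f}  W/L={rec.W_L:.3f}  h1/H={rec.h1_H:.3f}")
print(f"alpha={rec.alpha_deg:.1f}  beta={rec.beta_deg:.1f}  "
      f"A1/At={rec.overlap_ratio:.3f}  V={rec.V*1e3:.2f}e-3 mm^3")
print("basal center of mass:", ca.basal_com_check(rec))
```

prints

```
H/L=0.527  W/L=0.425  h1/H=0.346
alpha=115.8  beta=28.0  A1/At=0.335  V=9.24e-3 mm^3
basal center of mass: True
```

i.e. the generated *Rhyssoplax canariensis* scale sits inside the species'
reported descriptor windows (H/L 0.5–0.6, W/L 0.4–0.5, h₁/H 0.3–0.4,
α 110–120°, β 20–30°, A₁/A_total 0.3–0.4), is overlap-capable
(α + β = 143.8° < 180°), and keeps its center of mass inside the prismatic
base — the tilt-resistance property.

The same pipeline from the shell:

```bash
girdle scale --preset rhyssoplax_canariensis --out scale.stl
girdle measure scale.stl
girdle presets list
girdle assemble --spec panel.yaml --out-dir panel/
girdle bend --spec panel.yaml --phi 0,60,90 --kappa-sweep 0:0.08:0.005 --csv bend.csv
```

where `panel.yaml` might be

```yaml
pattern: uniform
preset: prototype      # the printed-prototype scale (h1 = 4.1 mm at L = 10 mm)
scale_length: 10.0
spacing: 0.5
embedded_height: 4.1
grid_rows: 7
grid_cols: 7
```

Bending this panel across the scale width (φ = 90°) produces sustained
interlocking from κ* ≈ 0.057 mm⁻¹ with each interior scale contacting
exactly its four diagonal neighbors; bending along the hooks (φ = 0°)
leaves the panel free of sustained interlocking — the flexible
orientation.  See `docs/methods.md` for the model's assumptions and known
limitations.

## Layout

```
src/chitonarmor/
  params.py         17-parameter schema, validation, similarity scaling
  curves.py         principal sections, markers, fillets, medial spine
  loft.py           three-zone sweep -> watertight ScaleMesh
  morphometrics.py  silhouettes, descriptor extraction, posing
  assembly.py       diamond/fan/curved-host tiling, socketed substrate
  bending.py        cylinder-wrap kinematics, contact graphs, onset
  presets.py        ten species presets + the printed-prototype scale
  fixtures.py       deterministic synthetic test meshes
  geomutils.py      ear-clipping triangulation, point-triangle distances
  meshfiles.py      STL/OBJ/PLY read-write
  cli.py            the `girdle` command
```
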