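# sacisolate

Objective, repeatable isolation of the abdominal-aortic-aneurysm (AAA) sac
from a triangulated wall surface, and the wall-stress metrics it enables.

## The problem

Peak wall stress (PWS) and mean wall stress (MWS) are the standard
biomechanical read-outs of image-based AAA stress analysis, but their value
depends strongly on the *region* they are computed over. Reconstructions
routinely include non-dilated neck segments, and that extraneous tissue
dilutes MWS and can hide real differences between patient groups (e.g.
clinically stable versus ruptured/intervened aneurysms). `sacisolate`
delimits the dilated sac from geometry alone — no user input, no manual
cutting planes — so that stress metrics become comparable across cases,
groups, and studies. It is aimed at vascular-biomechanics researchers
post-processing finite-element or other nodal stress fields on AAA wall
surfaces.

## The algorithm

With Z the craniocaudal axis and the surface centred at the origin, the
wall is rotated about Z in increments θ_z (N = 360/θ_z projections). Each
rotation is projected to the (x, z) plane; the silhouette is split at
x = 0 into left/right boundary curves; each curve is fitted with a
trigonometric Fourier series

x(z) = a₀ + Σᵢ₌₁ⁿ [ aᵢ cos(i w z) + bᵢ sin(i w z) ],   n = 7 by default,

with fundamental frequency w fitted. The sac limits are read from the
second derivative of the fitted series: the local extrema of x″ of
opposite curvature sign to the bulge apex, nearest below and above it —
the flanks where curvature flips from bulge to neck. Per-projection limits
are aggregated by their median, and all nodes between the bounds form the
sac mask. PWS is the 99th-percentile masked nodal von Mises stress
(linear-interpolation convention); MWS is the unweighted node mean after
removing open-edge boundary rings. See `docs/methods.md` for assumptions,
numerics and limitations.

Because clinical AAA surface datasets are rarely shareable, the package
ships a first-class synthetic-geometry module: fusiform sacs with known
ground-truth bounds, Laplace-law (P·r/t) stress surrogates, and
stable/unstable cohort simulation with a configurable sac-confined stress
offset.

## Worked example

```python
import numpy as np
from sacisolate import (FusiformSpec, RotationConfig, make_fusiform,
                        synthetic_stress_field, isolate_sac, stress_summary)

spec = FusiformSpec(asymmetry=0.2)           # 5 cm sac on a 2 cm neck
mesh, truth = make_fusiform(spec)
stress = synthetic_stress_field(mesh, pressure=120, thickness=1.9,
                                noise_sd=0.5, seed=7)

region = isolate_sac(mesh, RotationConfig(7.5))
print(f"truth sac bounds : [{truth[0]:.1f}, {truth[1]:.1f}] mm")
print(f"isolated bounds  : [{region.z_inferior:.2f}, {region.z_superior:.2f}] mm")
print(f"sac nodes        : {region.node_mask.sum()} / {mesh.n_nodes}")

sac = stress_summary(stress, region.node_mask, mesh, "sac")
entire = stress_summary(stress, np.ones(mesh.n_nodes, bool), mesh, "entire")
print(f"sac    : MWS {sac.mws:.2f}  PWS {sac.pws:.2f}  N/cm^2")
print(f"entire : MWS {entire.mws:.2f}  PWS {entire.pws:.2f}  N/cm^2")
```

prints

```
truth sac bounds : [-30.0, 30.0] mm
isolated bounds  : [-24.78, 24.78] mm
sac nodes        : 2816 / 6400
sac    : MWS 16.12  PWS 21.70  N/cm^2
entire : MWS 11.90  PWS 21.49  N/cm^2
```

The isolated bounds land just inside the ground truth (the Fourier fit
smooths the curvature transition — a stable, documented bias of ~9% of the
sac length). The stress contrast shows the core phenomenon: MWS rises by a
third once the non-dilated necks are excluded, while PWS barely moves —
the stress peak already lives in the sac, so the 99th percentile is
insensitive to the region definition.

The same pipeline is scriptable from the shell:

```sh
sacisolate synth --asymmetry 0.2 --out wall.stl --truth truth.json
sacisolate synth-stress --mesh wall.stl --noise 0.5 --seed 7 --out stress.csv
sacisolate isolate --mesh wall.stl --increment 7.5 --out sac.json
sacisolate metrics --mesh wall.stl --stress stress.csv --region sac --mask sac.json
sacisolate run-batch --manifest cohort/manifest.csv --outdir results/
```

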