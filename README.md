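# patmap

Estimation of the three-dimensional pose (6 DOF) of the patella from
skin-surface markers and a CT-derived bone mesh — a surface-mapping
alternative to biplane-fluoroscopy 2D–3D registration for static knee
postures.

## The problem

Tracking how the kneecap moves matters clinically (patellar tendinitis,
patellofemoral pain), but the standard 2D–3D registration approach needs a
biplane fluoroscopy system few labs have. The surface-mapping approach
needs only a motion-capture system and one CT scan: reflective markers are
stuck in a grid over the anterior knee, the patella surface is segmented
from CT, and the pose of the bone is inferred from how well the marker
cloud "fits" over the bone at the soft-tissue distance measured in CT.

## The method

Let `Q = (p_x, p_y, p_z, θ_x, θ_y, θ_z)` be the pose (translation in mm,
Cardan x-y-z angles in degrees) of the patella's local coordinate system.
For each triangle `i` of the bone-surface *analysis area* (faces whose
CT-measured soft-tissue thickness `ε_i` lies in a configured range,
default 0–20 mm):

1. pose the face by `Q`, take the line through its centroid along its
   outward unit normal;
2. pick the marker closest (perpendicular distance) to that line;
3. measure the signed *vertical distance* `d_i` — the projection of the
   marker onto the normal, positive outside the bone.

The surface-mapping error

```
S(Q, M, E) = Σ_{i=1..N} | d_i − ε_i |
```

is minimized over `Q` by a modified steepest-descent scheme with a fixed
step `h = 0.5` (mm or degree): each coordinate is tried at `q_i`,
`q_i + h`, `q_i − h` and moved to the strictly smallest of the three;
the run converges when a full sweep moves nothing. Preparation parameters
(bone remesh target edge length 3 mm, thickness threshold 0–20 mm, marker
minimum distance 10 mm) are the winners of a 3×3×3 factorial calibration
study scored by summed per-DOF error ranks; that machinery is included.

Because no CT or mocap data ship with the package, a phantom module
generates complete synthetic scenes — a superellipsoid patella, a skin
surface offset by a realistic soft-tissue thickness profile (3–20 mm),
~79 grid markers at 10-mm spacing, lower-leg landmark markers in both the
CT and motion-capture frames — with a known true pose, so every estimator
property is measurable exactly.

## Worked example

```python
import numpy as np
import patmap

# a synthetic knee at 30 deg flexion with its known true pose
truth = dict(patmap.pose_scenarios([30.0]))[30.0]
scene = patmap.make_phantom(truth, seed=0)

# prepare the bone model: remesh to 3 mm, measure soft-tissue thickness,
# keep faces with 0-20 mm of tissue
model = patmap.prepare_surface_model(
    scene.bone, scene.skin, scene.true_lcs,
    target_edge=3.0, thickness_range=(0.0, 20.0),
)
print(model.n_analysis)            # 508 analysis faces

# start from a deliberately wrong pose and descend
start = patmap.perturb_pose(scene.true_pose, 10.0, seed=4)
result = patmap.optimize_pose(start, model, scene.markers)
print(result.converged, result.sweeps)          # True 30
print(round(result.s_trace[0]), round(result.final_s))  # 6407 513

err = patmap.pose_error(scene.true_lcs, patmap.pose_to_transform(result.pose))
print(np.round(err.as_array(), 2))
# [-0.13  0.23 -0.05 -0.38  0.16 -3.48]
```

The trace shows `S` falling from 6407 mm to 513 mm over 30 sweeps; the
recovered pose is within half a millimetre/degree of truth in five DOFs,
while rotation about the anterior axis — the method's weakest DOF — ends
3.5° off: with real-style skin markers the fixed-step descent can stall
on axial rotation, the same failure mode behind the up-to-8° angle errors
such methods show on real sessions (see `docs/methods.md`).

The same pipeline is scriptable from a shell:

```
patmap phantom --seed 1 --out scene/
patmap register --bone scene/bone.stl --skin scene/skin.stl \
    --markers scene/markers.csv --truth scene/truth.json --out result.json
patmap grid --seed 1 --out report.csv      # factorial parameter study
```

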