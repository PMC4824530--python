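# hpft — Homographic Patch Feature Transform

Iterative, patch-wise homographic registration for endoscopic-style image
pairs and sequences, with a self-consistency evaluation scheme
(precision / robustness / uniformity) and a seeded synthetic-scene
generator so the whole pipeline can be developed and tested without
clinical footage.

**Who this is for:** researchers building image-guided tools on flexible
endoscopy video (lesion tracking, mosaicking, depth recovery) who need
dense, validated point correspondences on smooth, textured tissue surfaces
— and a way to quantify how trustworthy those correspondences are without
ground truth.

## The method

A smooth organ surface is modeled as piecewise planar: two views of a
small planar patch are related by a homography `m' = ρ H m`, which for
small patches reduces to a 6-parameter affine map fixed exactly by three
point correspondences. The algorithm:

1. rectifies lens distortion (given intrinsics) and masks saturated
   specular highlights;
2. detects SIFT keypoints with descriptors pooled from 128 to 32 elements,
   matches them (mutual nearest neighbor, 0.8 ratio test, squared
   descriptor distance `V = Σ (e_i − e_i')²`), and keeps the inliers of a
   RANSAC fundamental-matrix estimate;
3. Delaunay-triangulates the matched reference points, validates each
   triangle's affine map by normalized cross-correlation (`Dif_H`) of its
   warped interior, and splits each failing patch at its incircle center —
   the center is matched along the intersection of its epipolar line with
   the corresponding target triangle, subject to the ratio test and an
   absolute gate `V_min < ε`, symmetrically in both directions;
4. repeats on the grown match set until no new point or patch appears.

Quality without ground truth is measured by forward–backward (FB)
tracking error over a sequence (`PPV` = fraction of the 200-feature budget
returning within 4 px), a two-sided Kullback–Leibler comparison of forward
and backward trajectory distributions, a noise-injection robustness
ensemble (`RPV` = fraction of FB-reliable features whose registration site
stays stable, 0.25 px rms, across re-registrations under added Gaussian
noise), and a chi-square uniformity statistic of the matched coordinates.

See `docs/methods.md` for the full model, parameter table and limitations.

## Worked example

```python
import numpy as np
from hpft import HpftConfig, hpft_register, fixtures

# a 560x480 textured scene warped by a known affine, noise sigma 5
tex = fixtures.generate_textured_plane(560, 480, seed=1)
ang = 0.03
H = np.array([[np.cos(ang), -np.sin(ang), 6.0],
              [np.sin(ang),  np.cos(ang), -4.0],
              [0, 0, 1]])
scene = fixtures.warp_scene(tex, H, noise_sigma=5.0, seed=2)

res = hpft_register(scene.reference_image, scene.target_image,
                    cam=None, cfg=HpftConfig(seed=7))
ref = np.stack([m.ref for m in res.matches])
tgt = np.stack([m.tgt for m in res.matches])
err = np.hypot(*(ref @ H[:2, :2].T + H[:2, 2] - tgt).T)
print(f"{len(res.matches)} matches ({res.n_initial_inliers} initial) "
      f"in {res.iterations} iterations; "
      f"{(err <= 2).mean():.1%} within 2 px of truth")
```

Output:

```
181 matches (153 initial) in 6 iterations; 98.9% within 2 px of truth
```

The initial inlier set comes from descriptor matching; the extra matches
are incircle centers recovered by the split-and-refine loop, and every
accepted patch carries its validated affine map (`res.patches`).

The same pipeline is scriptable from the shell:

```sh
hpft synth --kind piecewise --size 560x480 --n-patches 2 --noise 5 --seed 3 --out scene/
hpft register scene/reference.png scene/target.png --seed 7 --out out/
hpft track FRAME_DIR --seed 7 --out track.json
hpft evaluate FRAME_DIR --noise 2,5,10 --reps 30 --seed 7 --out report.json
```

`register` writes `matches.csv` (x_ref, y_ref, x_tgt, y_tgt, distance,
source), `patches.json` (vertex ids, row-major 3x3 H, dif_h) and an
iteration trace; all artifacts are byte-reproducible under a fixed seed.

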