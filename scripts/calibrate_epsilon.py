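#!/usr/bin/env python
"""Calibrate the descriptor-distance gate (epsilon) for center matching.

On noise-free synthetic scenes the true correspondence of a patch center is
known exactly, so the distribution of the best candidate distance V_min for
*true* matches can be measured directly.  Epsilon should sit above the bulk
of that distribution (so true matches pass) while staying far below the
distances of unrelated points (~2 for independent normalized descriptors).

    python scripts/calibrate_epsilon.py --seed 1 [--epsilon 0.35]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from hpft import fixtures  # noqa: E402
from hpft._rng import substream  # noqa: E402
from hpft.features import DescriptorExtractor  # noqa: E402


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--epsilon", type=float, default=0.35)
    ap.add_argument("--n-scenes", type=int, default=5)
    ap.add_argument("--n-points", type=int, default=80)
    args = ap.parse_args()

    vmins = []
    for s in range(args.n_scenes):
        seed = substream(args.seed, f"calib-{s}")
        tex = fixtures.generate_textured_plane(320, 256, seed=seed)
        rng = np.random.default_rng(substream(seed, "warp"))
        ang = rng.uniform(-0.05, 0.05)
        H = np.array(
            [
                [np.cos(ang), -np.sin(ang), rng.uniform(-6, 6)],
                [np.sin(ang), np.cos(ang), rng.uniform(-6, 6)],
                [0, 0, 1],
            ]
        )
        scene = fixtures.warp_scene(tex, H, noise_sigma=0.0, seed=seed)
        er = DescriptorExtractor(scene.reference_image)
        et = DescriptorExtractor(scene.target_image)
        pts = np.column_stack(
            [rng.uniform(30, 290, args.n_points), rng.uniform(30, 226, args.n_points)]
        )
        truth = pts @ H[:2, :2].T + H[:2, 2]
        ok = (truth[:, 0] > 20) & (truth[:, 0] < 300) & (truth[:, 1] > 20) & (truth[:, 1] < 236)
        dref = er.describe(pts[ok])
        dtgt = et.describe(truth[ok])
        vmins.extend(((dref - dtgt) ** 2).sum(axis=1).tolist())

    vmins = np.array(vmins)
    frac = float((vmins < args.epsilon).mean())
    print(f"true-match V over {len(vmins)} points:")
    print(
        "  quartiles:",
        np.round(np.percentile(vmins, [50, 90, 95, 99]), 4),
        "(50/90/95/99%)",
    )
    print(f"  fraction passing epsilon={args.epsilon}: {frac:.3f}")
    if frac < 0.95:
        print("  WARNING: fewer than 95% of true matches pass; consider raising epsilon")
    return 0


if __name__ == "__main__":
    sys.exit(main())
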