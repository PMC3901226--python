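"""Viable-space exploration on a region with known volume.

Uses an analytic viability test (an ellipse of area 2*pi embedded in a
10 x 10 box) so the exploration machinery can be validated end to end:
the coarse adaptive random walk finds the region, the ellipsoid-based
refinement covers it tightly, and the importance-weighted union volume
should land within a few percent of 2*pi ~ 6.283.
"""

import numpy as np

from kinens import ExplorationConfig, estimate_volume, mebs, oeamc
from kinens.hyperspace import Ellipsoid

region = Ellipsoid(center=np.array([5.0, 5.0]),
                   shape=np.diag([1 / 4.0, 1.0]))  # semi-axes 2 and 1
box = (np.zeros(2), np.full(2, 10.0))
cfg = ExplorationConfig(seed=1, batch_size=150, max_iterations=4000)

viability = lambda x: bool(region.contains(x[None])[0])  # noqa: E731

coarse = oeamc(np.array([5.0, 5.0]), viability, box, cfg)
print(f"coarse exploration: {len(coarse)} viable points, "
      f"converged={coarse.converged}")

from dataclasses import replace
fine, cover = mebs(coarse, viability, replace(cfg, seed=2), bounds_box=box)
print(f"refinement: {len(fine)} viable points, {len(cover)} cover ellipsoids")

vol, se = estimate_volume(cover, 30000, seed=3, box=box)
print(f"estimated region volume: {vol:.3f} +- {se:.3f}")
print(f"true volume:             {region.volume:.3f}")
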