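"""Build area-of-habitat richness maps from a synthetic species pool.

Species ranges are filtered per cell by habitat affiliation and elevation
limits. SR_obs counts extant species under the current land cover; SR_ext
counts extinct-listed species plus extant species excluded by habitat
conversion; SR_threat is the regionally Red-Listed subset of SR_obs.
"""

import numpy as np

from serloss import (SERTruth, WorldConfig, classify_wilderness,
                     combine_sr_pot_wilderness, compute_sr_ext, compute_sr_obs,
                     compute_sr_threat, generate_species_pool, generate_world)

world = generate_world(WorldConfig(seed=1))
mask = classify_wilderness(world.footprint, world.forest_potential,
                           world.intact_forest, world.productive, realm=world.realm)
world.wilderness = mask.wilderness
truth = SERTruth.default(10)

pool = generate_species_pool(world, truth, 3000, extinct_prob=0.05, seed=3)
n_ext = sum(sp.status != "extant" for sp in pool)
print(f"pool: {len(pool)} species ({n_ext} extinct-listed), "
      f"median range {int(np.median([len(s.range_cells) for s in pool]))} cells")

sr_obs = compute_sr_obs(pool, world)
sr_ext = compute_sr_ext(pool, world)
sr_threat = compute_sr_threat(pool, world)
prod = world.productive
cov = world.redlist_covered & prod
print(f"SR_obs    mean {sr_obs[prod].mean():6.1f}  max {sr_obs.max()}")
print(f"SR_ext    mean {sr_ext[prod].mean():6.1f}  (conversion + extinction losses)")
print(f"SR_threat mean {sr_threat[cov].mean():6.1f}  on the "
      f"{cov.sum()} Red-List-covered cells")

sr_pot = combine_sr_pot_wilderness(sr_obs, sr_ext, world.wilderness)
wild_vals = sr_pot[world.wilderness]
print(f"SR_pot on wilderness (SR_obs + SR_ext): mean {wild_vals.mean():.1f} "
      "- the response for model calibration")
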