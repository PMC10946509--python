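"""Delineate wilderness and draw the stratified calibration sample.

Wilderness (zero footprint; intact forest where potentially forested) is
where the species-energy model is calibrated, because available energy is
still pristine there. Sampling is stratified by realm: up to 500 cells
per realm, a third of the cells in wilderness-poor realms, and the global
NPP_pot extremes are always included to avoid extrapolation.
"""

import pandas as pd

from serloss import SampleSpec, WorldConfig, classify_wilderness, \
    exclude_empty_realms, generate_world, stratified_sample

world = generate_world(WorldConfig(seed=1))
mask = classify_wilderness(world.footprint, world.forest_potential,
                           world.intact_forest, world.productive, realm=world.realm)
world.wilderness = mask.wilderness
kept, excluded = exclude_empty_realms(mask, world.realm)

print("wilderness cells per realm (the SER calibration domain):")
print(" ", dict(sorted(mask.n_wilderness_by_realm.items())))
print(f"kept realms: {kept}; excluded (no wilderness): {excluded or 'none'}")

cells = stratified_sample(mask, world.realm, world.npp_pot,
                          SampleSpec(n_per_realm=500, seed=2), kept)
per_realm = pd.Series([world.realm[c] for c in cells]).value_counts().sort_index()
print(f"stratified sample: {len(cells)} cells; per realm:")
print(" ", per_realm.to_dict())
print("realms under the 500-cell quota contribute one third of their cells")
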