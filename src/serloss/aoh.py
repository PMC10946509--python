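"""Area-of-habitat richness maps.

A species' extent-of-occurrence range is refined by matching each range
cell's habitat code (for the pristine or the current epoch) against the
species' habitat affiliations and its elevation limits. Counting species
that pass gives three maps per taxon:

* ``SR_obs``  — extant species passing the current-epoch filter;
* ``SR_ext``  — extinct-listed species passing the pristine filter, plus
  extant species that pass under the pristine habitat but fail once the
  current habitat is also required (losses from habitat conversion);
* ``SR_threat`` — the subset of ``SR_obs`` flagged as threatened on the
  regional Red List of the cell's region, defined only where Red-List
  coverage exists.

On wilderness cells, potential richness is taken directly from the maps:
``SR_pot = SR_obs + SR_ext``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .errors import DimensionError
from .world import NODATA_INT, SpeciesRecord, World

__all__ = ["RichnessMaps", "aoh_filter", "compute_sr_obs", "compute_sr_ext",
           "compute_sr_threat", "combine_sr_pot_wilderness"]

Epoch = Literal["current", "pristine", "both"]
_EXTINCT = ("extinct", "possibly_extinct")


@dataclass
class RichnessMaps:
    """The per-taxon species-count grids (integer; no-data sentinel -1)."""

    sr_obs: np.ndarray
    sr_ext: np.ndarray
    sr_threat: np.ndarray
    taxon: str = ""


def _pass_mask(species: SpeciesRecord, landcover_current: np.ndarray,
               habitat_pristine: np.ndarray, elevation: np.ndarray,
               epoch: Epoch) -> np.ndarray:
    """Vectorized habitat+elevation filter over the species' range cells."""
    rr, cc = species.range_cells[:, 0], species.range_cells[:, 1]
    codes = np.fromiter(species.habitat_codes, dtype=np.int64)
    ok = (elevation[rr, cc] >= species.elev_min) & (elevation[rr, cc] <= species.elev_max)
    if epoch in ("current", "both"):
        ok &= np.isin(landcover_current[rr, cc], codes)
    if epoch in ("pristine", "both"):
        ok &= np.isin(habitat_pristine[rr, cc], codes)
    return ok


def aoh_filter(species: SpeciesRecord, cell: tuple[int, int],
               landcover_current: np.ndarray, habitat_pristine: np.ndarray,
               elevation: np.ndarray, epoch: Epoch = "current") -> bool:
    """Does ``cell`` belong to the species' area of habitat for ``epoch``?"""
    r, c = cell
    nr, nc = elevation.shape
    if not (0 <= r < nr and 0 <= c < nc):
        raise DimensionError(f"cell {cell} outside grid of shape {elevation.shape}")
    hab = {"current": landcover_current[r, c] in species.habitat_codes,
           "pristine": habitat_pristine[r, c] in species.habitat_codes,
           "both": (landcover_current[r, c] in species.habitat_codes
                    and habitat_pristine[r, c] in species.habitat_codes)}[epoch]
    return bool(hab and species.elev_min <= elevation[r, c] <= species.elev_max)


def _accumulate(pool: Iterable[SpeciesRecord], world: World, epoch: Epoch,
                statuses: tuple[str, ...]) -> np.ndarray:
    counts = np.zeros(world.shape, dtype=np.int64)
    for sp in pool:
        if sp.status not in statuses:
            continue
        ok = _pass_mask(sp, world.landcover_current, world.habitat_pristine,
                        world.elevation, epoch)
        rr, cc = sp.range_cells[:, 0], sp.range_cells[:, 1]
        np.add.at(counts, (rr[ok], cc[ok]), 1)
    return counts


def compute_sr_obs(pool: list[SpeciesRecord], world: World) -> np.ndarray:
    """Observed richness: extant species passing the current-epoch filter."""
    counts = _accumulate(pool, world, "current", ("extant",))
    counts[~world.productive] = 0
    return counts


def compute_sr_ext(pool: list[SpeciesRecord], world: World) -> np.ndarray:
    """Richness lost to extinction or habitat conversion.

    Extinct-listed species passing the pristine filter, plus the (clamped
    non-negative) excess of extant pristine-only counts over counts that
    require the current habitat to match as well.
    """
    extinct = _accumulate(pool, world, "pristine", _EXTINCT)
    prist_only = _accumulate(pool, world, "pristine", ("extant",))
    both = _accumulate(pool, world, "both", ("extant",))
    counts = extinct + np.maximum(prist_only - both, 0)
    counts[~world.productive] = 0
    return counts


def compute_sr_threat(pool: list[SpeciesRecord], world: World,
                      region_map: np.ndarray | None = None) -> np.ndarray:
    """Threatened subset of SR_obs; no-data outside Red-List coverage.

    ``region_map`` defaults to the realm grid (the synthetic analogue of
    national Red-List regions).
    """
    region_map = world.realm if region_map is None else region_map
    if region_map.shape != world.shape:
        raise DimensionError("region_map shape differs from world grids")
    counts = np.zeros(world.shape, dtype=np.int64)
    for sp in pool:
        if sp.status != "extant" or not sp.threatened_regions:
            continue
        ok = _pass_mask(sp, world.landcover_current, world.habitat_pristine,
                        world.elevation, "current")
        rr, cc = sp.range_cells[:, 0], sp.range_cells[:, 1]
        regions = np.fromiter(sp.threatened_regions, dtype=np.int64)
        ok &= np.isin(region_map[rr, cc], regions)
        np.add.at(counts, (rr[ok], cc[ok]), 1)
    covered = world.redlist_covered & world.productive
    counts[~covered] = NODATA_INT
    return counts


def combine_sr_pot_wilderness(sr_obs: np.ndarray, sr_ext: np.ndarray,
                              wilderness: np.ndarray) -> np.ndarray:
    """SR_pot on wilderness cells = SR_obs + SR_ext; NaN elsewhere.

    Off-wilderness potential richness is filled later by the fitted model.
    """
    if not (sr_obs.shape == sr_ext.shape == wilderness.shape):
        raise DimensionError("richness/wilderness grids misaligned")
    out = np.full(sr_obs.shape, np.nan)
    out[wilderness] = (sr_obs + sr_ext)[wilderness].astype(float)
    return out
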