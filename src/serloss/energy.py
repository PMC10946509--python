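"""HANPP energy accounting.

NPP_eco — the energy left in the ecosystem for wildlife — is the potential
NPP of pristine vegetation minus what humans appropriate, where the
appropriation splits into a land-conversion component (HANPP_luc, which can
be negative under irrigation or fertilization) and a harvest component
(HANPP_harv):

    HANPP   = HANPP_luc + HANPP_harv
    NPP_eco = NPP_pot − HANPP

The module also provides resolution aggregation (area mean / bilinear for
continuous layers, majority for factor layers) and the low-productivity
mask that excludes deserts and ice from the analysis domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DimensionError
from .world import NODATA_INT

__all__ = ["EnergyLayers", "compute_npp_eco", "aggregate_continuous",
           "aggregate_factor", "mask_unproductive", "DEFAULT_UNPRODUCTIVE_THRESHOLD"]

#: free parameter: minimum NPP_pot (gC m-2 yr-1) for a cell to count as productive
DEFAULT_UNPRODUCTIVE_THRESHOLD = 20.0


@dataclass
class EnergyLayers:
    """Aligned energy grids satisfying the two accounting identities."""

    npp_pot: np.ndarray
    npp_eco: np.ndarray
    hanpp: np.ndarray
    hanpp_luc: np.ndarray
    hanpp_harv: np.ndarray
    productive: np.ndarray


def compute_npp_eco(npp_pot: np.ndarray, hanpp_luc: np.ndarray,
                    hanpp_harv: np.ndarray,
                    threshold: float = DEFAULT_UNPRODUCTIVE_THRESHOLD) -> EnergyLayers:
    """Derive NPP_eco by subtracting HANPP from NPP_pot.

    No-data (NaN) in any input propagates to all outputs; productive cells
    additionally require NPP_pot at or above ``threshold``.
    """
    npp_pot = np.asarray(npp_pot, dtype=float)
    hanpp_luc = np.asarray(hanpp_luc, dtype=float)
    hanpp_harv = np.asarray(hanpp_harv, dtype=float)
    if not (npp_pot.shape == hanpp_luc.shape == hanpp_harv.shape):
        raise DimensionError(
            f"shape mismatch: npp_pot {npp_pot.shape}, hanpp_luc {hanpp_luc.shape}, "
            f"hanpp_harv {hanpp_harv.shape}")
    hanpp = hanpp_luc + hanpp_harv
    npp_eco = npp_pot - hanpp
    productive = mask_unproductive(npp_pot, threshold)
    nodata = np.isnan(npp_pot) | np.isnan(hanpp_luc) | np.isnan(hanpp_harv)
    hanpp = np.where(nodata, np.nan, hanpp)
    npp_eco = np.where(nodata, np.nan, npp_eco)
    return EnergyLayers(npp_pot=npp_pot, npp_eco=npp_eco, hanpp=hanpp,
                        hanpp_luc=hanpp_luc, hanpp_harv=hanpp_harv,
                        productive=productive & ~nodata)


def aggregate_continuous(fine: np.ndarray, factor: int,
                         method: Literal["area_mean", "bilinear"] = "area_mean") -> np.ndarray:
    """Coarsen a continuous grid by an integer factor.

    ``area_mean`` averages non-missing cells in each factor×factor block
    (flux-conserving for complete blocks); ``bilinear`` interpolates the
    fine grid at the coarse-cell centers. Blocks that are entirely no-data
    aggregate to NaN.
    """
    fine = np.asarray(fine, dtype=float)
    if factor < 1:
        raise ConfigError("aggregation factor must be >= 1")
    if factor == 1:
        return fine.copy()
    if method == "area_mean":
        nr, nc = fine.shape
        if nr % factor or nc % factor:
            raise DimensionError(
                f"area_mean requires dimensions divisible by factor={factor}, got {fine.shape}")
        blocks = fine.reshape(nr // factor, factor, nc // factor, factor)
        with np.errstate(invalid="ignore"):
            out = np.nanmean(blocks.swapaxes(1, 2).reshape(nr // factor, nc // factor, -1),
                             axis=2)
        return out
    if method == "bilinear":
        nr, nc = (s // factor for s in fine.shape)
        rows = (np.arange(nr) + 0.5) * factor - 0.5
        cols = (np.arange(nc) + 0.5) * factor - 0.5
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return ndimage.map_coordinates(fine, [rr, cc], order=1, mode="nearest")
    raise ConfigError(f"unknown aggregation method {method!r}")


def aggregate_factor(fine: np.ndarray, factor: int,
                     nodata: int = NODATA_INT) -> np.ndarray:
    """Majority (modal) resampling of a factor grid; ties go to the lowest code.

    No-data cells are ignored; all-no-data blocks stay no-data.
    """
    fine = np.asarray(fine)
    if not np.issubdtype(fine.dtype, np.integer):
        raise ConfigError("aggregate_factor expects an integer factor grid")
    if factor < 1:
        raise ConfigError("aggregation factor must be >= 1")
    if factor == 1:
        return fine.copy()
    nr, nc = fine.shape
    if nr % factor or nc % factor:
        raise DimensionError(
            f"majority resampling requires dimensions divisible by factor={factor}")
    blocks = fine.reshape(nr // factor, factor, nc // factor, factor).swapaxes(1, 2)
    out = np.full((nr // factor, nc // factor), nodata, dtype=fine.dtype)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            vals = blocks[i, j][blocks[i, j] != nodata]
            if vals.size:
                codes, counts = np.unique(vals, return_counts=True)
                out[i, j] = codes[counts.argmax()]  # np.unique sorts -> lowest code wins ties
    return out


def mask_unproductive(npp_pot: np.ndarray,
                      threshold: float = DEFAULT_UNPRODUCTIVE_THRESHOLD) -> np.ndarray:
    """Productive = NPP_pot at or above the threshold and not no-data."""
    if threshold < 0:
        raise ConfigError("unproductive threshold must be >= 0")
    npp_pot = np.asarray(npp_pot, dtype=float)
    with np.errstate(invalid="ignore"):
        return (npp_pot >= threshold) & ~np.isnan(npp_pot)
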