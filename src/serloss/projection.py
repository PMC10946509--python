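"""Counterfactual richness projection and expected species loss.

The fitted species–energy model is evaluated across every productive cell
twice — once with NPP_pot (pristine energy, giving SR_pot) and once with
NPP_eco (energy left after human appropriation, giving SR_lu). Their
difference ΔSR = SR_pot − SR_lu is the realized-or-impending species loss
attributable to the energy taken; it is zero on wilderness by definition
(no appropriation there) and negative where irrigation or fertilization
push NPP_eco above NPP_pot. Projection uncertainty follows the NPP slope
varied by ± one standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DimensionError, FitError
from .ser import FittedSER
from .world import World

__all__ = ["ProjectionMaps", "project_sr", "delta_sr", "uncertainty_band", "project_all"]


@dataclass
class ProjectionMaps:
    """Expected-count grids (real-valued; rounding is presentation-only)."""

    sr_pot: np.ndarray
    sr_lu: np.ndarray
    delta_sr: np.ndarray
    sr_pot_low: np.ndarray
    sr_pot_high: np.ndarray


def project_sr(fit: FittedSER, world: World,
               npp_layer: Literal["pot", "eco"] = "pot",
               beta_npp_override: float | None = None) -> np.ndarray:
    """Expected richness exp(η) per productive cell under the chosen NPP layer.

    Cells of realms absent from the fit (excluded realms) come out NaN.
    """
    if npp_layer == "pot":
        npp = world.npp_pot
    elif npp_layer == "eco":
        npp = world.npp_eco
    else:
        raise FitError(f"unknown npp_layer {npp_layer!r}")
    npp = np.where(world.productive, npp, np.nan)
    eta = fit.linear_predictor(world.realm, world.island, npp, beta_npp_override)
    return np.exp(eta)


def delta_sr(sr_pot: np.ndarray, sr_lu: np.ndarray,
             wilderness: np.ndarray) -> np.ndarray:
    """ΔSR = SR_pot − SR_lu, exactly zero on wilderness cells.

    Negative values (richness gains under negative HANPP) are preserved.
    """
    if not (sr_pot.shape == sr_lu.shape == wilderness.shape):
        raise DimensionError("projection grids misaligned")
    out = sr_pot - sr_lu
    out[wilderness] = 0.0
    return out


def uncertainty_band(fit: FittedSER, world: World,
                     npp_layer: Literal["pot", "eco"] = "pot"
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Projections with the NPP slope at β ∓ SE (low) and β ± SE (high).

    Cellwise low ≤ central ≤ high whenever NPP ≥ 0.
    """
    se = fit.se_npp
    if not np.isfinite(se):
        raise FitError("standard error of the NPP coefficient is not finite")
    low = project_sr(fit, world, npp_layer, beta_npp_override=fit.beta_npp - se)
    high = project_sr(fit, world, npp_layer, beta_npp_override=fit.beta_npp + se)
    return low, high


def project_all(fit: FittedSER, world: World) -> ProjectionMaps:
    """Run the full counterfactual: SR_pot, SR_lu, ΔSR and the SR_pot band."""
    sr_pot = project_sr(fit, world, "pot")
    sr_lu = project_sr(fit, world, "eco")
    low, high = uncertainty_band(fit, world, "pot")
    return ProjectionMaps(sr_pot=sr_pot, sr_lu=sr_lu,
                          delta_sr=delta_sr(sr_pot, sr_lu, world.wilderness),
                          sr_pot_low=low, sr_pot_high=high)
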