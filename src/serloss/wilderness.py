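"""Wilderness delineation: the calibration domain of the species–energy model.

A cell counts as wilderness when it shows no human footprint — and, where
the pristine vegetation is forest, when it additionally belongs to an
intact forest landscape. Realms that end up with no wilderness at all
cannot inform the model and are excluded from fitting and projection
(the Madagascar case in the real-world analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, PipelineError

__all__ = ["WildernessMask", "classify_wilderness", "exclude_empty_realms"]


@dataclass
class WildernessMask:
    wilderness: np.ndarray  # bool
    n_wilderness_by_realm: dict[int, int] | None = None


def classify_wilderness(footprint: np.ndarray, forest_potential: np.ndarray,
                        intact_forest: np.ndarray, productive: np.ndarray,
                        realm: np.ndarray | None = None,
                        footprint_tolerance: float = 0.0) -> WildernessMask:
    """Apply the zero-footprint / intact-forest wilderness rule.

    Outside potentially forested areas, zero (or, with a nonzero
    ``footprint_tolerance``, near-zero) footprint suffices; potentially
    forested cells must also lie in an intact forest. Unproductive cells are
    never wilderness. Per-realm counts are tabulated when ``realm`` is given.
    """
    shapes = {a.shape for a in (footprint, forest_potential, intact_forest, productive)}
    if len(shapes) != 1:
        raise DimensionError(f"input layer shapes differ: {shapes}")
    no_impact = footprint <= footprint_tolerance
    wild = productive & no_impact & (~forest_potential | intact_forest)
    counts = None
    if realm is not None:
        if realm.shape != wild.shape:
            raise DimensionError("realm grid shape differs from footprint layers")
        realms = np.unique(realm[realm > 0])
        counts = {int(r): int((wild & (realm == r)).sum()) for r in realms}
    return WildernessMask(wilderness=wild, n_wilderness_by_realm=counts)


def exclude_empty_realms(mask: WildernessMask,
                         realm: np.ndarray) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Split realms into (kept, no-data) by presence of wilderness cells.

    No-data realms take no part in model fitting or projection. Raises if
    every realm is empty (the model would be unfittable).
    """
    if realm.shape != mask.wilderness.shape:
        raise DimensionError("realm grid shape differs from wilderness mask")
    realms = np.unique(realm[realm > 0])
    kept, excluded = [], []
    for r in realms:
        if (mask.wilderness & (realm == r)).any():
            kept.append(int(r))
        else:
            excluded.append(int(r))
    if not kept:
        raise PipelineError("no realm contains wilderness cells; species-energy model unfittable")
    return tuple(kept), tuple(excluded)
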