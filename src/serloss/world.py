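"""Synthetic worlds: grids and species pools with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes — a spatially autocorrelated potential-productivity field
(NPP_pot), human appropriation of NPP split into a land-use-change and a
harvest component (with negative-HANPP irrigation pockets), a realm
partition with mainland/island identity, unevenly distributed wilderness,
per-cell habitat codes for a pristine and a current epoch, and a species
pool whose per-cell range-overlap intensity follows a log-linear
species–energy relationship — so every pipeline stage can be tested
against known parameters without any external dataset.

Units: NPP and HANPP layers are in gC·m⁻²·yr⁻¹ throughout; slopes of the
species–energy relationship are per that unit. All flux layers are
quantized to multiples of 2⁻²⁰ gC·m⁻²·yr⁻¹ so that the energy-accounting
identity NPP_eco = NPP_pot − HANPP_luc − HANPP_harv holds bit-exactly in
double precision.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from .errors import ConfigError, GenerationError

__all__ = [
    "WorldConfig", "World", "SERTruth", "SpeciesRecord",
    "generate_world", "simulate_richness", "generate_species_pool",
    "NATURAL_CODES", "FOREST_CODES", "CONVERTED_CODES", "NODATA_INT",
]

#: pristine habitat codes (1–2 are potentially forested)
NATURAL_CODES = (1, 2, 3, 4, 5, 6)
FOREST_CODES = (1, 2)
#: current-epoch codes for human-converted land, ordered by conversion
#: intensity (101 lightest ... 116 heaviest); species tolerate a nested
#: prefix of these, so heavier conversion excludes more species
CONVERTED_CODES = tuple(range(101, 117))
#: sentinel for integer/factor grids (floats use NaN)
NODATA_INT = -1

_FLUX_QUANTUM = 2.0 ** 20  # reciprocal of the quantization step


def _quantize(x: np.ndarray) -> np.ndarray:
    """Snap fluxes to multiples of 2^-20 so sums/differences are fp-exact."""
    return np.round(x * _FLUX_QUANTUM) / _FLUX_QUANTUM


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic globe; defaults define the study conditions."""

    n_rows: int = 100
    n_cols: int = 100
    cell_size_km: float = 20.0
    n_realms: int = 10
    island_fraction: float = 0.15
    npp_range: tuple[float, float] = (0.0, 1500.0)
    autocorrelation_length: float = 8.0  # cells
    hanpp_intensity: float = 0.5         # mean appropriated NPP fraction off-wilderness
    irrigation_pocket_fraction: float = 0.02
    wilderness_target_fraction: float = 0.25
    wilderness_patches_per_realm: int = 3
    redlist_coverage_fraction: float = 0.7
    seed: int = 0
    unproductive_threshold: float = 20.0  # gC m-2 yr-1
    zero_wilderness_realms: tuple[int, ...] = ()
    conversion_energy_coef: float = 0.0032  # per gC m-2 yr-1, ties conversion to HANPP

    def validate(self) -> None:
        if self.n_rows < 8:
            raise ConfigError("n_rows must be >= 8")
        if self.n_cols < 8:
            raise ConfigError("n_cols must be >= 8")
        if self.n_realms < 1:
            raise ConfigError("n_realms must be >= 1")
        if self.npp_range[0] < 0 or self.npp_range[1] <= self.npp_range[0]:
            raise ConfigError("npp_range must satisfy 0 <= min < max")
        if self.autocorrelation_length <= 0:
            raise ConfigError("autocorrelation_length must be positive")
        for name in ("island_fraction", "hanpp_intensity", "irrigation_pocket_fraction",
                     "wilderness_target_fraction", "redlist_coverage_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.unproductive_threshold < 0:
            raise ConfigError("unproductive_threshold must be >= 0")
        if self.wilderness_patches_per_realm < 1:
            raise ConfigError("wilderness_patches_per_realm must be >= 1")
        bad = [r for r in self.zero_wilderness_realms if not (1 <= r <= self.n_realms)]
        if bad:
            raise ConfigError(f"zero_wilderness_realms contains unknown realm ids {bad}")


@dataclass(frozen=True)
class SERTruth:
    """Ground-truth species–energy relationship on the log scale.

    Cell mean richness is exp(beta0_realm[r] + beta_island·island +
    beta_npp·NPP); counts have variance ``dispersion``·mean.
    """

    beta0_realm: tuple[float, ...]
    beta_island: float = -0.4
    beta_npp: float = 0.0015
    dispersion: float = 1.5

    @classmethod
    def default(cls, n_realms: int = 10) -> "SERTruth":
        # realm intercepts spread around log(~20) species per cell at NPP=0
        base = np.linspace(2.6, 3.4, n_realms)
        return cls(beta0_realm=tuple(base))

    def linear_predictor(self, realm: np.ndarray, island: np.ndarray,
                         npp: np.ndarray) -> np.ndarray:
        b0 = np.asarray(self.beta0_realm)[np.clip(realm, 1, len(self.beta0_realm)) - 1]
        return b0 + self.beta_island * island.astype(float) + self.beta_npp * npp


@dataclass
class World:
    """Aligned grid-layer stack; float layers use NaN off the productive mask."""

    config: WorldConfig
    npp_pot: np.ndarray
    hanpp_luc: np.ndarray
    hanpp_harv: np.ndarray
    npp_eco: np.ndarray
    realm: np.ndarray            # factor 1..n_realms
    island: np.ndarray           # bool, True = island
    footprint: np.ndarray        # >= 0
    forest_potential: np.ndarray  # bool
    intact_forest: np.ndarray     # bool
    landcover_current: np.ndarray  # factor codes
    habitat_pristine: np.ndarray   # factor codes
    elevation: np.ndarray          # m
    redlist_covered: np.ndarray    # bool
    productive: np.ndarray         # bool
    wilderness_designate: np.ndarray  # bool; HANPP forced to 0 here
    wilderness: np.ndarray = field(default=None)  # filled by the wilderness module

    def __post_init__(self) -> None:
        if self.wilderness is None:
            self.wilderness = np.zeros(self.npp_pot.shape, dtype=bool)
        shapes = {name: getattr(self, name).shape
                  for name in ("npp_pot", "hanpp_luc", "hanpp_harv", "npp_eco", "realm",
                               "island", "footprint", "forest_potential", "intact_forest",
                               "landcover_current", "habitat_pristine", "elevation",
                               "redlist_covered", "productive", "wilderness_designate",
                               "wilderness")}
        if len(set(shapes.values())) != 1:
            raise ConfigError(f"layer shapes differ: {shapes}")

    @property
    def shape(self) -> tuple:
        return self.npp_pot.shape

    @property
    def hanpp(self) -> np.ndarray:
        return self.hanpp_luc + self.hanpp_harv


@dataclass
class SpeciesRecord:
    """A species: contiguous range, habitat/elevation affiliation, status."""

    species_id: str
    taxon: Literal["bird", "mammal", "amphibian"]
    range_cells: np.ndarray  # (k, 2) int array of (row, col)
    habitat_codes: frozenset
    elev_min: float
    elev_max: float
    status: Literal["extant", "extinct", "possibly_extinct"] = "extant"
    threatened_regions: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.range_cells = np.atleast_2d(np.asarray(self.range_cells, dtype=np.int64))
        if self.range_cells.shape[0] == 0:
            raise ConfigError(f"species {self.species_id}: empty range")
        if not self.habitat_codes:
            raise ConfigError(f"species {self.species_id}: no habitat codes")
        if self.elev_min > self.elev_max:
            raise ConfigError(f"species {self.species_id}: elev_min > elev_max")


# -- random-field helpers -----------------------------------------------------

def _smooth_standard_field(rng: np.random.Generator, shape: tuple,
                           length: float) -> np.ndarray:
    """Gaussian-kernel-smoothed white noise, re-standardized to ~N(0,1)."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=length, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def _smooth_uniform_field(rng: np.random.Generator, shape: tuple,
                          length: float) -> np.ndarray:
    """Autocorrelated field with ~uniform(0,1) marginal (probit transform)."""
    return ndtr(_smooth_standard_field(rng, shape, length))


def _voronoi_realms(rng: np.random.Generator, shape: tuple, n_realms: int) -> np.ndarray:
    """Balanced contiguous partition: k-means on cell coordinates."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    pts = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    centers = pts[rng.choice(len(pts), size=n_realms, replace=False)]
    for _ in range(12):
        d = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        lab = d.argmin(axis=1)
        for k in range(n_realms):
            sel = lab == k
            if sel.any():
                centers[k] = pts[sel].mean(axis=0)
    return (lab + 1).reshape(shape).astype(np.int64)


_NEIGH = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _grow_patch(rng: np.random.Generator, allowed: np.ndarray, seed_cell: tuple,
                target: int, weight: np.ndarray | None = None) -> np.ndarray:
    """Grow a contiguous patch of ``target`` cells inside ``allowed``.

    Frontier cells are consumed in weighted-random order (exponential-race
    keys), which yields compact but irregular patches. Returns a boolean mask.
    """
    nrows, ncols = allowed.shape
    patch = np.zeros_like(allowed, dtype=bool)
    heap: list = []
    counter = 0

    def push(r: int, c: int) -> None:
        nonlocal counter
        w = 1.0 if weight is None else max(float(weight[r, c]), 1e-12)
        heapq.heappush(heap, (rng.exponential() / w, counter, r, c))
        counter += 1

    push(*seed_cell)
    n = 0
    while heap and n < target:
        _, _, r, c = heapq.heappop(heap)
        if patch[r, c]:
            continue
        patch[r, c] = True
        n += 1
        for dr, dc in _NEIGH:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and allowed[rr, cc] and not patch[rr, cc]:
                push(rr, cc)
    return patch


# -- operations ---------------------------------------------------------------

def generate_world(config: WorldConfig) -> World:
    """Generate a synthetic world; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)
    L = config.autocorrelation_length

    lo, hi = config.npp_range
    npp_pot = _quantize(lo + (hi - lo) * _smooth_uniform_field(rng, shape, L))
    elevation = 3000.0 * _smooth_uniform_field(rng, shape, L / 2)
    realm = _voronoi_realms(rng, shape, config.n_realms)
    island = _smooth_uniform_field(rng, shape, L) > 1.0 - config.island_fraction \
        if config.island_fraction > 0 else np.zeros(shape, dtype=bool)
    if config.island_fraction > 0 and not island.any():
        # quantile fallback so tiny grids still get some island cells
        u = _smooth_uniform_field(rng, shape, L)
        island = u >= np.quantile(u, 1.0 - config.island_fraction)

    # pristine habitat: productivity-correlated mosaic of 6 codes, 1-2 forest
    hab_score = 0.6 * (npp_pot - lo) / (hi - lo) + 0.4 * _smooth_uniform_field(rng, shape, L / 2)
    edges = np.quantile(hab_score, np.linspace(0, 1, len(NATURAL_CODES) + 1)[1:-1])
    habitat_pristine = (len(NATURAL_CODES) - np.digitize(hab_score, edges)).astype(np.int64)
    forest_potential = np.isin(habitat_pristine, FOREST_CODES)

    productive = npp_pot >= config.unproductive_threshold

    # a few contiguous HANPP-free designate patches per realm, so the
    # calibration domain samples each realm's conditions representatively
    designate = np.zeros(shape, dtype=bool)
    for r in range(1, config.n_realms + 1):
        if r in config.zero_wilderness_realms:
            continue
        allowed = productive & (realm == r)
        n_allowed = int(allowed.sum())
        if n_allowed == 0:
            continue
        target = int(round(config.wilderness_target_fraction * n_allowed))
        if target == 0:
            continue
        n_patches = config.wilderness_patches_per_realm
        per_patch = [target // n_patches + (1 if i < target % n_patches else 0)
                     for i in range(n_patches)]
        for want in per_patch:
            open_cells = allowed & ~designate
            idx = np.flatnonzero(open_cells.ravel())
            if want == 0 or len(idx) == 0:
                continue
            seed_flat = int(rng.choice(idx))
            designate |= _grow_patch(rng, open_cells, divmod(seed_flat, config.n_cols),
                                     want)

    footprint = np.where(designate, 0.0, rng.lognormal(mean=0.5, sigma=1.0, size=shape))
    intact_forest = forest_potential & ndimage.binary_erosion(designate)

    # appropriated fraction of NPP_pot, spatially autocorrelated, 0 on designate
    f = np.clip(2.0 * config.hanpp_intensity * _smooth_uniform_field(rng, shape, L / 2),
                0.0, 0.95)
    f[designate | ~productive] = 0.0
    hanpp_luc = 0.7 * f * npp_pot
    hanpp_harv = 0.3 * f * npp_pot

    # irrigation pockets: negative HANPP_luc in arid used cells -> NPP_eco gain
    candidates = productive & ~designate & (npp_pot <= np.quantile(npp_pot[productive], 0.4)) \
        if productive.any() else np.zeros(shape, dtype=bool)
    n_pockets = int(round(config.irrigation_pocket_fraction * int((productive & ~designate).sum())))
    cand_idx = np.flatnonzero(candidates.ravel())
    if n_pockets > 0 and len(cand_idx) > 0:
        chosen = rng.choice(cand_idx, size=min(n_pockets, len(cand_idx)), replace=False)
        rr, cc = np.unravel_index(chosen, shape)
        hanpp_luc[rr, cc] = -0.3 * npp_pot[rr, cc]
        hanpp_harv[rr, cc] = 0.05 * npp_pot[rr, cc]

    hanpp_luc = _quantize(hanpp_luc)
    hanpp_harv = _quantize(hanpp_harv)
    npp_eco = npp_pot - (hanpp_luc + hanpp_harv)

    # habitat conversion tracks energy appropriation: the converted code's
    # intensity level is the (binned) expected richness loss share under the
    # conversion_energy_coef slope (see methods note)
    hanpp_total = np.clip(np.nan_to_num(hanpp_luc + hanpp_harv), 0.0, None)
    loss_share = 1.0 - np.exp(-config.conversion_energy_coef * hanpp_total)
    n_levels = len(CONVERTED_CODES)
    level = np.round(loss_share * n_levels).astype(np.int64)
    level[~productive | designate] = 0
    landcover_current = habitat_pristine.copy()
    converted = level > 0
    landcover_current[converted] = CONVERTED_CODES[0] - 1 + level[converted]

    cov = _smooth_uniform_field(rng, shape, L)
    if config.redlist_coverage_fraction >= 1.0:
        redlist_covered = np.ones(shape, dtype=bool)
    else:
        redlist_covered = cov <= np.quantile(cov, config.redlist_coverage_fraction)

    # no-data (NaN) outside the productive domain for all flux layers
    for layer in (hanpp_luc, hanpp_harv, npp_eco):
        layer[~productive] = np.nan

    return World(
        config=config, npp_pot=npp_pot, hanpp_luc=hanpp_luc, hanpp_harv=hanpp_harv,
        npp_eco=npp_eco, realm=realm, island=island, footprint=footprint,
        forest_potential=forest_potential, intact_forest=intact_forest,
        landcover_current=landcover_current, habitat_pristine=habitat_pristine,
        elevation=elevation, redlist_covered=redlist_covered, productive=productive,
        wilderness_designate=designate,
    )


def simulate_richness(world: World, truth: SERTruth,
                      npp_layer: Literal["pot", "eco"] = "pot",
                      seed: int = 0) -> np.ndarray:
    """Draw per-cell richness counts from the ground-truth model.

    Mean is exp(linear predictor); variance is ``truth.dispersion`` times the
    mean (gamma–Poisson mixture for dispersion > 1, plain Poisson at 1).
    Cells outside the productive mask carry the integer no-data sentinel.
    """
    if npp_layer == "pot":
        npp = world.npp_pot
    elif npp_layer == "eco":
        npp = world.npp_eco
    else:
        raise ConfigError(f"unknown npp_layer {npp_layer!r} (expected 'pot' or 'eco')")
    rng = np.random.default_rng(seed)
    prod = world.productive
    mu = np.exp(truth.linear_predictor(world.realm, world.island, np.where(prod, npp, 0.0)))
    phi = truth.dispersion
    counts = np.full(world.shape, NODATA_INT, dtype=np.int64)
    if phi < 1.0:
        raise ConfigError("dispersion must be >= 1")
    if phi == 1.0:
        counts[prod] = rng.poisson(mu[prod])
    else:
        k = mu[prod] / (phi - 1.0)  # NB shape chosen so variance = phi * mean
        counts[prod] = rng.negative_binomial(k, 1.0 / phi)
    return counts


def generate_species_pool(world: World, truth: SERTruth, n_species_target: int,
                          extinct_prob: float = 0.05, seed: int = 0,
                          threat_threshold: float = 0.5,
                          range_median_cells: int = 80,
                          range_sigma: float = 0.6,
                          habitat_share_min: float = 0.02,
                          elev_coverage: float = 0.96,
                          taxon: str = "bird") -> list[SpeciesRecord]:
    """Place species so per-cell overlap intensity follows the SER.

    Each species gets a contiguous range grown from a centroid sampled
    proportionally to exp(true linear predictor at NPP_pot), habitat codes
    from its range's pristine habitat (every code holding at least
    ``habitat_share_min`` of the range) plus a nested prefix of the
    intensity-ordered converted codes up to a uniformly drawn tolerance
    threshold (so any converted cell retains, in expectation, the share of
    species its conversion level implies), an elevation interval covering
    at least ``elev_coverage`` — and always at least 80% — of its range
    cells, an extinct status with probability ``extinct_prob``, and
    threatened-region flags wherever the within-region share of currently
    habitat-mismatched range cells exceeds ``threat_threshold``.
    """
    if n_species_target < 1:
        raise ConfigError("n_species_target must be >= 1")
    if not (0.8 <= elev_coverage <= 1.0):
        raise ConfigError("elev_coverage must lie in [0.8, 1]")
    prod = world.productive
    n_prod = int(prod.sum())
    if n_species_target > n_prod:
        raise GenerationError(
            f"cannot place {n_species_target} species on {n_prod} productive cells")
    rng = np.random.default_rng(seed)
    eta = truth.linear_predictor(world.realm, world.island, np.where(prod, world.npp_pot, 0.0))
    w = np.where(prod, np.exp(eta), 0.0)
    p_centroid = (w / w.sum()).ravel()
    ncols = world.shape[1]
    n_levels = len(CONVERTED_CODES)

    max_size = max(20, n_prod // 4)
    pool: list[SpeciesRecord] = []
    for i in range(n_species_target):
        size = int(np.clip(round(rng.lognormal(np.log(range_median_cells), range_sigma)),
                           20, max_size))
        seed_flat = int(rng.choice(len(p_centroid), p=p_centroid))
        patch = _grow_patch(rng, prod, divmod(seed_flat, ncols), size, weight=w)
        cells = np.argwhere(patch)
        rr, cc = cells[:, 0], cells[:, 1]

        prist = world.habitat_pristine[rr, cc]
        counts = np.bincount(prist)
        shares = counts / len(prist)
        codes = {int(c) for c in np.flatnonzero(shares >= habitat_share_min)}
        codes.add(int(counts.argmax()))
        # nested conversion tolerance: level k survives iff 1 - k/K >= u
        tol_level = int(np.floor(n_levels * (1.0 - rng.random())))
        codes.update(CONVERTED_CODES[:tol_level])

        elev = world.elevation[rr, cc]
        tail = 100.0 * (1.0 - elev_coverage) / 2.0
        elev_min = float(np.percentile(elev, tail, method="lower"))
        elev_max = float(np.percentile(elev, 100.0 - tail, method="higher"))

        if rng.random() < extinct_prob:
            status = "extinct" if rng.random() < 0.5 else "possibly_extinct"
        else:
            status = "extant"

        cur = world.landcover_current[rr, cc]
        code_arr = np.array(sorted(codes))
        mismatch = ~np.isin(cur, code_arr)
        regions = set()
        for r in np.unique(world.realm[rr, cc]):
            sel = world.realm[rr, cc] == r
            if mismatch[sel].mean() > threat_threshold:
                regions.add(int(r))

        pool.append(SpeciesRecord(
            species_id=f"{taxon}_{i:05d}", taxon=taxon, range_cells=cells,
            habitat_codes=frozenset(codes), elev_min=elev_min, elev_max=elev_max,
            status=status, threatened_regions=frozenset(regions)))
    return pool
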