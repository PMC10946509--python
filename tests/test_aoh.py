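"""Area-of-habitat filtering and the three richness maps."""

import numpy as np
import pytest

from serloss.aoh import (aoh_filter, combine_sr_pot_wilderness, compute_sr_ext,
                         compute_sr_obs, compute_sr_threat)
from serloss.errors import DimensionError
from serloss.world import NODATA_INT, SpeciesRecord, World, WorldConfig


def make_world(habitat_pristine, landcover_current=None, elevation=None,
               redlist_covered=None, realm=None):
    """Hand-built world for exact-count fixtures."""
    hp = np.asarray(habitat_pristine, dtype=np.int64)
    shape = hp.shape
    lc = hp.copy() if landcover_current is None else np.asarray(landcover_current,
                                                                dtype=np.int64)
    elev = np.zeros(shape) if elevation is None else np.asarray(elevation, dtype=float)
    cov = np.ones(shape, dtype=bool) if redlist_covered is None \
        else np.asarray(redlist_covered, dtype=bool)
    rlm = np.ones(shape, dtype=np.int64) if realm is None \
        else np.asarray(realm, dtype=np.int64)
    zeros = np.zeros(shape)
    return World(config=WorldConfig(), npp_pot=np.full(shape, 500.0), hanpp_luc=zeros,
                 hanpp_harv=zeros.copy(), npp_eco=np.full(shape, 500.0), realm=rlm,
                 island=np.zeros(shape, dtype=bool), footprint=zeros.copy(),
                 forest_potential=np.zeros(shape, dtype=bool),
                 intact_forest=np.zeros(shape, dtype=bool), landcover_current=lc,
                 habitat_pristine=hp, elevation=elev, redlist_covered=cov,
                 productive=np.ones(shape, dtype=bool),
                 wilderness_designate=np.zeros(shape, dtype=bool))


def sp(range_cells, habitat_codes, elev=(0.0, 3000.0), status="extant",
       regions=(), sid="s0"):
    return SpeciesRecord(species_id=sid, taxon="bird", range_cells=range_cells,
                         habitat_codes=frozenset(habitat_codes),
                         elev_min=elev[0], elev_max=elev[1], status=status,
                         threatened_regions=frozenset(regions))


class TestAohFilter:
    def test_all_filters_pass(self):
        w = make_world([[1]], elevation=[[800.0]])
        s = sp([[0, 0]], {1}, elev=(500, 1500))
        assert aoh_filter(s, (0, 0), w.landcover_current, w.habitat_pristine,
                          w.elevation, "current")

    def test_elevation_excludes(self):
        w = make_world([[1]], elevation=[[2000.0]])
        s = sp([[0, 0]], {1}, elev=(500, 1500))
        assert not aoh_filter(s, (0, 0), w.landcover_current, w.habitat_pristine,
                              w.elevation, "current")

    def test_epoch_distinguishes_converted_habitat(self):
        w = make_world([[1]], landcover_current=[[101]])
        s = sp([[0, 0]], {1})
        args = (w.landcover_current, w.habitat_pristine, w.elevation)
        assert aoh_filter(s, (0, 0), *args, "pristine")
        assert not aoh_filter(s, (0, 0), *args, "current")

    def test_cell_outside_grid_rejected(self):
        w = make_world([[1]])
        with pytest.raises(DimensionError):
            aoh_filter(sp([[0, 0]], {1}), (5, 5), w.landcover_current,
                       w.habitat_pristine, w.elevation)


class TestSrObs:
    def test_empty_pool_gives_zeros(self):
        w = make_world(np.ones((3, 3)))
        assert not compute_sr_obs([], w).any()

    def test_single_species_unit_count(self):
        w = make_world(np.ones((3, 3)))
        grid = compute_sr_obs([sp([[1, 2]], {1})], w)
        assert grid[1, 2] == 1 and grid.sum() == 1

    def test_extinct_species_not_counted(self):
        w = make_world(np.ones((2, 2)))
        assert compute_sr_obs([sp([[0, 0]], {1}, status="extinct")], w).sum() == 0

    def test_matches_bruteforce_recount(self, small_world, small_pool):
        grid = compute_sr_obs(small_pool, small_world)
        rng = np.random.default_rng(0)
        cells = [(int(r), int(c)) for r, c in
                 rng.integers(0, small_world.shape[0], size=(50, 2))]
        for (r, c) in cells:
            expect = 0
            for s in small_pool:
                if s.status != "extant":
                    continue
                in_range = bool(((s.range_cells[:, 0] == r) &
                                 (s.range_cells[:, 1] == c)).any())
                if in_range and aoh_filter(s, (r, c), small_world.landcover_current,
                                           small_world.habitat_pristine,
                                           small_world.elevation, "current"):
                    expect += 1
            if not small_world.productive[r, c]:
                expect = 0
            assert grid[r, c] == expect

    def test_relaxing_elevation_never_decreases_counts(self, small_world, small_pool):
        import dataclasses
        widened = [dataclasses.replace(s, elev_min=-1.0, elev_max=4000.0)
                   for s in small_pool]
        assert np.all(compute_sr_obs(widened, small_world)
                      >= compute_sr_obs(small_pool, small_world))


class TestSrExt:
    def test_table_definition_direct_case(self):
        # one cell: 2 extinct-listed pass pristine; 3 extant pass pristine of
        # which 1 also passes current -> SR_ext = 2 + (3 - 1) = 4
        w = make_world([[1]], landcover_current=[[101]])
        pool = ([sp([[0, 0]], {1}, status="extinct", sid=f"x{i}") for i in range(2)]
                + [sp([[0, 0]], {1}, sid="a0"), sp([[0, 0]], {1}, sid="a1"),
                   sp([[0, 0]], {1, 101}, sid="a2")])
        assert compute_sr_ext(pool, w)[0, 0] == 4

    def test_zero_without_conversion_or_listings(self):
        w = make_world(np.ones((4, 4)))
        pool = [sp([[i, i]], {1}, sid=f"s{i}") for i in range(4)]
        assert not compute_sr_ext(pool, w).any()

    def test_matches_bruteforce_recount(self, small_world, small_pool):
        grid = compute_sr_ext(small_pool, small_world)
        args = (small_world.landcover_current, small_world.habitat_pristine,
                small_world.elevation)
        rng = np.random.default_rng(1)
        for r, c in rng.integers(0, small_world.shape[0], size=(30, 2)):
            r, c = int(r), int(c)
            ext = prist = both = 0
            for s in small_pool:
                if not ((s.range_cells[:, 0] == r) & (s.range_cells[:, 1] == c)).any():
                    continue
                if s.status in ("extinct", "possibly_extinct"):
                    ext += aoh_filter(s, (r, c), *args, "pristine")
                else:
                    prist += aoh_filter(s, (r, c), *args, "pristine")
                    both += aoh_filter(s, (r, c), *args, "both")
            expect = ext + max(prist - both, 0)
            if not small_world.productive[r, c]:
                expect = 0
            assert grid[r, c] == expect

    def test_never_negative(self, small_world, small_pool):
        assert (compute_sr_ext(small_pool, small_world) >= 0).all()


class TestSrThreat:
    def test_no_threatened_species_gives_zero_on_covered(self):
        w = make_world(np.ones((2, 2)), redlist_covered=[[True, False], [True, True]])
        grid = compute_sr_threat([sp([[0, 0]], {1})], w)
        assert grid[0, 0] == 0 and grid[0, 1] == NODATA_INT

    def test_unit_count_in_threatened_region(self):
        w = make_world(np.ones((1, 2)), realm=[[1, 2]])
        s = sp([[0, 0], [0, 1]], {1}, regions={2})
        grid = compute_sr_threat([s], w)
        assert grid[0, 0] == 0 and grid[0, 1] == 1

    def test_matches_bruteforce_and_bounded_by_sr_obs(self, small_world, small_pool):
        threat = compute_sr_threat(small_pool, small_world)
        obs = compute_sr_obs(small_pool, small_world)
        covered = small_world.redlist_covered & small_world.productive
        assert np.all(threat[covered] <= obs[covered])
        assert np.all(threat[~covered] == NODATA_INT)
        args = (small_world.landcover_current, small_world.habitat_pristine,
                small_world.elevation)
        rng = np.random.default_rng(2)
        checked = 0
        for r, c in rng.integers(0, small_world.shape[0], size=(60, 2)):
            r, c = int(r), int(c)
            if not covered[r, c]:
                continue
            expect = sum(
                1 for s in small_pool
                if s.status == "extant"
                and int(small_world.realm[r, c]) in s.threatened_regions
                and ((s.range_cells[:, 0] == r) & (s.range_cells[:, 1] == c)).any()
                and aoh_filter(s, (r, c), *args, "current"))
            assert threat[r, c] == expect
            checked += 1
        assert checked > 10


class TestSrPotWilderness:
    def test_sum_on_wilderness_nan_elsewhere(self):
        sr_obs = np.array([[12, 3]])
        sr_ext = np.array([[1, 2]])
        wild = np.array([[True, False]])
        out = combine_sr_pot_wilderness(sr_obs, sr_ext, wild)
        assert out[0, 0] == 13.0 and np.isnan(out[0, 1])

    def test_zero_extinct_reduces_to_sr_obs(self):
        sr_obs = np.array([[5, 7]])
        out = combine_sr_pot_wilderness(sr_obs, np.zeros_like(sr_obs),
                                        np.ones((1, 2), dtype=bool))
        assert np.array_equal(out, sr_obs.astype(float))
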