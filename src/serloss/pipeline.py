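"""Pipeline orchestration, configuration and artifact persistence.

A :class:`PipelineConfig` drives the full chain — synthetic world →
energy accounting → wilderness delineation → area-of-habitat richness →
species–energy fit → counterfactual projection → validation — writing
every product (rasters, species table, fit and validation summaries, and
a manifest with per-file hashes) into one output directory. Stage seeds
are derived from the global seed by stable hashing of the stage name, so
stages stay decoupled and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aoh import (RichnessMaps, combine_sr_pot_wilderness, compute_sr_ext,
                  compute_sr_obs, compute_sr_threat)
from .energy import compute_npp_eco
from .errors import PipelineError
from .gridio import GridLayer, read_grid, write_grid
from .projection import ProjectionMaps, project_all
from .ser import FittedSER, SampleSpec, fit_ser
from .validation import (ValidationReport, build_domain_mask, build_thr_ext,
                         repeated_sample_correlation)
from .wilderness import classify_wilderness, exclude_empty_realms
from .world import (NODATA_INT, SERTruth, SpeciesRecord, World, WorldConfig,
                    generate_species_pool, generate_world)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "save_world", "load_world",
           "save_species", "load_species", "fit_to_dict", "fit_from_dict"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


@dataclass(frozen=True)
class PipelineConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    sample: SampleSpec = field(default_factory=SampleSpec)
    truth: SERTruth | None = None
    taxa: tuple[str, ...] = ("bird",)
    n_species: int = 3000
    extinct_prob: float = 0.05
    n_draws: int = 10
    n_per_draw: int = 5000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        world = WorldConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in raw.get("world", {}).items()})
        sample = SampleSpec(**raw.get("sample", {}))
        truth = None
        if "truth" in raw:
            t = dict(raw["truth"])
            t["beta0_realm"] = tuple(t["beta0_realm"])
            truth = SERTruth(**t)
        keys = {f.name for f in dataclasses.fields(cls)} - {"world", "sample", "truth"}
        rest = {k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.items() if k in keys}
        return cls(world=world, sample=sample, truth=truth, **rest)


# -- persistence --------------------------------------------------------------

_LAYERS = {
    "npp_pot": ("gC m-2 yr-1", "float64"), "hanpp_luc": ("gC m-2 yr-1", "float64"),
    "hanpp_harv": ("gC m-2 yr-1", "float64"), "npp_eco": ("gC m-2 yr-1", "float64"),
    "realm": ("", "int64"), "island": ("", "int64"), "footprint": ("", "float64"),
    "forest_potential": ("", "int64"), "intact_forest": ("", "int64"),
    "landcover_current": ("", "int64"), "habitat_pristine": ("", "int64"),
    "elevation": ("m", "float64"), "redlist_covered": ("", "int64"),
    "productive": ("", "int64"), "wilderness_designate": ("", "int64"),
    "wilderness": ("", "int64"),
}


def save_world(world: World, outdir: str | Path, fmt: str = "asc") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, (units, dtype) in _LAYERS.items():
        arr = getattr(world, name)
        if arr.dtype == bool:
            arr = arr.astype(np.int64)
        nodata = NODATA_INT if np.issubdtype(np.dtype(dtype), np.integer) else -9999.0
        layer = GridLayer(values=arr.astype(dtype), name=name, units=units, nodata=nodata)
        written.append(write_grid(layer, outdir / f"{name}.{fmt}"))
    (outdir / "world_config.json").write_text(
        json.dumps(dataclasses.asdict(world.config), indent=1))
    written.append(outdir / "world_config.json")
    return written


def load_world(indir: str | Path, fmt: str = "asc") -> World:
    indir = Path(indir)
    cfg = json.loads((indir / "world_config.json").read_text())
    for key in ("npp_range", "zero_wilderness_realms"):
        cfg[key] = tuple(cfg[key])
    config = WorldConfig(**cfg)
    arrays = {}
    for name, (_, dtype) in _LAYERS.items():
        layer = read_grid(indir / f"{name}.{fmt}")
        arr = layer.values
        if name in ("island", "forest_potential", "intact_forest", "redlist_covered",
                    "productive", "wilderness_designate", "wilderness"):
            arr = arr.astype(bool)
        arrays[name] = arr
    return World(config=config, **arrays)


def _rle(cells: np.ndarray, ncols: int) -> str:
    flat = np.sort(cells[:, 0] * ncols + cells[:, 1])
    breaks = np.flatnonzero(np.diff(flat) != 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(flat) - 1]])
    return ";".join(f"{flat[s]}:{e - s + 1}" for s, e in zip(starts, ends))


def _unrle(text: str, ncols: int) -> np.ndarray:
    out = []
    for run in text.split(";"):
        start, length = (int(x) for x in run.split(":"))
        out.append(np.arange(start, start + length))
    flat = np.concatenate(out)
    return np.column_stack(divmod(flat, ncols))


def save_species(pool: list[SpeciesRecord], path: str | Path, ncols: int) -> Path:
    rows = [{
        "species_id": sp.species_id, "taxon": sp.taxon, "status": sp.status,
        "elev_min": sp.elev_min, "elev_max": sp.elev_max,
        "habitat_codes": "|".join(str(c) for c in sorted(sp.habitat_codes)),
        "threatened_regions": "|".join(str(r) for r in sorted(sp.threatened_regions)),
        "range_rle": _rle(sp.range_cells, ncols),
    } for sp in pool]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def load_species(path: str | Path, ncols: int) -> list[SpeciesRecord]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    pool = []
    for row in df.itertuples(index=False):
        pool.append(SpeciesRecord(
            species_id=row.species_id, taxon=row.taxon,
            range_cells=_unrle(row.range_rle, ncols),
            habitat_codes=frozenset(int(c) for c in str(row.habitat_codes).split("|")),
            elev_min=float(row.elev_min), elev_max=float(row.elev_max),
            status=row.status,
            threatened_regions=frozenset(int(r) for r in str(row.threatened_regions).split("|")
                                         if r != "")))
    return pool


def fit_to_dict(fit: FittedSER) -> dict:
    return {
        "coefficients": fit.coefficients, "standard_errors": fit.standard_errors,
        "t_values": fit.t_values, "dispersion_phi": fit.dispersion_phi,
        "deviance_null": fit.deviance_null, "deviance_resid": fit.deviance_resid,
        "df_null": fit.df_null, "df_resid": fit.df_resid,
        "adjusted_r2": fit.adjusted_r2, "partial_r2": fit.partial_r2,
        "realm_levels": list(fit.realm_levels), "reference_realm": fit.reference_realm,
        "sample": [list(c) for c in fit.sample],
    }


def fit_from_dict(d: dict) -> FittedSER:
    return FittedSER(
        coefficients=d["coefficients"], standard_errors=d["standard_errors"],
        t_values=d["t_values"], dispersion_phi=d["dispersion_phi"],
        deviance_null=d["deviance_null"], deviance_resid=d["deviance_resid"],
        df_null=d["df_null"], df_resid=d["df_resid"], adjusted_r2=d["adjusted_r2"],
        partial_r2=d["partial_r2"], sample=[tuple(c) for c in d["sample"]],
        realm_levels=tuple(d["realm_levels"]), reference_realm=d["reference_realm"])


def _report_to_dict(rep: ValidationReport) -> dict:
    d = dataclasses.asdict(rep)
    d["per_draw"] = [{"r": r, "p": p, "n": n} for r, p, n in rep.per_draw]
    return d


# -- orchestration ------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis chain; returns in-memory results.

    When ``outdir`` is given, every product plus a manifest (inputs, seeds,
    versions, per-file hashes, and the defaults actually used) is written
    there; rerunning with the same config reproduces identical bytes.
    """
    results: dict = {}
    stage = "world"
    try:
        wcfg = dataclasses.replace(config.world, seed=stage_seed(config.seed, "world"))
        world = generate_world(wcfg)
        truth = config.truth or SERTruth.default(wcfg.n_realms)

        stage = "energy"
        energy = compute_npp_eco(world.npp_pot, world.hanpp_luc, world.hanpp_harv,
                                 threshold=wcfg.unproductive_threshold)
        results["energy"] = energy

        stage = "wilderness"
        wmask = classify_wilderness(world.footprint, world.forest_potential,
                                    world.intact_forest, world.productive,
                                    realm=world.realm)
        world.wilderness = wmask.wilderness
        kept, excluded = exclude_empty_realms(wmask, world.realm)
        results.update(world=world, truth=truth, wilderness=wmask,
                       kept_realms=kept, excluded_realms=excluded)

        per_taxon: dict[str, dict] = {}
        for taxon in config.taxa:
            stage = f"aoh[{taxon}]"
            pool = generate_species_pool(
                world, truth, config.n_species, extinct_prob=config.extinct_prob,
                seed=stage_seed(config.seed, f"species:{taxon}"), taxon=taxon)
            sr_obs = compute_sr_obs(pool, world)
            sr_ext = compute_sr_ext(pool, world)
            sr_threat = compute_sr_threat(pool, world)
            maps = RichnessMaps(sr_obs=sr_obs, sr_ext=sr_ext, sr_threat=sr_threat,
                                taxon=taxon)
            sr_pot_wild = combine_sr_pot_wilderness(sr_obs, sr_ext, world.wilderness)

            stage = f"ser[{taxon}]"
            spec = dataclasses.replace(config.sample,
                                       seed=stage_seed(config.seed, f"sample:{taxon}"))
            fit = fit_ser(world, sr_pot_wild, wmask, spec, kept_realms=kept)

            stage = f"projection[{taxon}]"
            proj = project_all(fit, world)

            stage = f"validation[{taxon}]"
            mask_lu = build_domain_mask(world, "sr_lu_vs_sr_obs", kept)
            rep_lu = repeated_sample_correlation(
                proj.sr_lu, sr_obs.astype(float), mask_lu,
                n_draws=config.n_draws, n_per_draw=config.n_per_draw,
                seed=stage_seed(config.seed, f"validate_lu:{taxon}"),
                comparison="sr_lu_vs_sr_obs")
            mask_d = build_domain_mask(world, "delta_vs_thr_ext", kept)
            thr_ext = build_thr_ext(sr_threat, sr_ext)
            rep_d = repeated_sample_correlation(
                proj.delta_sr, thr_ext.astype(float), mask_d,
                n_draws=config.n_draws, n_per_draw=config.n_per_draw,
                seed=stage_seed(config.seed, f"validate_delta:{taxon}"),
                comparison="delta_vs_thr_ext")
            per_taxon[taxon] = {"pool": pool, "richness": maps,
                                "sr_pot_wilderness": sr_pot_wild, "fit": fit,
                                "projection": proj, "thr_ext": thr_ext,
                                "validation_lu": rep_lu, "validation_delta": rep_d}
    except PipelineError as err:
        raise PipelineError(f"stage {stage!r}: {err}") from err
    results["taxa"] = per_taxon

    if outdir is not None:
        _write_artifacts(config, results, Path(outdir))
    return results


def _write_artifacts(config: PipelineConfig, results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    world: World = results["world"]
    files = save_world(world, outdir / "world")
    for taxon, res in results["taxa"].items():
        tdir = outdir / taxon
        tdir.mkdir(exist_ok=True)
        files.append(save_species(res["pool"], tdir / "species.csv", world.shape[1]))
        maps = res["richness"]
        for name in ("sr_obs", "sr_ext", "sr_threat"):
            layer = GridLayer(values=getattr(maps, name), name=name, nodata=NODATA_INT)
            files.append(write_grid(layer, tdir / f"{name}.asc"))
        proj: ProjectionMaps = res["projection"]
        for name in ("sr_pot", "sr_lu", "delta_sr", "sr_pot_low", "sr_pot_high"):
            layer = GridLayer(values=getattr(proj, name), name=name, nodata=-9999.0)
            files.append(write_grid(layer, tdir / f"{name}.asc"))
        (tdir / "fit.json").write_text(json.dumps(fit_to_dict(res["fit"]), indent=1))
        files.append(tdir / "fit.json")
        report = {"sr_lu_vs_sr_obs": _report_to_dict(res["validation_lu"]),
                  "delta_vs_thr_ext": _report_to_dict(res["validation_delta"])}
        (tdir / "validation.json").write_text(json.dumps(report, indent=1))
        files.append(tdir / "validation.json")

    manifest = {
        "serloss_version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ["world"] + [f"species:{t}" for t in config.taxa]},
        "kept_realms": list(results["kept_realms"]),
        "excluded_realms": list(results["excluded_realms"]),
        "defaults_in_effect": {
            "unproductive_threshold": config.world.unproductive_threshold,
            "link": "log",
            "sampling_quota": config.sample.n_per_realm,
            "small_realm_fraction": config.sample.small_realm_fraction,
            "factor_tie_break": "lowest code",
            "threat_mismatch_threshold": 0.5,
        },
        "outputs": {str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(files)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
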