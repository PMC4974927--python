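"""End-to-end pipeline: simulate -> fit -> project -> metrics -> turnover ->
fragmentation -> report.

Every stage persists its outputs under the configured directory; a manifest
records the configuration, seeds, library versions and the SHA-256 of every
artifact, so a rerun with the same configuration is byte-identical and
verifiably so.

The simulate stage builds the study system: a baseline climate stack, one or
more future scenario stacks, and a set of virtual species split into two
guilds — montane species anchored on high ground (cold-adapted; under
warming they contract upslope and their ranges tend to fragment) and warm
lowland species (which tend to hold or expand).  Anchors are restricted away
from the northern grid edge so ranges have room to track the climate.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .errors import PipelineConfigError
from .fragmentation import ci_change, label_patches
from .grids import ClimateStack, GridSpec, RangeMap
from .range_metrics import compute_metrics, summarize_assemblage
from .sdm import binarize, fit_species, project
from .synthetic import (
    ScenarioSpec,
    VirtualSpecies,
    make_climate_stack,
    make_virtual_species,
    sample_occurrences,
    species_suitability,
)
from .turnover import auto_thresholds, build_turnover, priority_areas

log = logging.getLogger("rangeshift")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_GRID = dict(
    n_rows=60, n_cols=60, origin_lon=100.0, origin_lat=40.0, cell_size=0.25,
    elevation_model="ridge_west",
)

DEFAULT_SCENARIOS = [
    dict(name="baseline", period="baseline", pathway="baseline"),
    dict(name="SYN45_2050s", period="2050s", pathway="RCP4.5",
         temp_delta=2.0, precip_factor=1.0, seasonality_delta=0.0),
]


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline deterministically."""

    grid: GridSpec
    scenarios: list[ScenarioSpec]
    out_dir: Path
    seed: int = 0
    n_species: int = 20
    n_occurrences: int = 100
    prevalence: float = 0.03
    montane_fraction: float = 0.5
    n_replicates: int = 20
    background_size: int = 10_000
    beta: float = 1.0
    split_ratio: float = 0.8
    tr_min: float = 50.0
    ts_min: float = 20.0
    auto_threshold: bool = False
    connectivity: int = 8
    # optional external inputs (skip the simulate stage):
    # {"stacks": {scenario_name: dir}, "occurrences": csv_path}
    inputs: dict | None = None

    @classmethod
    def from_dict(cls, d: dict, out_dir: str | Path | None = None) -> "PipelineConfig":
        d = dict(d)
        grid = GridSpec(**{**DEFAULT_GRID, **d.pop("grid", {})})
        scen_dicts = d.pop("scenarios", None) or DEFAULT_SCENARIOS
        scenarios = [ScenarioSpec(**s) for s in scen_dicts]
        out = Path(out_dir or d.pop("out_dir", "rangeshift_out"))
        d.pop("out_dir", None)
        cfg = cls(grid=grid, scenarios=scenarios, out_dir=out, **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path,
                  out_dir: str | Path | None = None) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {}, out_dir=out_dir)

    def validate(self) -> None:
        """Pre-flight checks; every referenced path must resolve before any
        stage runs."""
        baselines = [s for s in self.scenarios if s.is_baseline]
        if len(baselines) != 1:
            raise PipelineConfigError(
                f"exactly one baseline scenario required, got {len(baselines)}"
            )
        if self.n_occurrences < 10:
            raise PipelineConfigError("n_occurrences must be >= 10")
        if self.connectivity not in (4, 8):
            raise PipelineConfigError("connectivity must be 4 or 8")
        if self.inputs is not None:
            for name, path in self.inputs.get("stacks", {}).items():
                if not Path(path).is_dir():
                    raise PipelineConfigError(
                        f"input stack for scenario '{name}' not found: {path}"
                    )
            occ = self.inputs.get("occurrences")
            if occ is not None and not Path(occ).is_file():
                raise PipelineConfigError(f"occurrence file not found: {occ}")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["inputs"] = self.inputs
        return d

    @property
    def baseline(self) -> ScenarioSpec:
        return next(s for s in self.scenarios if s.is_baseline)

    @property
    def futures(self) -> list[ScenarioSpec]:
        return [s for s in self.scenarios if not s.is_baseline]


# ---------------------------------------------------------------------------
# simulate stage
# ---------------------------------------------------------------------------

def guild_anchor_pools(stack: ClimateStack) -> dict[str, np.ndarray]:
    """Flat-index anchor pools for the two species guilds.

    Montane: cells above the 70th elevation percentile.  Lowland: below the
    30th percentile, warmer than the median but below the 75th temperature
    percentile.  Both pools exclude the northernmost quarter of rows so
    suitable climate remains on-grid under warming, and the lowland warm
    bound keeps the whole niche response (optimum plus the scenario shift
    plus a tolerance) inside the environmental range the baseline samples —
    a response curve truncated at the warm margin is not identifiable from
    presence data, which is an experimental-design constraint, not a model
    property.
    """
    grid = stack.grid
    elev = stack.elevation.ravel()
    tmean = stack.layers["annual_mean_temp"].ravel()
    rows = np.repeat(np.arange(grid.n_rows), grid.n_cols)
    south_of_edge = rows >= grid.n_rows // 4
    valid = stack.mask.ravel() & south_of_edge
    montane = np.flatnonzero(valid & (elev >= np.quantile(elev[valid], 0.70)))
    lowland = np.flatnonzero(
        valid & (elev <= np.quantile(elev[valid], 0.30))
        & (tmean >= np.median(tmean[valid]))
        & (tmean <= np.quantile(tmean[valid], 0.75))
    )
    return {"montane": montane, "lowland": lowland}


def simulate_study(
    config: PipelineConfig,
) -> tuple[dict[str, ClimateStack], list[VirtualSpecies], pd.DataFrame]:
    """Generate all scenario stacks, the virtual species, and occurrences."""
    stacks = {
        s.name: make_climate_stack(config.grid, s, seed=config.seed)
        for s in config.scenarios
    }
    baseline = stacks[config.baseline.name]
    pools = guild_anchor_pools(baseline)
    n_montane = int(round(config.montane_fraction * config.n_species))
    species: list[VirtualSpecies] = []
    occ_frames: list[pd.DataFrame] = []
    for k in range(config.n_species):
        guild = "montane" if k < n_montane else "lowland"
        sp_seed = int(config.seed) * 1009 + k
        vs = make_virtual_species(
            baseline,
            species_id=f"sp{k:03d}_{guild}",
            seed=sp_seed,
            anchor_pool=pools[guild],
            prevalence=config.prevalence,
            n_occurrences=config.n_occurrences,
        )
        truth = species_suitability(vs, baseline)
        occ_frames.append(sample_occurrences(vs, truth, seed=sp_seed))
        species.append(vs)
    occurrences = pd.concat(occ_frames, ignore_index=True)
    return stacks, species, occurrences


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns a report bundle of key tables.

    Any stage failure aborts with the failing stage named; partial outputs
    are retained on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    stage = "init"
    t0 = time.time()
    try:
        # ---- stage 1: simulate (or load) ---------------------------------
        stage = "simulate"
        if config.inputs is None:
            stacks, species, occurrences = simulate_study(config)
            for name, stack in stacks.items():
                rio.write_stack(stack, out / "climate" / name)
            rio.write_occurrences(occurrences, out / "occurrences.csv")
            truth_payload = {
                vs.species_id: {
                    "niche_optimum": list(vs.niche_optimum),
                    "niche_breadth": list(vs.niche_breadth),
                    "prevalence": vs.prevalence,
                    "n_occurrences": vs.n_occurrences,
                    "seed": vs.seed,
                }
                for vs in species
            }
            (out / "species_truth.json").write_text(
                json.dumps(truth_payload, indent=1, sort_keys=True) + "\n"
            )
        else:
            stacks = {
                name: rio.read_stack(path, scenario=name,
                                     elevation_model=config.grid.elevation_model)
                for name, path in config.inputs["stacks"].items()
            }
            occurrences = rio.read_occurrences(config.inputs["occurrences"])
        log.info("stage simulate done in %.1fs (seed=%d)",
                 time.time() - t0, config.seed)

        baseline = stacks[config.baseline.name]
        by_species = rio.split_by_species(occurrences)
        species_ids = sorted(by_species)

        # ---- stage 2: fit ------------------------------------------------
        stage = "fit"
        (out / "fits").mkdir(exist_ok=True)
        fits = {}
        for sid in species_ids:
            fit = fit_species(
                baseline, by_species[sid],
                n_replicates=config.n_replicates,
                split_ratio=config.split_ratio,
                seed=config.seed,
                n_background=config.background_size,
                beta=config.beta,
            )
            fits[sid] = fit
            rio.write_fit(fit, out / "fits" / f"{sid}.json")
        log.info("stage fit done (%d species)", len(fits))

        # ---- stage 3: project + binarize ---------------------------------
        stage = "project"
        ranges: dict[str, dict[str, RangeMap]] = {}
        for scen_name, stack in stacks.items():
            (out / "suitability" / scen_name).mkdir(parents=True, exist_ok=True)
            (out / "ranges" / scen_name).mkdir(parents=True, exist_ok=True)
            ranges[scen_name] = {}
            for sid in species_ids:
                smap = project(fits[sid], stack)
                rmap = binarize(smap, fits[sid].threshold)
                ranges[scen_name][sid] = rmap
                rio.write_suitability(
                    smap, out / "suitability" / scen_name / f"{sid}.asc"
                )
                rio.write_range_map(rmap, out / "ranges" / scen_name / f"{sid}.asc")
        log.info("stage project done")

        # ---- stage 4: metrics + fragmentation ----------------------------
        stage = "metrics"
        elev = baseline.elevation
        all_metrics = []
        frag_rows = []
        for scen in config.futures:
            for sid in species_ids:
                cur = ranges[config.baseline.name][sid]
                fut = ranges[scen.name][sid]
                if cur.area == 0:
                    log.warning("species %s has empty current range; skipped", sid)
                    continue
                m = compute_metrics(cur, fut, elev)
                p_cur = label_patches(cur, connectivity=config.connectivity)
                row = {
                    "species_id": sid, "scenario": scen.name,
                    "n_patches_current": p_cur.n_patches,
                    "ci_current": p_cur.ci,
                }
                if fut.area > 0:
                    p_fut = label_patches(fut, connectivity=config.connectivity)
                    m.ci_change = ci_change(p_cur, p_fut)
                    row.update(
                        n_patches_future=p_fut.n_patches,
                        ci_future=p_fut.ci, ci_change=m.ci_change,
                    )
                else:
                    row.update(n_patches_future=0, ci_future=np.nan,
                               ci_change=np.nan)
                all_metrics.append(m)
                frag_rows.append(row)
        per_species, summary, correlations = summarize_assemblage(all_metrics)
        (out / "metrics").mkdir(exist_ok=True)
        rio.write_table(per_species, out / "metrics" / "species_metrics.csv")
        rio.write_table(summary, out / "metrics" / "summary.csv")
        rio.write_table(correlations, out / "metrics" / "correlations.csv")
        frag = pd.DataFrame(frag_rows)
        rio.write_table(frag, out / "metrics" / "fragmentation.csv")
        report.update(per_species=per_species, summary=summary,
                      correlations=correlations, fragmentation=frag)
        log.info("stage metrics done (%d species x scenario rows)",
                 len(per_species))

        # ---- stage 5: turnover -------------------------------------------
        stage = "turnover"
        turnover_tables = {}
        for scen in config.futures:
            cur_maps = [ranges[config.baseline.name][sid] for sid in species_ids]
            fut_maps = [ranges[scen.name][sid] for sid in species_ids]
            t = build_turnover(cur_maps, fut_maps)
            tr_min, ts_min = (
                auto_thresholds(t) if config.auto_threshold
                else (config.tr_min, config.ts_min)
            )
            hot, regions = priority_areas(
                t, tr_min=tr_min, ts_min=ts_min,
                connectivity=config.connectivity,
            )
            tdir = out / "turnover" / scen.name
            tdir.mkdir(parents=True, exist_ok=True)
            for name, arr in (("NT", t.NT), ("NC", t.NC), ("NE", t.NE),
                              ("TS", t.TS)):
                rio.write_ascii_grid(tdir / f"{name}.asc", arr.astype(float),
                                     t.grid)
            rio.write_ascii_grid(tdir / "TR.asc", np.nan_to_num(t.TR, nan=rio.NODATA),
                                 t.grid, nodata_mask=t.tr_defined)
            rio.write_ascii_grid(tdir / "priority.asc", hot.astype(float), t.grid)
            rio.write_table(regions, tdir / "priority_regions.csv")
            turnover_tables[scen.name] = {"turnover": t, "regions": regions,
                                          "tr_min": tr_min, "ts_min": ts_min}
        report["turnover"] = turnover_tables
        log.info("stage turnover done")

        # ---- stage 6: manifest -------------------------------------------
        stage = "manifest"
        files = sorted(
            p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "config": config.to_jsonable(),
            "seed": config.seed,
            "versions": {
                "rangeshift": __import__("rangeshift").__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "artifacts": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        report["manifest"] = manifest
    except Exception as exc:
        # abort naming the failing stage; partial outputs are left on disk
        exc.add_note(f"pipeline stage '{stage}' failed")
        log.error("pipeline stage '%s' failed: %s", stage, exc)
        raise
    return report
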