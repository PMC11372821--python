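"""End-to-end orchestration: simulate → prep → niche → fit → project → gaps.

One :class:`RunConfig` drives every stage.  Stages communicate through an
in-memory context dict and persist their tables (CSV), geometries
(GeoJSON) and rasters (ASCII grid) under the run directory, together with
a manifest recording the configuration, derived per-stage seeds and
package versions, and a plain-text log of per-stage decisions.

The single config seed fans out to per-stage seeds by hashing the stage
name, so each stage is individually reproducible regardless of order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString, mapping, shape

from . import __version__
from .ensemble import (
    ALGORITHMS,
    CvScores,
    build_ensemble,
    cross_validate,
    default_specs,
    evaluate,
    response_curve,
    select_members,
    variable_importance,
)
from .gaps import (
    classify_conservation,
    gap_report_frame,
    protection_stats,
    rasterize_mpas,
    write_mpas_geojson,
)
from .grid import GridSpec, Layer, PredictorStack, write_raster, write_stack
from .hypervolume import comparison_frame, overlap, paired_hypervolumes
from .occurrences import (
    assign_population,
    build_response_table,
    clean_records,
    generate_pseudo_absences,
    thin_to_grid,
)
from .predictors import collinearity_filter, extract_env, pca_fit
from .projection import (
    binarize,
    change_areas_km2,
    change_map,
    predict_map,
    range_change,
    restrict_to_region,
)
from .simulate import (
    SCENARIO_PRESETS,
    NicheFunction,
    PopulationNiches,
    default_boundary,
    sample_occurrences,
    scenario_stacks,
    simulate_mpas,
    simulate_predictors,
)

log = logging.getLogger(__name__)

STAGES = ["simulate", "prep", "niche", "fit", "project", "gaps"]


def derive_seed(seed: int, stage: str) -> int:
    """Stage-specific seed below 2^31, stable across stage re-ordering."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Every stage parameter in one place; defaults give the demo run."""

    out_dir: str = "runs/demo"
    seed: int = 0
    level: str = "all"  # species | EIOS | WPI | all

    # study window (defaults: a compact demo window inside the study area)
    lon_min: float = 105.0
    lon_max: float = 130.0
    lat_min: float = -8.0
    lat_max: float = 9.0
    resolution: float = 5.0 / 60.0

    # synthetic truth
    n_presences: int = 400
    autocorr_cells: float = 6.0
    sea_fraction: float = 0.8
    boundary_lon: float = 119.0
    # optima sit below the ambient temperature mode: the populations live
    # near their upper thermal limit, so every warming scenario costs habitat
    eios_temp_optimum: float = 27.4
    wpi_temp_optimum: float = 27.0
    eios_sal_optimum: float = 32.8
    wpi_sal_optimum: float = 33.6
    temp_tolerance: float = 1.2
    sal_tolerance: float = 1.0
    mpa_coverage: float = 0.16
    mpa_polygons: int = 25

    # occurrence prep
    pseudo_absence_strategy: str = "envelope"
    thinning: bool = True

    # niche
    pca_k: int = 4
    hv_quantile: float = 0.95
    hv_points: int = 20000

    # modelling
    algorithms: list[str] = field(default_factory=lambda: list(ALGORITHMS))
    folds: int = 5
    replicates: int = 10
    tss_min: float = 0.7
    auc_min: float = 0.8
    weighting: str = "equal"

    def grid(self) -> GridSpec:
        return GridSpec(
            lon_min=self.lon_min, lon_max=self.lon_max,
            lat_min=self.lat_min, lat_max=self.lat_max,
            resolution=self.resolution,
        )

    def levels(self) -> list[str]:
        return ["species", "EIOS", "WPI"] if self.level == "all" else [self.level]

    def effective_boundary_lon(self) -> float:
        """The configured boundary meridian, or the window midline when the
        configured one does not cross the window."""
        if self.lon_min < self.boundary_lon < self.lon_max:
            return self.boundary_lon
        return 0.5 * (self.lon_min + self.lon_max)

    def niches(self) -> PopulationNiches:
        mk = lambda t, s: NicheFunction(
            optima={"temperature_mean": t, "salinity": s},
            tolerances={"temperature_mean": self.temp_tolerance,
                        "salinity": self.sal_tolerance},
        )
        return PopulationNiches(
            west=mk(self.eios_temp_optimum, self.eios_sal_optimum),
            east=mk(self.wpi_temp_optimum, self.wpi_sal_optimum),
            boundary_lon=self.effective_boundary_lon(),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _ensure_dir(path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    return path


def _log_line(ctx: dict, msg: str) -> None:
    log.info(msg)
    with open(ctx["out"] / "run.log", "a") as fh:
        fh.write(msg + "\n")


def new_context(cfg: RunConfig) -> dict:
    out = _ensure_dir(Path(cfg.out_dir))
    return {"cfg": cfg, "out": out}


# ---------------------------------------------------------------------------
# stages

def stage_simulate(ctx: dict) -> dict:
    """Generate predictor stacks (current + four scenarios), presences,
    the population boundary and synthetic MPAs."""
    cfg: RunConfig = ctx["cfg"]
    seed = derive_seed(cfg.seed, "simulate")
    grid = cfg.grid()
    stack = simulate_predictors(
        grid, seed=seed, autocorr_cells=cfg.autocorr_cells,
        sea_fraction=cfg.sea_fraction,
    )
    futures = scenario_stacks(stack)
    boundary = default_boundary(grid, lon=cfg.effective_boundary_lon())
    niches = cfg.niches()
    presences = sample_occurrences(
        stack, niches, n=cfg.n_presences, seed=seed + 1, boundary=boundary
    )
    mpas = simulate_mpas(
        grid, stack.mask, coverage_target=cfg.mpa_coverage,
        n_polygons=cfg.mpa_polygons, seed=seed + 2,
    )
    out = ctx["out"]
    write_stack(stack, out / "stack_current")
    for tag, st in futures.items():
        write_stack(st, out / f"stack_{tag}")
    presences.to_csv(out / "occurrences_raw.csv", index=False)
    write_mpas_geojson(mpas, out / "mpas.geojson")
    (out / "boundary.geojson").write_text(
        json.dumps({"type": "Feature", "properties": {},
                    "geometry": mapping(boundary)})
    )
    _log_line(ctx, f"simulate: {int(stack.mask.sum())} sea cells, "
                   f"{len(presences)} presences, {len(mpas)} MPA polygons")
    ctx.update(stack=stack, futures=futures, boundary=boundary,
               presences_raw=presences, mpas=mpas, niches=niches)
    return ctx


def stage_prep(ctx: dict) -> dict:
    """Clean, thin and label occurrences; build balanced response tables
    for each modelling level (split happens after thinning)."""
    cfg: RunConfig = ctx["cfg"]
    seed = derive_seed(cfg.seed, "prep")
    stack: PredictorStack = ctx["stack"]
    occ = clean_records(ctx["presences_raw"], stack)
    if cfg.thinning:
        occ = thin_to_grid(occ, stack.grid)
    occ = assign_population(occ, ctx["boundary"], stack.grid)
    occ["response"] = 1
    out = ctx["out"]
    occ.to_csv(out / "occurrences_thinned.csv", index=False)
    counts = occ["population"].value_counts().to_dict()
    _log_line(ctx, f"prep: {len(occ)} presences after thinning "
                   f"(EIOS {counts.get('EIOS', 0)}, WPI {counts.get('WPI', 0)})")

    tables: dict[str, pd.DataFrame] = {}
    for i, level in enumerate(cfg.levels()):
        pres = occ if level == "species" else occ[occ["population"] == level]
        pres = pres.reset_index(drop=True)
        if pres.empty:
            raise ValueError(f"no presences for level '{level}'")
        absences = generate_pseudo_absences(
            pres, stack, seed=seed + i, strategy=cfg.pseudo_absence_strategy
        )
        table = build_response_table(pres, absences)
        table.to_csv(out / f"response_{level}.csv", index=False)
        tables[level] = table
        _log_line(ctx, f"prep[{level}]: {len(pres)} presences + "
                       f"{len(absences)} pseudo-absences")
    ctx.update(presences=occ, tables=tables)
    return ctx


def stage_niche(ctx: dict) -> dict:
    """Collinearity screening, pooled PCA, per-population hypervolumes and
    the beta decomposition of their difference."""
    cfg: RunConfig = ctx["cfg"]
    seed = derive_seed(cfg.seed, "niche")
    stack: PredictorStack = ctx["stack"]
    occ = ctx["presences"]
    env = extract_env(occ, stack)
    retained, screen = collinearity_filter(env)
    out = ctx["out"]
    screen.to_csv(out / "collinearity_report.csv", index=False)
    _log_line(ctx, f"niche: collinearity screening retained "
                   f"{len(retained)}/{env.shape[1]} predictors")
    pca = pca_fit(env[retained], k=min(cfg.pca_k, len(retained)))
    pca.loadings.to_csv(out / "pca_loadings.csv")
    _log_line(ctx, f"niche: first {pca.k} PCs explain "
                   f"{100 * pca.cumulative_variance:.1f}% of variance")
    is_west = (occ["population"] == "EIOS").to_numpy()
    hv_w, hv_e = paired_hypervolumes(
        pca.scores[is_west], pca.scores[~is_west],
        n_stochastic=cfg.hv_points, quantile=cfg.hv_quantile, seed=seed,
    )
    cmp = overlap(hv_w, hv_e, seed=seed + 2)
    comparison_frame(cmp).to_csv(out / "niche_comparison.csv", index=False)
    _log_line(ctx, f"niche: beta_total={cmp.beta_total:.3f} "
                   f"(shift {cmp.beta_shift:.3f}, rich {cmp.beta_rich:.3f})")
    ctx.update(env_presences=env, retained=retained, pca=pca,
               hypervolumes=(hv_w, hv_e), niche_cmp=cmp)
    return ctx


def stage_fit(ctx: dict) -> dict:
    """Cross-validate the candidate algorithms per level, gate on TSS/AUC,
    build the weighted ensembles and derive the maxTSS thresholds."""
    cfg: RunConfig = ctx["cfg"]
    seed = derive_seed(cfg.seed, "fit")
    stack: PredictorStack = ctx["stack"]
    specs = default_specs(cfg.algorithms)
    out = ctx["out"]
    ensembles, thresholds, scores_by_level = {}, {}, {}
    for i, level in enumerate(cfg.levels()):
        table = ctx["tables"][level]
        env = extract_env(table, stack)
        y = table["response"].to_numpy(dtype=int)
        scores = cross_validate(specs, env, y, folds=cfg.folds,
                                replicates=cfg.replicates, seed=seed + 100 * i)
        scores.table.to_csv(out / f"cv_scores_{level}.csv")
        included, exclusions = select_members(scores, cfg.tss_min, cfg.auc_min)
        exclusions.to_csv(out / f"exclusions_{level}.csv", index=False)
        _log_line(ctx, f"fit[{level}]: included {included}; excluded "
                       f"{exclusions['learner'].tolist()}")
        ens = build_ensemble(included, scores, env, y, weighting=cfg.weighting,
                             seed=seed + 100 * i + 1, specs=specs,
                             tss_min=cfg.tss_min, auc_min=cfg.auc_min)
        full_pred = ens.predict(env)
        tss, auc, tau = evaluate(full_pred, y)
        thresholds[level] = tau
        _log_line(ctx, f"fit[{level}]: full-data TSS={tss:.3f} AUC={auc:.3f} "
                       f"maxTSS threshold={tau:.3f}")
        imp = variable_importance(ens, env, seed=seed + 100 * i + 2)
        imp.to_csv(out / f"importance_{level}.csv")
        curves = {v: response_curve(ens, env, v) for v in env.columns}
        pd.concat(curves, names=["variable", "i"]).reset_index(
            level=0
        ).to_csv(out / f"response_curves_{level}.csv", index=False)
        ensembles[level] = ens
        scores_by_level[level] = scores
    ctx.update(ensembles=ensembles, thresholds=thresholds,
               cv_scores=scores_by_level)
    return ctx


def _region_mask(cfg: RunConfig, grid: GridSpec, level: str) -> np.ndarray:
    lon = grid.lon_centers()
    west = np.broadcast_to(lon[None, :] < cfg.effective_boundary_lon(), grid.shape)
    if level == "EIOS":
        return west.copy()
    if level == "WPI":
        return (~west).copy()
    return np.ones(grid.shape, dtype=bool)


def stage_project(ctx: dict) -> dict:
    """Continuous and binary maps for the current and the four scenario
    stacks per level, change maps and the range-change table."""
    cfg: RunConfig = ctx["cfg"]
    stack: PredictorStack = ctx["stack"]
    out = ctx["out"]
    binary_maps: dict[tuple[str, str], object] = {}
    rows = []
    scenario_order = ["2050s_RCP2.6", "2100s_RCP2.6", "2050s_RCP8.5", "2100s_RCP8.5"]
    for level, ens in ctx["ensembles"].items():
        tau = ctx["thresholds"][level]
        region = _region_mask(cfg, stack.grid, level)
        cur_cont = predict_map(ens, stack, model_id=level)
        write_raster(cur_cont.layer, out / f"suitability_{level}_current.asc")
        cur_bin = restrict_to_region(binarize(cur_cont, tau), region)
        write_raster(cur_bin.layer, out / f"binary_{level}_current.asc")
        binary_maps[(level, "current")] = cur_bin
        for tag in scenario_order:
            fut_cont = predict_map(ens, ctx["futures"][tag], model_id=level)
            fut_bin = restrict_to_region(binarize(fut_cont, tau), region)
            binary_maps[(level, tag)] = fut_bin
            cmap = change_map(cur_bin, fut_bin)
            write_raster(fut_bin.layer, out / f"binary_{level}_{tag}.asc")
            write_raster(cmap.layer, out / f"change_{level}_{tag}.asc")
            areas = change_areas_km2(cmap)
            rows.append(
                {
                    "level": level,
                    "scenario": tag,
                    "range_change_pct": round(range_change(cur_bin, fut_bin), 2),
                    **{f"{k}_km2": round(v, 2) for k, v in areas.items()},
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(out / "range_change.csv", index=False)
    for _, r in table.iterrows():
        _log_line(ctx, f"project[{r['level']}][{r['scenario']}]: "
                       f"range change {r['range_change_pct']:+.2f}%")
    ctx.update(binary_maps=binary_maps, range_change_table=table)
    return ctx


def stage_gaps(ctx: dict) -> dict:
    """Overlay species-level binary maps with the MPAs: protection stats
    per scenario plus the PCA/POCA conservation masks."""
    cfg: RunConfig = ctx["cfg"]
    stack: PredictorStack = ctx["stack"]
    out = ctx["out"]
    mpa_mask = rasterize_mpas(ctx["mpas"], stack.grid)
    level = "species" if "species" in ctx["ensembles"] else cfg.levels()[0]
    rows = []
    for (lvl, tag), bmap in ctx["binary_maps"].items():
        if lvl != level:
            continue
        rows.append(protection_stats(bmap, mpa_mask, scenario=tag))
    report = gap_report_frame(rows)
    report.to_csv(out / "gap_report.csv", index=False)
    for r in rows:
        _log_line(ctx, f"gaps[{r.scenario}]: {r.predicted_km2:.0f} km2 "
                       f"predicted, {r.percent_protected:.2f}% protected")
    cur = ctx["binary_maps"][(level, "current")]
    fut = ctx["binary_maps"][(level, "2100s_RCP8.5")]
    pca_mask, poca_mask = classify_conservation(cur, fut, mpa_mask)
    for name, m in (("pca", pca_mask), ("poca", poca_mask)):
        lyr = Layer(grid=stack.grid, values=m.astype(float),
                    mask=stack.mask.copy(), name=f"{name}_mask")
        write_raster(lyr, out / f"{name}_mask.asc")
    _log_line(ctx, f"gaps: PCA {int(pca_mask.sum())} cells, "
                   f"POCA {int(poca_mask.sum())} cells")
    ctx.update(mpa_mask=mpa_mask, gap_report=report,
               pca_mask=pca_mask, poca_mask=poca_mask)
    return ctx


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "niche": stage_niche,
    "fit": stage_fit,
    "project": stage_project,
    "gaps": stage_gaps,
}


def run(cfg: RunConfig, upto: str = "gaps") -> dict:
    """Run the pipeline up to (and including) ``upto``; returns the context.

    Writes a manifest (config, derived stage seeds, versions) on success;
    a failing stage aborts with its name while earlier outputs remain.
    """
    ctx = new_context(cfg)
    last = STAGES.index(upto)
    for stage in STAGES[: last + 1]:
        try:
            ctx = _STAGE_FUNCS[stage](ctx)
        except Exception as exc:
            _log_line(ctx, f"ABORT in stage '{stage}': {exc}")
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "stage_seeds": {s: derive_seed(cfg.seed, s) for s in STAGES},
        "stages_run": STAGES[: last + 1],
    }
    (ctx["out"] / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ctx
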