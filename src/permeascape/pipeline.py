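"""End-to-end orchestration: scenarios -> summaries -> surfaces ->
segments -> models -> validation, under one config with deterministic
seeding.

A run covers one or more study cells (``n_cells``). Genetic summaries,
membership surfaces and B/W segments are computed per cell; the segment
tables are then pooled into a single analysis set, as the study design
pools segments from all cells, and the bootstrap regressions and
validation run on the pooled table. Every stage draws its randomness
from a sub-seed derived from the master seed and the stage name, so
stage outputs are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .models import bootstrap_models, design_from_table
from .popgen import diversity_summary, mantel_ibd, pairwise_fst
from .segments import build_segments, segment_table
from .surface import assign_posteriors, build_surface, modal_surface, population_weights
from .synthetic import ScenarioConfig, generate_scenario, stage_rng
from .types import (
    DEFAULT_FALLBACK_W_LENGTH,
    DEFAULT_WIDTHS,
    ConfigurationError,
    validate_widths,
)
from .validation import validate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "summaries", "surface", "segments", "fit", "validate")

__all__ = ["RunConfig", "run_pipeline", "STAGES"]


@dataclass
class RunConfig:
    """Single configuration governing a pipeline run.

    Either ``scenario`` (synthetic generation parameters, optionally
    replicated over ``n_cells`` study cells) or the four input paths
    (raster, sites, genotypes, partition) must be provided. Bootstrap
    and validation defaults mirror the analysis design: B = 1000
    resamples, a 900-iteration retention rule, 20% validation subsets
    redrawn 1000 times, and the 776 m fallback W-segment length.
    """

    output_dir: str = "permeascape_run"
    seed: int = 0
    scenario: dict | None = None
    n_cells: int = 1
    raster_path: str | None = None
    sites_path: str | None = None
    genotypes_path: str | None = None
    partition_path: str | None = None
    widths: tuple[float, ...] = DEFAULT_WIDTHS
    bootstrap_B: int = 1000
    retain_threshold: int = 900
    validation_fraction: float = 0.2
    validation_reps: int = 1000
    validation_widths: tuple[float, ...] | None = (100.0, 200.0, 400.0)
    median_scope: str = "global"
    fallback_w_length: float = DEFAULT_FALLBACK_W_LENGTH
    surface_source: str = "truth"  # "truth" (synthetic only) | "assign"
    fst_permutations: int = 199
    fis_permutations: int = 199
    mantel_permutations: int = 999
    do_summaries: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.widths = validate_widths(self.widths)
        if self.retain_threshold > self.bootstrap_B:
            raise ConfigurationError("retain_threshold cannot exceed bootstrap_B")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ConfigurationError("validation_fraction must lie in (0, 1)")
        if self.median_scope not in ("global", "pair"):
            raise ConfigurationError("median_scope must be 'global' or 'pair'")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.scenario is None:
            if self.n_cells != 1:
                raise ConfigurationError("n_cells > 1 requires a synthetic scenario")
            for name in ("raster_path", "sites_path", "genotypes_path", "partition_path"):
                value = getattr(self, name)
                if value is None:
                    raise ConfigurationError(
                        f"missing input: provide 'scenario' or the '{name}' field"
                    )
                if not Path(value).exists():
                    raise ConfigurationError(f"{name} does not exist: {value}")

    @classmethod
    def ci_profile(cls, **kw) -> "RunConfig":
        """Reduced-size profile for quick runs."""
        defaults = dict(bootstrap_B=100, retain_threshold=90, validation_reps=50,
                        fst_permutations=99, fis_permutations=99, mantel_permutations=199)
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "widths" in raw:
            raw["widths"] = tuple(raw["widths"])
        if raw.get("validation_widths") is not None:
            raw["validation_widths"] = tuple(raw["validation_widths"])
        return cls(**raw)


@dataclass
class _Cell:
    cell_id: str
    raster: object
    sites: list
    genotypes: object
    partition: object
    truth_surface: object = None
    surface: object = None
    modal: object = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cells(cfg: RunConfig, out: Path, written: list[Path]) -> list[_Cell]:
    cells: list[_Cell] = []
    if cfg.scenario is not None:
        for ci in range(cfg.n_cells):
            cell_id = f"cell{ci + 1:02d}"
            base_seed = cfg.scenario.get("seed", cfg.seed)
            scen_cfg = ScenarioConfig(**{**cfg.scenario, "seed": base_seed + 1000 * ci})
            scen = generate_scenario(scen_cfg)
            sites = [dataclasses.replace(s, cell_id=cell_id) for s in scen.sites]
            prefix = "" if cfg.n_cells == 1 else f"{cell_id}_"
            pio.write_raster(out / f"{prefix}landcover.asc", scen.raster)
            pio.write_sites_csv(out / f"{prefix}sites.csv", sites)
            pio.write_genotypes_csv(out / f"{prefix}genotypes.csv", scen.genotypes)
            pio.write_partition_csv(out / f"{prefix}partition.csv", scen.partition)
            pio.write_scenario_truth(out / f"{prefix}scenario_truth.yaml", scen_cfg)
            written += [out / f"{prefix}{f}" for f in (
                "landcover.asc", "sites.csv", "genotypes.csv", "partition.csv",
                "scenario_truth.yaml")]
            cells.append(_Cell(cell_id=cell_id, raster=scen.raster, sites=sites,
                               genotypes=scen.genotypes, partition=scen.partition,
                               truth_surface=scen.surface))
    else:
        cells.append(_Cell(
            cell_id="cell01",
            raster=pio.read_raster(cfg.raster_path),
            sites=pio.read_sites_csv(cfg.sites_path),
            genotypes=pio.read_genotypes_csv(cfg.genotypes_path),
            partition=pio.read_partition_csv(cfg.partition_path),
        ))
    return cells


def run_pipeline(cfg: RunConfig, through: str = "validate") -> dict:
    """Run the pipeline up to (and including) stage ``through``.

    Writes per-cell inputs, a pooled segments CSV, per-width model
    summary CSVs, a validation report and a manifest (config echo,
    per-file content hashes, master seed) into ``cfg.output_dir``.
    Returns a dict of the in-memory stage results.
    """
    if through not in STAGES:
        raise ConfigurationError(f"unknown stage {through!r}; stages are {STAGES}")
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    upto = STAGES.index(through)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {"config": cfg}

    # -- stage: simulate / load inputs
    cells = _load_cells(cfg, out, written)
    results["cells"] = cells
    if upto == 0:
        return _finish(results, cfg, out, written)

    # -- stage: genetic summaries (per cell)
    if cfg.do_summaries:
        div_tables, fst_results, mantel_results = [], {}, {}
        for cell in cells:
            div = diversity_summary(
                cell.genotypes, cell.partition, n_perm=cfg.fis_permutations,
                seed=int(stage_rng(cfg.seed, f"fis-{cell.cell_id}").integers(2**31)))
            t = div.table.copy()
            t.insert(0, "cell", cell.cell_id)
            div_tables.append(t)
            if cell.partition.k >= 2:
                fst = pairwise_fst(
                    cell.genotypes, cell.partition, n_perm=cfg.fst_permutations,
                    seed=int(stage_rng(cfg.seed, f"fst-{cell.cell_id}").integers(2**31)))
                fst_results[cell.cell_id] = fst
                centroids = _population_centroids(cell.partition, cell.sites)
                if centroids is not None and len(fst.populations) >= 4:
                    mantel_results[cell.cell_id] = mantel_ibd(
                        fst, centroids, n_perm=cfg.mantel_permutations,
                        seed=int(stage_rng(cfg.seed, f"mantel-{cell.cell_id}").integers(2**31)))
        pd.concat(div_tables).to_csv(out / "diversity.csv", index=False)
        written.append(out / "diversity.csv")
        results["diversity"] = pd.concat(div_tables)
        if fst_results:
            rows = []
            for cid, fst in fst_results.items():
                for i, p1 in enumerate(fst.populations):
                    for j, p2 in enumerate(fst.populations):
                        if j > i and not np.isnan(fst.theta[i, j]):
                            rows.append(dict(cell=cid, pop_a=p1, pop_b=p2,
                                             theta=fst.theta[i, j],
                                             p_value=fst.p_value[i, j]))
            pd.DataFrame(rows).to_csv(out / "fst.csv", index=False)
            written.append(out / "fst.csv")
            results["fst"] = fst_results
        if mantel_results:
            results["mantel"] = mantel_results
    if upto == 1:
        return _finish(results, cfg, out, written)

    # -- stage: membership surfaces (per cell)
    for cell in cells:
        if cfg.surface_source == "truth" and cell.truth_surface is not None:
            cell.surface = cell.truth_surface
        else:
            post, flagged = assign_posteriors(cell.genotypes, cell.partition)
            if flagged:
                logger.warning("%s: %d individuals with no typed locus assigned uniformly",
                               cell.cell_id, len(flagged))
            site_by_id = {s.id: s for s in cell.sites}
            coords = np.array([
                (site_by_id[sid].x, site_by_id[sid].y)
                for sid in cell.genotypes.site_ids
            ])
            cell.surface = build_surface(
                post, coords, k=cell.partition.k,
                weights=population_weights(cell.partition, cell.genotypes.individuals))
        prefix = "" if len(cells) == 1 else f"{cell.cell_id}_"
        pio.write_surface(out / f"{prefix}surface", cell.surface)
        written += sorted(out.glob(f"{prefix}surface*"))
        cell.modal = modal_surface(cell.surface)
    results["surfaces"] = {c.cell_id: c.surface for c in cells}
    if upto == 2:
        return _finish(results, cfg, out, written)

    # -- stage: segments (per cell, pooled table)
    all_segments: dict[str, list] = {}
    tables = []
    for cell in cells:
        segs = build_segments(cell.partition, cell.sites, scope=cfg.median_scope,
                              fallback_length=cfg.fallback_w_length)
        if not segs:
            logger.info("%s: no segments", cell.cell_id)
            continue
        t = segment_table(segs, cell.raster, modal_grid=cell.modal,
                          surf=cell.surface, widths=cfg.widths)
        t.insert(0, "cell", cell.cell_id)
        tables.append(t)
        all_segments[cell.cell_id] = segs
    if not tables:
        raise ConfigurationError("no segments could be built from the inputs")
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "segments.csv", index=False)
    geo = {cid: pio.segments_geojson(segs, width=cfg.widths[0])
           for cid, segs in all_segments.items()}
    with open(out / "segments.geojson", "w") as fh:
        json.dump(geo if len(geo) > 1 else next(iter(geo.values())), fh)
    written += [out / "segments.csv", out / "segments.geojson"]
    results.update(segments=all_segments, segment_table=table)
    if upto == 3:
        return _finish(results, cfg, out, written)

    # -- stage: bootstrap models (pooled)
    has_both = table["category"].nunique() == 2
    boots: dict[tuple[str, float], object] = {}
    var_rows, fit_rows = [], []
    for width in cfg.widths:
        kinds = ("logistic", "linear") if has_both else ("linear",)
        for kind in kinds:
            design = design_from_table(table, kind, width=width)
            boot = bootstrap_models(
                design, B=cfg.bootstrap_B, retain=cfg.retain_threshold,
                seed=int(stage_rng(cfg.seed, f"boot-{kind}-{width}").integers(2**31)))
            boots[(kind, width)] = boot
            vt = boot.variable_table()
            vt.insert(0, "width", width)
            vt.insert(0, "model", kind)
            var_rows.append(vt)
            fit_rows.append({"model": kind, "width": width, **boot.fit_summary()})
    pd.concat(var_rows).to_csv(out / "model_variables.csv", index=False)
    pd.DataFrame(fit_rows).to_csv(out / "model_fit.csv", index=False)
    written += [out / "model_variables.csv", out / "model_fit.csv"]
    results.update(bootstraps=boots, model_fit=pd.DataFrame(fit_rows))
    if upto == 4:
        return _finish(results, cfg, out, written)

    # -- stage: validation
    val_rows = []
    vwidths = cfg.validation_widths or cfg.widths
    for width in vwidths:
        if width not in cfg.widths:
            continue
        for kind in ("logistic", "linear"):
            if (kind, width) not in boots:
                continue
            design = design_from_table(table, kind, width=width)
            rep = validate(boots[(kind, width)], design,
                           fraction=cfg.validation_fraction, reps=cfg.validation_reps,
                           seed=int(stage_rng(cfg.seed, f"val-{kind}-{width}").integers(2**31)))
            val_rows.append(dict(model=kind, width=width,
                                 proportion_correct=rep.proportion_correct,
                                 ci_lower=rep.ci_lower, ci_upper=rep.ci_upper,
                                 n_validated=rep.n_validated))
    vdf = pd.DataFrame(val_rows)
    vdf.to_csv(out / "validation.csv", index=False)
    written.append(out / "validation.csv")
    results["validation"] = vdf
    return _finish(results, cfg, out, written)


def _population_centroids(partition, sites) -> np.ndarray | None:
    cent = []
    for p in range(1, partition.k + 1):
        members = [s for s in sites if partition.site_to_pop.get(s.id) == p]
        if not members:
            return None
        cent.append((np.mean([s.x for s in members]), np.mean([s.y for s in members])))
    return np.array(cent)


def _finish(results: dict, cfg: RunConfig, out: Path, written: list[Path]) -> dict:
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "seed": cfg.seed,
        "files": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    results["output_dir"] = out
    return results
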