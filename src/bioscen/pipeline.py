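"""End-to-end experiment orchestration from a single YAML config.

Stages (in order): ``simulate`` -> ``fit`` -> ``project`` -> ``mask`` ->
``metrics`` -> ``partition`` -> ``report``.  Each stage reads the previous
stages' artifacts from the output directory, writes its own, and updates a
JSON run manifest; every source of randomness derives deterministically from
the master seed, so re-running a stage with unchanged inputs reproduces its
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml
from numpy.random import SeedSequence

from . import dispersal, metrics, partition, sdm, world

STAGES = ("simulate", "fit", "project", "mask", "metrics", "partition", "report")

# stage -> artifact whose presence marks the stage as done
_STAGE_SENTINELS = {
    "simulate": "world.npz",
    "fit": "models.joblib",
    "project": "projections.joblib",
    "mask": "masks.npz",
    "metrics": "species_sensitivity.csv",
    "partition": "partition_species.csv",
    "report": "report.txt",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    n_rows: int = 15
    n_cols: int = 20
    cell_size_km: float = 100.0
    corr_length: float = 3.0
    gcm_ids: list[str] = field(default_factory=lambda: list(world.DEFAULT_GCMS))
    rcp_ids: list[str] = field(default_factory=lambda: list(world.DEFAULT_RCPS))
    combos: list[list[str]] | None = None      # None -> full factorial
    periods: list[str] = field(default_factory=lambda: list(world.DEFAULT_PERIODS))
    n_species: int = 20
    prevalence_range: list[float] = field(default_factory=lambda: [0.08, 0.3])
    taxon_mix: dict[str, float] = field(
        default_factory=lambda: {"amphibian": 0.12, "bird": 0.63, "mammal": 0.25})
    buffer_km_by_taxon: dict[str, float] = field(
        default_factory=lambda: dict(dispersal.DEFAULT_BUFFER_KM))
    n_regions: int = 6
    algorithms: list[str] = field(default_factory=lambda: list(sdm.ALGORITHMS))
    n_repetitions: int = 4
    split_fraction: float = 0.7
    n_absences: int | None = None              # None -> min(10*presences, buffer)
    tss_thresholds: list[float] = field(default_factory=lambda: [0.4, 0.6, 0.7])
    delta_beta_semantics: str = "whittaker"
    range_size_bins: int = 3
    partition_scheme: str = "nested"
    seed: int = 1
    # scenario effect sizes (None -> package defaults)
    scenario_effects: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return yaml.safe_dump(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def design(self) -> world.ScenarioDesign:
        combos = (tuple((g, r) for g, r in self.combos) if self.combos is not None
                  else tuple((g, r) for g in self.gcm_ids for r in self.rcp_ids))
        return world.ScenarioDesign(tuple(self.gcm_ids), tuple(self.rcp_ids),
                                    combos, tuple(self.periods))

    def grid(self) -> world.Grid:
        return world.Grid(self.n_rows, self.n_cols, self.cell_size_km)

    def effects(self) -> world.ScenarioEffectConfig:
        if self.scenario_effects is None:
            return world.ScenarioEffectConfig()
        return world.ScenarioEffectConfig(**self.scenario_effects)

    def stage_seed(self, stage: str) -> int:
        return int(SeedSequence([int(self.seed), STAGES.index(stage)])
                   .generate_state(1)[0] % (2**31))


def expected_projection_count(
    n_algorithms: int, n_repetitions: int, n_combos: int, n_periods: int,
    n_species: int = 1,
) -> dict[str, int]:
    """Closed-form design arithmetic: future projections per species and in
    total, assuming no dropped models."""
    per_species = n_algorithms * n_repetitions * n_combos * n_periods
    return {"per_species": per_species, "total": per_species * n_species}


# ------------------------------------------------------------------ manifest

def _load_manifest(outdir: Path) -> dict:
    p = outdir / "manifest.json"
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _update_manifest(outdir: Path, config: ExperimentConfig, stage: str,
                     outputs: list[str], counts: dict) -> None:
    man = _load_manifest(outdir)
    man["config_hash"] = config.config_hash()
    man["tool"] = "bioscen 0.1.0"
    man["stages"][stage] = {"outputs": sorted(outputs), "counts": counts}
    (outdir / "manifest.json").write_text(json.dumps(man, indent=2, sort_keys=True))


def _require(outdir: Path, stage: str) -> None:
    sentinel = outdir / _STAGE_SENTINELS[stage]
    if not sentinel.exists():
        raise PipelineError(
            f"missing artifact {sentinel.name!r}: run the {stage!r} stage first")


# -------------------------------------------------------------- world (de)ser

def _save_world(outdir: Path, cube: world.ClimateCube,
                species: list[world.VirtualSpecies], regions: world.RegionMap) -> None:
    arrays: dict[str, np.ndarray] = {}
    for v in world.VARIABLES:
        arrays[f"current|{v}"] = cube.current[v]
    for (g, r, p), layers in cube.future.items():
        for v in world.VARIABLES:
            arrays[f"future|{g}|{r}|{p}|{v}"] = layers[v]
    arrays["regions"] = regions.labels
    for sp in species:
        arrays[f"range|{sp.species_id}"] = sp.range_mask
    np.savez(outdir / "world.npz", **arrays)
    rows = []
    for sp in species:
        row = {"species_id": sp.species_id, "taxon": sp.taxon,
               "prevalence_target": sp.prevalence_target, "range_size": sp.range_size}
        for v in world.VARIABLES:
            row[f"optimum_{v}"] = sp.niche_optimum[v]
            row[f"breadth_{v}"] = sp.niche_breadth[v]
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "species.csv", index=False, float_format="%.17g")


def _load_world(outdir: Path, config: ExperimentConfig
                ) -> tuple[world.ClimateCube, list[world.VirtualSpecies], world.RegionMap]:
    _require(outdir, "simulate")
    grid = config.grid()
    design = config.design()
    with np.load(outdir / "world.npz") as npz:
        current = world.ClimateLayers(
            grid, {v: npz[f"current|{v}"] for v in world.VARIABLES})
        future = {}
        for key in design.scenario_keys():
            g, r, p = key
            future[key] = world.ClimateLayers(
                grid, {v: npz[f"future|{g}|{r}|{p}|{v}"] for v in world.VARIABLES})
        regions = world.RegionMap(grid, npz["regions"])
        ranges = {k.split("|", 1)[1]: npz[k] for k in npz.files if k.startswith("range|")}
    cube = world.ClimateCube(current, future, design)
    meta = pd.read_csv(outdir / "species.csv")
    species = []
    for rec in meta.to_dict("records"):
        species.append(world.VirtualSpecies(
            species_id=rec["species_id"], taxon=rec["taxon"],
            niche_optimum={v: rec[f"optimum_{v}"] for v in world.VARIABLES},
            niche_breadth={v: rec[f"breadth_{v}"] for v in world.VARIABLES},
            prevalence_target=rec["prevalence_target"],
            range_mask=ranges[rec["species_id"]].astype(bool),
        ))
    return cube, species, regions


# -------------------------------------------------------------------- stages

def stage_simulate(config: ExperimentConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())
    seed = config.stage_seed("simulate")
    grid = config.grid()
    current = world.simulate_current_climate(grid, config.corr_length, seed)
    cube = world.simulate_scenario_climate(current, config.design(), config.effects(), seed)
    species = world.simulate_species(
        current, config.n_species, config.taxon_mix,
        tuple(config.prevalence_range), seed)
    regions = world.assign_regions(grid, config.n_regions, seed)
    _save_world(outdir, cube, species, regions)
    counts = {"species_generated": len(species), "n_scenarios": cube.design.n_scenarios,
              "n_regions": config.n_regions}
    _update_manifest(outdir, config, "simulate",
                     ["world.npz", "species.csv", "config.yaml"], counts)
    return counts


def stage_fit(config: ExperimentConfig, outdir: Path) -> dict:
    cube, species, _ = _load_world(outdir, config)
    seed = config.stage_seed("fit")
    all_models: dict[str, list[sdm.FittedSDM]] = {}
    rows = []
    for si, sp in enumerate(species):
        sp_seed = int(SeedSequence([seed, si]).generate_state(1)[0] % (2**31))
        _, models = sdm.fit_species_models(
            sp, cube.current, config.buffer_km_by_taxon[sp.taxon],
            config.n_repetitions, tuple(config.algorithms), sp_seed,
            config.n_absences)
        all_models[sp.species_id] = models
        for m in models:
            rows.append({"species_id": sp.species_id, "taxon": sp.taxon,
                         "algorithm": m.algorithm, "repetition": m.repetition,
                         "tss": m.tss_score, "cutoff": m.cutoff,
                         "converged": m.converged})
    registry = pd.DataFrame(rows)
    registry.to_csv(outdir / "models.csv", index=False, float_format="%.17g")
    joblib.dump(all_models, outdir / "models.joblib")
    counts = {"models_fitted": len(registry),
              "mean_tss": float(registry["tss"].mean())}
    for thr in config.tss_thresholds:
        counts[f"models_retained_tss_{thr}"] = int((registry["tss"] >= thr).sum())
    _update_manifest(outdir, config, "fit", ["models.csv", "models.joblib"], counts)
    return counts


def stage_project(config: ExperimentConfig, outdir: Path) -> dict:
    cube, species, _ = _load_world(outdir, config)
    _require(outdir, "fit")
    all_models = joblib.load(outdir / "models.joblib")
    # project every model above the laxest threshold; stricter policies filter
    # records downstream so all three ANOVA columns share one projection pass
    policy = sdm.TSSThresholdPolicy(min(config.tss_thresholds))
    projections: dict[str, sdm.SpeciesProjections] = {}
    excluded = []
    registry = pd.read_csv(outdir / "models.csv")
    registry["retained"] = registry["converged"] & (
        registry["tss"] >= policy.threshold)
    for sp in species:
        models = [m for m in all_models[sp.species_id] if policy.retains(m)]
        if not models:
            warnings.warn(f"{sp.species_id}: zero retained models; excluded",
                          stacklevel=2)
            excluded.append(sp.species_id)
            continue
        domain = dispersal.limited_dispersal_mask(
            sp.range_mask, cube.grid, config.buffer_km_by_taxon[sp.taxon],
            sp.species_id).mask
        current = {}
        future = {}
        for m in models:
            current[(m.algorithm, m.repetition)] = sdm.project(m, cube.current, domain)
            for key, layers in cube.future.items():
                future[(m.algorithm, m.repetition) + key] = sdm.project(m, layers, domain)
        projections[sp.species_id] = sdm.SpeciesProjections(sp, models, current,
                                                            future, domain)
    proj_cube = sdm.ProjectionCube(cube.grid, projections, registry, excluded)
    joblib.dump(proj_cube, outdir / "projections.joblib")
    n_future = sum(p.n_future for p in projections.values())
    expected = expected_projection_count(
        len(config.algorithms), config.n_repetitions,
        len(config.design().combos), len(config.periods), len(species))
    counts = {"future_projections": n_future,
              "expected_if_no_drops": expected["total"],
              "species_excluded": len(excluded)}
    _update_manifest(outdir, config, "project", ["projections.joblib"], counts)
    return counts


def stage_mask(config: ExperimentConfig, outdir: Path) -> dict:
    cube, species, _ = _load_world(outdir, config)
    arrays = {}
    for sp in species:
        nd = dispersal.no_dispersal_mask(sp.range_mask, sp.species_id)
        ld = dispersal.limited_dispersal_mask(
            sp.range_mask, cube.grid, config.buffer_km_by_taxon[sp.taxon],
            sp.species_id)
        arrays[f"{sp.species_id}|no_dispersal"] = nd.mask
        arrays[f"{sp.species_id}|limited_dispersal"] = ld.mask
    np.savez(outdir / "masks.npz", **arrays)
    counts = {"masks_written": len(arrays)}
    _update_manifest(outdir, config, "mask", ["masks.npz"], counts)
    return counts


def stage_metrics(config: ExperimentConfig, outdir: Path) -> dict:
    _require(outdir, "project")
    _require(outdir, "mask")
    _, _, regions = _load_world(outdir, config)
    proj_cube: sdm.ProjectionCube = joblib.load(outdir / "projections.joblib")
    species_tab = metrics.species_sensitivity_table(proj_cube)
    pixel_tab = metrics.pixel_sensitivity_table(proj_cube)
    region_tab = metrics.region_sensitivity_table(
        proj_cube, regions, config.delta_beta_semantics)
    species_tab.to_csv(outdir / "species_sensitivity.csv", index=False,
                       float_format="%.17g")
    pixel_tab.to_csv(outdir / "pixel_sensitivity.csv", index=False,
                     float_format="%.17g")
    region_tab.to_csv(outdir / "region_sensitivity.csv", index=False,
                      float_format="%.17g")
    counts = {
        "species_records": len(species_tab),
        "pixel_records": len(pixel_tab),
        "region_records": len(region_tab),
        "species_records_undefined": int(species_tab[["ccs", "lcs"]].isna().any(axis=1).sum()),
    }
    _update_manifest(outdir, config, "metrics",
                     ["species_sensitivity.csv", "pixel_sensitivity.csv",
                      "region_sensitivity.csv"], counts)
    return counts


def stage_partition(config: ExperimentConfig, outdir: Path) -> dict:
    _require(outdir, "metrics")
    species_tab = pd.read_csv(outdir / "species_sensitivity.csv")
    pixel_tab = pd.read_csv(outdir / "pixel_sensitivity.csv")
    scheme = config.partition_scheme
    frames = []
    for metric_name in ("ccs", "lcs"):
        cmp_tab = partition.threshold_sensitivity(
            species_tab, tuple(config.tss_thresholds), response=metric_name,
            scheme=scheme)
        cmp_tab["metric"] = metric_name
        frames.append(cmp_tab)
        # full-factorial cross-check at the strictest threshold
        strict = species_tab[species_tab["tss"] >= max(config.tss_thresholds)]
        if not strict.empty:
            ff = partition.full_factorial_partition(strict, response=metric_name).to_frame()
            ff["metric"] = metric_name
            ff["tss_threshold"] = max(config.tss_thresholds)
            frames.append(ff)
    part_species = pd.concat(frames, ignore_index=True)
    part_species.to_csv(outdir / "partition_species.csv", index=False,
                        float_format="%.17g")

    strict_thr = max(config.tss_thresholds)
    strict_tab = species_tab[species_tab["tss"] >= strict_thr]
    bins = metrics.bin_by_range_size(
        strict_tab.groupby("species_id")["range_size"].first(),
        config.range_size_bins)
    bin_frames = []
    for metric_name in ("ccs", "lcs"):
        bf = partition.partition_by_range_bin(strict_tab, bins.labels,
                                              response=metric_name, scheme=scheme)
        bf["metric"] = metric_name
        bin_frames.append(bf)
    pd.concat(bin_frames, ignore_index=True).to_csv(
        outdir / "partition_range_bins.csv", index=False, float_format="%.17g")

    pix_frames = []
    for metric_name in ("delta_alpha", "percent_loss", "beta_t"):
        pf = partition.partition_per_pixel(pixel_tab, response=metric_name,
                                           scheme=scheme)
        pf["metric"] = metric_name
        pix_frames.append(pf)
    pd.concat(pix_frames, ignore_index=True).to_csv(
        outdir / "partition_pixels.csv", index=False, float_format="%.17g")

    region_tab = pd.read_csv(outdir / "region_sensitivity.csv")
    reg_frames = []
    for (assumption, rid), sub in region_tab.groupby(["assumption", "region_id"]):
        part_r = partition.nested_partition(sub, response="delta_beta_s")
        fr = part_r.to_frame()
        fr["assumption"], fr["region_id"] = assumption, rid
        reg_frames.append(fr)
    pd.concat(reg_frames, ignore_index=True).to_csv(
        outdir / "partition_regions.csv", index=False, float_format="%.17g")

    counts = {"species_partitions": len(part_species),
              "range_bins": int(bins.n_bins)}
    _update_manifest(outdir, config, "partition",
                     ["partition_species.csv", "partition_range_bins.csv",
                      "partition_pixels.csv", "partition_regions.csv"], counts)
    return counts


def stage_report(config: ExperimentConfig, outdir: Path) -> dict:
    _require(outdir, "partition")
    part_species = pd.read_csv(outdir / "partition_species.csv")
    models_tab = pd.read_csv(outdir / "models.csv")
    lines = ["bioscen run summary", "===================", ""]
    lines.append(f"config hash: {config.config_hash()}")
    lines.append(f"mean hold-out TSS across fitted models: {models_tab['tss'].mean():.3f}")
    for thr in config.tss_thresholds:
        kept = int((models_tab["tss"] >= thr).sum())
        lines.append(f"models retained at TSS >= {thr}: {kept}/{len(models_tab)}")
    lines.append("")
    strict = max(config.tss_thresholds)
    for metric_name in ("ccs", "lcs"):
        # CSV round-trips of floats are not exact under pandas' fast parser
        near = np.isclose(part_species["tss_threshold"], strict)
        sel = part_species[(part_species["metric"] == metric_name) & near
                           & (part_species["scheme"] == config.partition_scheme)]
        lines.append(f"{metric_name.upper()} deviance shares (TSS >= {strict}, "
                     f"{config.partition_scheme} scheme, % of explained):")
        for rec in sel.to_dict("records"):
            if rec["component"] != "residual":
                lines.append(f"  {rec['component']}: {rec['share_of_explained']:.1f}%")
        lines.append("")
    report = "\n".join(lines)
    (outdir / "report.txt").write_text(report)
    _plot_partitions(part_species, outdir, config)
    _update_manifest(outdir, config, "report",
                     ["report.txt", "partition_shares.png"], {})
    return {"report_lines": len(lines)}


def _plot_partitions(part_species: pd.DataFrame, outdir: Path,
                     config: ExperimentConfig) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, metric_name in zip(axes, ("ccs", "lcs")):
        sel = part_species[(part_species["metric"] == metric_name)
                           & (part_species["scheme"] == config.partition_scheme)
                           & (part_species["component"] != "residual")]
        piv = sel.pivot_table(index="tss_threshold", columns="component",
                              values="share_of_explained")
        piv.plot(kind="bar", ax=ax, legend=(metric_name == "ccs"))
        ax.set_title(metric_name.upper())
        ax.set_ylabel("% of explained deviance")
        ax.set_xlabel("TSS retention threshold")
    fig.tight_layout()
    fig.savefig(outdir / "partition_shares.png", dpi=120)
    plt.close(fig)


_STAGE_FN = {
    "simulate": stage_simulate, "fit": stage_fit, "project": stage_project,
    "mask": stage_mask, "metrics": stage_metrics, "partition": stage_partition,
    "report": stage_report,
}


def run_stage(stage: str, config: ExperimentConfig, outdir: str | Path) -> dict:
    """Run one named stage; raises PipelineError naming the missing upstream
    stage if its artifacts are absent."""
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return _STAGE_FN[stage](config, Path(outdir))


def run_all(config: ExperimentConfig, outdir: str | Path) -> dict:
    """simulate -> ... -> report; returns the merged stage counts."""
    out = {}
    for stage in STAGES:
        out[stage] = run_stage(stage, config, outdir)
    return out
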