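"""Synthetic planar world: climate layers, scenario perturbations, virtual species, regions.

Everything downstream of this module (SDM fitting, dispersal masks, sensitivity
metrics, deviance partitioning) is exercised on worlds generated here, so the
generator exposes the knobs that control the ground-truth variance structure:
how strongly emission pathways (RCPs) shift the climate, how idiosyncratic each
circulation model (GCM) is, and how much unstructured noise sits on top.

The world is a planar equal-area grid (default 100 km cells).  Distances are
Euclidean in km on the grid plane; there is no wrap-around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.ndimage import gaussian_filter

#: The four bioclimatic variables carried by every climate layer set, in order:
#: annual mean temperature (degC), annual temperature range (degC), annual
#: precipitation sum (mm), precipitation seasonality (CV of monthly sums, %).
VARIABLES = ("mean_temp", "temp_range", "precip_sum", "precip_cv")

#: Variables whose scenario deltas are additive (temperature-like) vs
#: multiplicative (precipitation-like).
ADDITIVE_VARIABLES = ("mean_temp", "temp_range")
MULTIPLICATIVE_VARIABLES = ("precip_sum", "precip_cv")

#: Non-negative variables, clipped at zero after perturbation.
NONNEGATIVE_VARIABLES = ("precip_sum", "precip_cv")

TAXA = ("amphibian", "bird", "mammal")


class WorldError(ValueError):
    """Invalid world configuration or unattainable generation request."""


@dataclass(frozen=True)
class Grid:
    """Planar equal-area grid of square cells."""

    n_rows: int
    n_cols: int
    cell_size_km: float = 100.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise WorldError(f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}")
        if self.cell_size_km <= 0:
            raise WorldError(f"cell_size_km must be > 0, got {self.cell_size_km}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers_km(self) -> np.ndarray:
        """(n_cells, 2) array of cell-centre coordinates in km, row-major order."""
        rr, cc = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float) * self.cell_size_km


@dataclass
class ClimateLayers:
    """One map per bioclimatic variable on a shared grid."""

    grid: Grid
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(VARIABLES) - set(self.data)
        if missing:
            raise WorldError(f"missing climate variables: {sorted(missing)}")
        for name, arr in self.data.items():
            if arr.shape != self.grid.shape:
                raise WorldError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
        for name in NONNEGATIVE_VARIABLES:
            if np.any(self.data[name] < 0):
                raise WorldError(f"layer {name!r} must be non-negative")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def as_matrix(self) -> np.ndarray:
        """(n_cells, 4) design matrix in VARIABLES order, row-major cells."""
        return np.column_stack([self.data[v].ravel() for v in VARIABLES])


# Default CMIP5-style ensemble: five GCMs, four RCPs ordered by severity.
DEFAULT_GCMS = ("CESM1-BGC", "CMCC-CMS", "CM5A-LR", "MIROC5", "ESM-MR")
DEFAULT_RCPS = ("RCP2.6", "RCP4.5", "RCP6.0", "RCP8.5")
DEFAULT_PERIODS = ("2041-2060", "2061-2080")


def _default_combos() -> tuple[tuple[str, str], ...]:
    """A 14-member subset of the 5x4 factorial mirroring the study's unbalanced
    ensemble: every GCM is run under RCP4.5 and RCP8.5, and two GCMs each under
    RCP2.6 and RCP6.0."""
    combos = [(g, r) for g in DEFAULT_GCMS for r in ("RCP4.5", "RCP8.5")]
    combos += [("CESM1-BGC", "RCP2.6"), ("CM5A-LR", "RCP2.6")]
    combos += [("MIROC5", "RCP6.0"), ("ESM-MR", "RCP6.0")]
    return tuple(combos)


@dataclass(frozen=True)
class ScenarioDesign:
    """The factorial (GCM x RCP x period) scenario layout.

    ``rcp_ids`` is ordered by emission severity; a scenario's "RCP rank" is its
    1-based position in that ordering and drives the size of the climate delta.
    """

    gcm_ids: tuple[str, ...] = DEFAULT_GCMS
    rcp_ids: tuple[str, ...] = DEFAULT_RCPS
    combos: tuple[tuple[str, str], ...] = field(default_factory=_default_combos)
    periods: tuple[str, ...] = DEFAULT_PERIODS

    def __post_init__(self) -> None:
        if not self.combos:
            raise WorldError("scenario design needs at least one (gcm, rcp) combo")
        if not self.periods:
            raise WorldError("scenario design needs at least one period")
        if len(set(self.combos)) != len(self.combos):
            raise WorldError("duplicate (gcm, rcp) combos")
        full = {(g, r) for g in self.gcm_ids for r in self.rcp_ids}
        bad = set(self.combos) - full
        if bad:
            raise WorldError(f"combos outside the gcm x rcp factorial: {sorted(bad)}")

    def rcp_rank(self, rcp: str) -> int:
        return self.rcp_ids.index(rcp) + 1

    def scenario_keys(self) -> list[tuple[str, str, str]]:
        return [(g, r, p) for (g, r) in self.combos for p in self.periods]

    @property
    def n_scenarios(self) -> int:
        return len(self.combos) * len(self.periods)


@dataclass
class ClimateCube:
    """Current climate plus one ClimateLayers per (gcm, rcp, period)."""

    current: ClimateLayers
    future: dict[tuple[str, str, str], ClimateLayers]
    design: ScenarioDesign

    def __post_init__(self) -> None:
        expected = set(self.design.scenario_keys())
        if set(self.future) != expected:
            raise WorldError("future layers do not match the scenario design")
        for layers in self.future.values():
            if layers.grid != self.current.grid:
                raise WorldError("all layers must share one grid")

    @property
    def grid(self) -> Grid:
        return self.current.grid


@dataclass(frozen=True)
class ScenarioEffectConfig:
    """Controls the ground-truth variance structure of the scenario ensemble.

    ``rcp_severity_step`` is the per-rank climate delta: additive (units of the
    variable) for temperature-like variables, a relative fraction for
    precipitation-like ones.  ``gcm_sd`` is the standard deviation of each
    GCM's idiosyncratic deviation (additive degC for temperature, relative for
    precipitation); the deviation field is drawn once per GCM and reused across
    RCPs and periods, so "GCM" is a coherent factor level.  ``noise_sd`` adds
    scenario-specific noise on top.
    """

    rcp_severity_step: dict[str, float] = field(
        default_factory=lambda: {
            "mean_temp": 0.8,      # degC of warming per RCP severity rank
            "temp_range": 0.25,    # degC
            "precip_sum": -0.025,  # relative change per rank (drying)
            "precip_cv": 0.02,     # relative increase in seasonality
        }
    )
    gcm_sd: dict[str, float] = field(
        default_factory=lambda: {
            "mean_temp": 0.5,
            "temp_range": 0.2,
            "precip_sum": 0.05,
            "precip_cv": 0.03,
        }
    )
    period_scaling: dict[str, float] = field(
        default_factory=lambda: {"2041-2060": 1.0, "2061-2080": 1.6}
    )
    spatial_corr_length: float = 5.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "mean_temp": 0.1,
            "temp_range": 0.05,
            "precip_sum": 0.01,
            "precip_cv": 0.01,
        }
    )

    def __post_init__(self) -> None:
        for name, table in (("gcm_sd", self.gcm_sd), ("noise_sd", self.noise_sd)):
            if any(v < 0 for v in table.values()):
                raise WorldError(f"{name} entries must be >= 0")
        if any(v <= 0 for v in self.period_scaling.values()):
            raise WorldError("period_scaling entries must be > 0")

    def scaled(self, **overrides: dict[str, float]) -> "ScenarioEffectConfig":
        return replace(self, **overrides)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], corr_length: float) -> np.ndarray:
    """Zero-mean, unit-sd spatially autocorrelated Gaussian field."""
    z = rng.standard_normal(shape)
    if corr_length > 0:
        z = gaussian_filter(z, sigma=corr_length, mode="reflect")
    sd = z.std()
    if sd == 0:  # degenerate 1x1 grid
        return np.zeros(shape)
    return (z - z.mean()) / sd


# Baseline gradients: (value at row 0 / col 0, value at last row / col, axis).
_GRADIENTS = {
    "mean_temp": (-12.0, 27.0, "row"),
    "temp_range": (38.0, 12.0, "row"),
    "precip_sum": (150.0, 2400.0, "col"),
    "precip_cv": (95.0, 20.0, "col"),
}

_DEFAULT_NOISE_SD = {"mean_temp": 1.5, "temp_range": 2.0, "precip_sum": 180.0, "precip_cv": 9.0}


def simulate_current_climate(
    grid: Grid,
    corr_length: float = 3.0,
    seed: int = 0,
    noise_sd: dict[str, float] | None = None,
) -> ClimateLayers:
    """Baseline climate: smooth latitudinal/longitudinal gradients plus
    spatially autocorrelated noise.

    With ``noise_sd`` forced to zero each variable is an exact planar gradient.
    Deterministic given ``seed``.
    """
    if corr_length < 0:
        raise WorldError("corr_length must be >= 0")
    sds = dict(_DEFAULT_NOISE_SD)
    if noise_sd is not None:
        sds.update(noise_sd)
    rng = default_rng(SeedSequence([int(seed), 0xC11A]))
    rows = np.linspace(0.0, 1.0, grid.n_rows)[:, None] if grid.n_rows > 1 else np.zeros((1, 1))
    cols = np.linspace(0.0, 1.0, grid.n_cols)[None, :] if grid.n_cols > 1 else np.zeros((1, 1))
    data = {}
    for var in VARIABLES:
        lo, hi, axis = _GRADIENTS[var]
        ramp = rows if axis == "row" else cols
        base = lo + (hi - lo) * ramp
        # a mild cross-axis tilt so no variable is constant along either axis
        tilt = 0.1 * (hi - lo) * (cols if axis == "row" else rows)
        layer = np.broadcast_to(base + tilt, grid.shape).copy()
        if sds[var] > 0:
            layer = layer + sds[var] * _smooth_field(rng, grid.shape, corr_length)
        if var in NONNEGATIVE_VARIABLES:
            layer = np.clip(layer, 0.0, None)
        data[var] = layer
    return ClimateLayers(grid=grid, data=data)


def simulate_scenario_climate(
    current: ClimateLayers,
    design: ScenarioDesign,
    effects: ScenarioEffectConfig | None = None,
    seed: int = 0,
) -> ClimateCube:
    """Perturb the baseline into every (gcm, rcp, period) scenario.

    Temperature-like variables receive additive deltas
    ``rank * step * period_scaling + gcm deviation + noise``; precipitation-like
    variables the multiplicative analogue
    ``x * (1 + rank*step*scaling) * (1 + gcm deviation) * (1 + noise)``,
    clipped at zero.  The GCM deviation field is drawn once per GCM (from the
    master seed) and reused across RCPs and periods; its spatial mean is an
    exact N(0, gcm_sd) draw so the between-GCM variance of the spatial-mean
    delta equals ``gcm_sd**2`` by construction.
    """
    effects = effects or ScenarioEffectConfig()
    grid = current.grid
    ss = SeedSequence([int(seed), 0x5CEA])
    gcm_fields: dict[str, dict[str, np.ndarray]] = {}
    for gi, gcm in enumerate(design.gcm_ids):
        rng = default_rng(SeedSequence([int(seed), 0x5CEA, gi]))
        fields = {}
        for var in VARIABLES:
            sd = effects.gcm_sd.get(var, 0.0)
            level = rng.standard_normal()  # spatial-mean offset, N(0,1)
            shape_field = _smooth_field(rng, grid.shape, effects.spatial_corr_length)
            fields[var] = sd * (level + shape_field)
        gcm_fields[gcm] = fields

    future: dict[tuple[str, str, str], ClimateLayers] = {}
    for si, (gcm, rcp, period) in enumerate(design.scenario_keys()):
        rank = design.rcp_rank(rcp)
        scale = effects.period_scaling.get(period, 1.0)
        rng = default_rng(SeedSequence([int(seed), 0x5CEA, 0xFF, si]))
        data = {}
        for var in VARIABLES:
            step = effects.rcp_severity_step.get(var, 0.0)
            nsd = effects.noise_sd.get(var, 0.0)
            noise = nsd * _smooth_field(rng, grid.shape, effects.spatial_corr_length) if nsd > 0 else 0.0
            dev = gcm_fields[gcm][var]
            if var in ADDITIVE_VARIABLES:
                layer = current[var] + rank * step * scale + dev + noise
            else:
                layer = current[var] * np.clip(1.0 + rank * step * scale, 0.0, None)
                layer = layer * np.clip(1.0 + dev, 0.0, None) * np.clip(1.0 + noise, 0.0, None)
            if var in NONNEGATIVE_VARIABLES:
                layer = np.clip(layer, 0.0, None)
            data[var] = layer
        future[(gcm, rcp, period)] = ClimateLayers(grid=grid, data=data)
    return ClimateCube(current=current, future=future, design=design)


MIN_RANGE_CELLS = 20  # retention filter: species in fewer cells are not modelled


@dataclass
class VirtualSpecies:
    """A species with a known 4-D Gaussian climatic niche and derived range.

    Suitability at a cell is the product over the four variables of
    ``exp(-(x - optimum)**2 / (2 * breadth**2))``; the true range is the set of
    cells above the suitability quantile that realizes the target prevalence.
    """

    species_id: str
    taxon: str
    niche_optimum: dict[str, float]
    niche_breadth: dict[str, float]
    prevalence_target: float
    range_mask: np.ndarray  # boolean, grid shape

    def __post_init__(self) -> None:
        if self.taxon not in TAXA:
            raise WorldError(f"unknown taxon {self.taxon!r}")
        if any(b <= 0 for b in self.niche_breadth.values()):
            raise WorldError("niche breadths must be strictly positive")
        if int(self.range_mask.sum()) < MIN_RANGE_CELLS:
            raise WorldError(
                f"{self.species_id}: range has {int(self.range_mask.sum())} cells"
                f" (< {MIN_RANGE_CELLS})"
            )

    @property
    def range_size(self) -> int:
        return int(self.range_mask.sum())

    def suitability(self, layers: ClimateLayers) -> np.ndarray:
        """Closed-form true suitability of this species on any climate layers."""
        s = np.ones(layers.grid.shape)
        for var in VARIABLES:
            mu = self.niche_optimum[var]
            sig = self.niche_breadth[var]
            s = s * np.exp(-((layers[var] - mu) ** 2) / (2.0 * sig**2))
        return s


def simulate_species(
    climate: ClimateLayers,
    n_species: int,
    taxon_mix: dict[str, float] | None = None,
    prevalence_range: tuple[float, float] = (0.05, 0.3),
    seed: int = 0,
    max_tries: int = 25,
) -> list[VirtualSpecies]:
    """Draw virtual species with Gaussian niches anchored at occupied climates.

    Each species' optimum is the climate of a randomly chosen cell (jittered),
    its breadth a random fraction of each variable's spatial spread, and its
    range the cells above the suitability cutoff realizing a prevalence drawn
    uniformly from ``prevalence_range``.  Species falling below the
    20-presence-cell retention filter are re-drawn up to ``max_tries`` times
    and then dropped with a warning.  Deterministic given ``seed``.
    """
    if n_species < 1:
        raise WorldError("n_species must be >= 1")
    lo, hi = prevalence_range
    if not (0.0 < lo < hi < 1.0):
        raise WorldError(f"prevalence_range must be within (0,1), got {prevalence_range}")
    grid = climate.grid
    if hi * grid.n_cells < MIN_RANGE_CELLS:
        raise WorldError(
            f"grid of {grid.n_cells} cells cannot host {MIN_RANGE_CELLS} presence"
            f" cells at prevalence <= {hi}"
        )
    mix = taxon_mix or {"amphibian": 0.12, "bird": 0.63, "mammal": 0.25}
    taxa = sorted(mix)
    probs = np.array([mix[t] for t in taxa], dtype=float)
    probs = probs / probs.sum()
    rng = default_rng(SeedSequence([int(seed), 0x5BEC]))
    spread = {v: max(climate[v].std(), 1e-9) for v in VARIABLES}
    flat = climate.as_matrix()

    species: list[VirtualSpecies] = []
    for i in range(n_species):
        sp = None
        for _ in range(max_tries):
            taxon = taxa[rng.choice(len(taxa), p=probs)]
            prevalence = rng.uniform(lo, hi)
            anchor = int(rng.integers(grid.n_cells))
            optimum = {
                v: float(flat[anchor, j] + 0.15 * spread[v] * rng.standard_normal())
                for j, v in enumerate(VARIABLES)
            }
            breadth = {v: float(spread[v] * rng.uniform(0.4, 1.2)) for v in VARIABLES}
            suit = np.ones(grid.shape)
            for v in VARIABLES:
                suit *= np.exp(-((climate[v] - optimum[v]) ** 2) / (2.0 * breadth[v] ** 2))
            cutoff = np.quantile(suit, 1.0 - prevalence)
            mask = suit >= cutoff
            if int(mask.sum()) >= MIN_RANGE_CELLS:
                sp = VirtualSpecies(
                    species_id=f"sp{i:04d}",
                    taxon=taxon,
                    niche_optimum=optimum,
                    niche_breadth=breadth,
                    prevalence_target=float(prevalence),
                    range_mask=mask,
                )
                break
        if sp is None:
            warnings.warn(
                f"species sp{i:04d} dropped: could not reach {MIN_RANGE_CELLS}"
                f" presence cells in {max_tries} tries",
                stacklevel=2,
            )
        else:
            species.append(sp)
    return species


@dataclass
class RegionMap:
    """Contiguous rectangular regions tiling the grid (IPBES-style sub-regions)."""

    grid: Grid
    labels: np.ndarray  # int region id per cell, grid shape

    def __post_init__(self) -> None:
        if self.labels.shape != self.grid.shape:
            raise WorldError("region labels must match the grid shape")

    @property
    def region_ids(self) -> list[int]:
        return sorted(np.unique(self.labels).tolist())


def assign_regions(grid: Grid, n_regions: int, seed: int = 0) -> RegionMap:
    """Tile the grid into ``n_regions`` contiguous rectangular blocks.

    The factorization of ``n_regions`` into row x column bands is chosen to
    keep blocks as square as possible; band sizes differ by at most one cell.
    ``seed`` is accepted for interface symmetry but the tiling is deterministic.
    """
    if not (1 <= n_regions <= grid.n_cells):
        raise WorldError(f"n_regions must be in [1, {grid.n_cells}], got {n_regions}")
    best = None
    for a in range(1, n_regions + 1):
        if n_regions % a:
            continue
        b = n_regions // a
        if a > grid.n_rows or b > grid.n_cols:
            continue
        # squareness of the resulting blocks
        cost = abs((grid.n_rows / a) - (grid.n_cols / b))
        if best is None or cost < best[0]:
            best = (cost, a, b)
    if best is None:
        raise WorldError(f"cannot tile {grid.shape} into {n_regions} rectangular blocks")
    _, a, b = best
    row_bands = np.array_split(np.arange(grid.n_rows), a)
    col_bands = np.array_split(np.arange(grid.n_cols), b)
    labels = np.empty(grid.shape, dtype=int)
    rid = 0
    for rb in row_bands:
        for cb in col_bands:
            labels[np.ix_(rb, cb)] = rid
            rid += 1
    return RegionMap(grid=grid, labels=labels)
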