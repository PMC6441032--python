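"""Species-, pixel- and region-level sensitivity metrics in long format.

Species level:
  CCS (change in climatic suitability): relative change in suitable-cell count
  between the future projection under limited dispersal and the current
  projection, ``(future - current) / current``.
  LCS (loss in climatic suitability): fraction of currently suitable cells
  within the species' current range that become unsuitable,
  evaluated under the no-dispersal assumption; in [0, 1].

Pixel level (per taxon, from stacked per-species binary maps):
  delta-alpha: percent change in species richness where current richness > 0.
  percent loss: percent of currently present species lost (no dispersal).
  beta-t: temporal turnover (lost + gained) / (current richness + gained),
  under limited dispersal; in [0, 1].

Region level:
  delta-beta-s: percent change in spatial turnover per sub-region.  Default
  semantics is Whittaker's multiplicative beta, beta = gamma / mean(alpha);
  a literal alternative (percent change in gamma, divided by mean alpha) is
  available via ``semantics="literal"``.

Suitable "area" is a cell count throughout: the grid is equal-area, so counts
are proportional to area.  Undefined values (zero denominators) propagate as
NaN and are excluded from variance partitioning with logged counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dispersal import LIMITED_DISPERSAL, NO_DISPERSAL
from .sdm import ProjectionCube
from .world import RegionMap


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------- species level

def species_ccs(current_suitable: int, future_suitable_limited: int) -> float:
    """(future - current) / current; NaN (flagged) when current is zero."""
    if current_suitable < 0 or future_suitable_limited < 0:
        raise MetricError("cell counts must be non-negative")
    if current_suitable == 0:
        return float("nan")
    return (future_suitable_limited - current_suitable) / current_suitable


def species_lcs(current_suitable_cells: np.ndarray, future_map: np.ndarray) -> float:
    """Fraction of currently suitable cells that become unsuitable.

    ``current_suitable_cells`` is a boolean mask of the cells suitable now
    (already restricted to the no-dispersal domain); ``future_map`` the future
    binary map on the same grid.  NaN when no cell is currently suitable.
    """
    n_cur = int(current_suitable_cells.sum())
    if n_cur == 0:
        return float("nan")
    fut = future_map[current_suitable_cells]
    lost = np.sum(~(fut == 1))  # NaN (outside future domain) counts as lost
    return float(lost) / n_cur


def species_sensitivity_table(cube: ProjectionCube) -> pd.DataFrame:
    """One row per (species, algorithm, repetition, gcm, rcp, period) with CCS
    and LCS, the species' range size and the model's TSS."""
    rows = []
    for sid, proj in cube.species.items():
        sp = proj.species
        range_mask = sp.range_mask
        tss = {(m.algorithm, m.repetition): m.tss_score for m in proj.models}
        for (alg, rep), cur_map in proj.current.items():
            cur_limited = int(np.nansum(cur_map == 1))
            cur_in_range = (cur_map == 1) & range_mask
            for key, fut_map in proj.future.items():
                if key[:2] != (alg, rep):
                    continue
                gcm, rcp, period = key[2:]
                fut_limited = int(np.nansum(fut_map == 1))
                rows.append({
                    "species_id": sid, "taxon": sp.taxon,
                    "algorithm": alg, "repetition": rep,
                    "gcm": gcm, "rcp": rcp, "period": period,
                    "ccs": species_ccs(cur_limited, fut_limited),
                    "lcs": species_lcs(cur_in_range, fut_map),
                    "range_size": sp.range_size,
                    "tss": tss[(alg, rep)],
                })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- pixel level

def pixel_richness(stack: np.ndarray) -> np.ndarray:
    """Per-cell count of suitable species from a (n_species, rows, cols) stack
    of binary maps; NaN where every species' map is missing (outside all
    domains)."""
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise MetricError("need a non-empty (n_species, rows, cols) stack")
    richness = np.nansum(stack == 1, axis=0).astype(float)
    all_missing = np.all(np.isnan(stack), axis=0)
    richness[all_missing] = np.nan
    return richness


def pixel_delta_alpha(current_richness: np.ndarray, future_richness: np.ndarray) -> np.ndarray:
    """100 * (future - current) / current; NaN where current richness is 0."""
    if current_richness.shape != future_richness.shape:
        raise MetricError("richness maps must share one grid")
    out = np.full(current_richness.shape, np.nan)
    ok = np.nan_to_num(current_richness) > 0
    out[ok] = 100.0 * (future_richness[ok] - current_richness[ok]) / current_richness[ok]
    return out


def pixel_percent_loss(current_stack: np.ndarray, future_stack: np.ndarray) -> np.ndarray:
    """Percent of currently present species lost per cell (no-dispersal view)."""
    if current_stack.shape != future_stack.shape:
        raise MetricError("stacks must be paired species-for-species")
    cur = current_stack == 1
    lost = (cur & ~(future_stack == 1)).sum(axis=0).astype(float)
    richness = cur.sum(axis=0).astype(float)
    out = np.full(richness.shape, np.nan)
    ok = richness > 0
    out[ok] = 100.0 * lost[ok] / richness[ok]
    return out


def pixel_beta_t(lost: np.ndarray, gained: np.ndarray, current_richness: np.ndarray) -> np.ndarray:
    """Temporal turnover (lost + gained) / (current richness + gained); NaN
    where the denominator is zero."""
    denom = np.nan_to_num(current_richness) + gained
    out = np.full(denom.shape, np.nan)
    ok = denom > 0
    out[ok] = (lost[ok] + gained[ok]) / denom[ok]
    return out


def _stacks_for(cube: ProjectionCube, taxon: str, alg: str, rep: int,
                key: tuple[str, str, str], assumption: str) -> tuple[np.ndarray, np.ndarray] | None:
    """Paired (current, future) stacks for one taxon and design cell, with each
    species' maps restricted to the requested dispersal domain."""
    cur_maps, fut_maps = [], []
    for proj in cube.species.values():
        if proj.species.taxon != taxon:
            continue
        if (alg, rep) not in proj.current or (alg, rep) + key not in proj.future:
            continue
        cur = proj.current[(alg, rep)]
        fut = proj.future[(alg, rep) + key]
        if assumption == NO_DISPERSAL:
            dom = proj.species.range_mask
            cur = np.where(dom, cur, np.nan)
            fut = np.where(dom, fut, np.nan)
        cur_maps.append(cur)
        fut_maps.append(fut)
    if not cur_maps:
        return None
    return np.stack(cur_maps), np.stack(fut_maps)


def pixel_sensitivity_table(cube: ProjectionCube) -> pd.DataFrame:
    """Long-format pixel metrics: one row per (cell, taxon, algorithm,
    repetition, gcm, rcp, period) carrying delta-alpha, percent loss and
    beta-t.  Delta-alpha and beta-t use the limited-dispersal stacks, percent
    loss the no-dispersal stacks."""
    taxa = sorted({p.species.taxon for p in cube.species.values()})
    design_cells = sorted({k for p in cube.species.values() for k in p.future})
    rows = []
    for taxon in taxa:
        for (alg, rep, gcm, rcp, period) in design_cells:
            key = (gcm, rcp, period)
            lim = _stacks_for(cube, taxon, alg, rep, key, LIMITED_DISPERSAL)
            nod = _stacks_for(cube, taxon, alg, rep, key, NO_DISPERSAL)
            if lim is None:
                continue
            cur_l, fut_l = lim
            rich_c = pixel_richness(cur_l)
            rich_f = pixel_richness(fut_l)
            d_alpha = pixel_delta_alpha(rich_c, rich_f)
            lost = ((cur_l == 1) & ~(fut_l == 1)).sum(axis=0).astype(float)
            gained = (~(cur_l == 1) & (fut_l == 1)).sum(axis=0).astype(float)
            b_t = pixel_beta_t(lost, gained, rich_c)
            p_loss = pixel_percent_loss(*nod) if nod is not None else np.full(rich_c.shape, np.nan)
            defined = ~(np.isnan(d_alpha) & np.isnan(b_t) & np.isnan(p_loss))
            rr, cc = np.nonzero(defined)
            for r, c in zip(rr.tolist(), cc.tolist()):
                rows.append({
                    "row": r, "col": c, "taxon": taxon,
                    "algorithm": alg, "repetition": rep,
                    "gcm": gcm, "rcp": rcp, "period": period,
                    "delta_alpha": d_alpha[r, c],
                    "percent_loss": p_loss[r, c],
                    "beta_t": b_t[r, c],
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- region level

def region_delta_beta_s(
    current_stack: np.ndarray,
    future_stack: np.ndarray,
    regions: RegionMap,
    semantics: str = "whittaker",
) -> pd.DataFrame:
    """Change in spatial turnover per sub-region.

    Default ("whittaker"): beta = gamma / mean(alpha) per region and period,
    delta-beta-s = 100 * (beta_future - beta_current) / beta_current.
    Literal alternative ("literal"): 100 * (gamma_f - gamma_c) / gamma_c,
    divided by the current mean alpha.  Regions with zero current gamma or
    zero mean alpha are flagged undefined (NaN).
    """
    if semantics not in ("whittaker", "literal"):
        raise MetricError(f"unknown semantics {semantics!r}")
    if current_stack.shape != future_stack.shape:
        raise MetricError("stacks must be paired")
    if current_stack.shape[1:] != regions.grid.shape:
        raise MetricError("regions must cover the stacks' grid")
    rows = []
    for rid in regions.region_ids:
        sel = regions.labels == rid
        cur = current_stack[:, sel]
        fut = future_stack[:, sel]
        gamma_c = float(np.any(cur == 1, axis=1).sum())
        gamma_f = float(np.any(fut == 1, axis=1).sum())
        alpha_c = float(np.nansum(cur == 1, axis=0).mean())
        alpha_f = float(np.nansum(fut == 1, axis=0).mean())
        if gamma_c == 0 or alpha_c == 0:
            value = float("nan")
        elif semantics == "whittaker":
            beta_c = gamma_c / alpha_c
            beta_f = gamma_f / alpha_f if alpha_f > 0 else float("nan")
            value = 100.0 * (beta_f - beta_c) / beta_c
        else:
            value = (100.0 * (gamma_f - gamma_c) / gamma_c) / alpha_c
        rows.append({"region_id": rid, "delta_beta_s": value,
                     "gamma_current": gamma_c, "gamma_future": gamma_f,
                     "mean_alpha_current": alpha_c, "mean_alpha_future": alpha_f})
    return pd.DataFrame(rows)


def region_sensitivity_table(cube: ProjectionCube, regions: RegionMap,
                             semantics: str = "whittaker") -> pd.DataFrame:
    """Delta-beta-s per (region, taxon, design cell, dispersal assumption)."""
    taxa = sorted({p.species.taxon for p in cube.species.values()})
    design_cells = sorted({k for p in cube.species.values() for k in p.future})
    rows = []
    for taxon in taxa:
        for (alg, rep, gcm, rcp, period) in design_cells:
            key = (gcm, rcp, period)
            for assumption in (NO_DISPERSAL, LIMITED_DISPERSAL):
                stacks = _stacks_for(cube, taxon, alg, rep, key, assumption)
                if stacks is None:
                    continue
                tab = region_delta_beta_s(stacks[0], stacks[1], regions, semantics)
                for rec in tab.to_dict("records"):
                    rows.append({
                        "region_id": rec["region_id"], "taxon": taxon,
                        "algorithm": alg, "repetition": rep,
                        "gcm": gcm, "rcp": rcp, "period": period,
                        "assumption": assumption,
                        "delta_beta_s": rec["delta_beta_s"],
                    })
    return pd.DataFrame(rows)


# ------------------------------------------------------------- range-size bins

@dataclass
class RangeSizeBins:
    """Equal-width bins on log10(range size), right-closed."""

    edges: np.ndarray                 # strictly increasing, log10 scale
    labels: pd.Series                 # bin index (0-based) per species_id

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


def bin_by_range_size(range_sizes: pd.Series, n_bins: int) -> RangeSizeBins:
    """Classify species into ``n_bins`` equal-width bins on the log10 scale.

    ``range_sizes`` is indexed by species_id.  Bins span [min, max] of the
    observed log sizes and are right-closed with the lowest edge included, so
    every species is assigned.  A single distinct size collapses to one bin
    with a warning.
    """
    import warnings as _warnings

    if (range_sizes <= 0).any():
        raise MetricError("range sizes must be positive")
    if n_bins < 1:
        raise MetricError("n_bins must be >= 1")
    logs = np.log10(range_sizes.astype(float))
    lo, hi = float(logs.min()), float(logs.max())
    if lo == hi:
        _warnings.warn("all species share one range size; single bin", stacklevel=2)
        edges = np.array([lo - 0.5, hi + 0.5])
        labels = pd.Series(0, index=range_sizes.index)
        return RangeSizeBins(edges, labels)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.searchsorted(edges, logs, side="left") - 1
    labels = pd.Series(np.clip(idx, 0, n_bins - 1), index=range_sizes.index)
    return RangeSizeBins(edges, labels)
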