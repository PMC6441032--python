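"""Nested ANOVA deviance partitioning of projection uncertainty.

Each sensitivity metric yields a long table with one response value per design
cell (SDM algorithm x GCM x RCP, with cross-validation repetitions as
replicates).  The engine attributes the response's deviance — operationalized
as Gaussian deviance, i.e. sums of squares — to the three choices via
sequential (order-dependent, type-I) model comparisons:

nested scheme (SDM/GCM:RCP):
    (1) SDM main effect; (2) GCM within SDM; (3) RCP within SDM.
full-factorial scheme:
    (1) SDM; (2) GCM; (3) RCP as crossed main effects.

Each term's deviance is the drop in residual sum of squares when the term is
added; the remainder is residual.  Interactions are pooled into the residual
by default (``include_interaction`` exposes the within-SDM GCM:RCP term).
Fits are plain least squares on the observed rows, so the unbalanced
14-of-20 GCM x RCP design and dropped models are handled without imputation.

Relative influence is reported both as share of explained deviance (the
convention used for headline figures) and as share of total deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orth

COMPONENTS = ("SDM", "GCM", "RCP")
FACTORS = {"SDM": "algorithm", "GCM": "gcm", "RCP": "rcp"}

#: conservation identity tolerance (relative)
CONSERVATION_RTOL = 1e-8


class PartitionError(ValueError):
    pass


@dataclass
class DeviancePartition:
    """Absolute and relative deviance attributed to SDM, GCM, RCP + residual."""

    ss: dict[str, float]          # per component + "residual"
    total: float
    n: int
    scheme: str
    interaction_ss: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def explained(self) -> float:
        return sum(self.ss[c] for c in COMPONENTS) + (self.interaction_ss or 0.0)

    def share_of_explained(self) -> dict[str, float]:
        ex = self.explained
        if ex <= 0:
            return {c: float("nan") for c in COMPONENTS}
        return {c: 100.0 * self.ss[c] / ex for c in COMPONENTS}

    def share_of_total(self) -> dict[str, float]:
        if self.total <= 0:
            return {c: float("nan") for c in COMPONENTS}
        return {c: 100.0 * self.ss[c] / self.total for c in COMPONENTS}

    @property
    def degenerate(self) -> bool:
        return self.total <= 0

    def to_frame(self) -> pd.DataFrame:
        soe, sot = self.share_of_explained(), self.share_of_total()
        rows = [
            {"component": c, "deviance": self.ss[c],
             "share_of_explained": soe[c], "share_of_total": sot[c]}
            for c in COMPONENTS
        ]
        rows.append({"component": "residual", "deviance": self.ss["residual"],
                     "share_of_explained": float("nan"),
                     "share_of_total": 100.0 * self.ss["residual"] / self.total
                     if self.total > 0 else float("nan")})
        out = pd.DataFrame(rows)
        out["total_deviance"] = self.total
        out["n"] = self.n
        out["scheme"] = self.scheme
        return out


def _onehot(codes: np.ndarray, k: int) -> np.ndarray:
    return (codes[:, None] == np.arange(k)).astype(float)


def _codes(df: pd.DataFrame, cols: list[str]) -> tuple[np.ndarray, int]:
    if len(cols) == 1:
        codes, uniq = pd.factorize(df[cols[0]])
        return codes, len(uniq)
    codes, uniq = pd.factorize(pd.MultiIndex.from_frame(df[cols]))
    return codes, len(uniq)


def _term_matrices(df: pd.DataFrame, scheme: str,
                   include_interaction: bool, block_col: str | None) -> list[np.ndarray]:
    """Cumulative design matrices M1..Mk; each spans its predecessor."""
    n = len(df)
    base_cols = [np.ones((n, 1))]
    if block_col is not None:
        c, k = _codes(df, [block_col])
        base_cols.append(_onehot(c, k))
    sdm, k_sdm = _codes(df, [FACTORS["SDM"]])
    mats = []
    if scheme == "nested":
        gcm_in_sdm, k1 = _codes(df, [FACTORS["SDM"], FACTORS["GCM"]])
        rcp_in_sdm, k2 = _codes(df, [FACTORS["SDM"], FACTORS["RCP"]])
        steps = [[_onehot(sdm, k_sdm)],
                 [_onehot(gcm_in_sdm, k1)],
                 [_onehot(rcp_in_sdm, k2)]]
        if include_interaction:
            cell, k3 = _codes(df, [FACTORS["SDM"], FACTORS["GCM"], FACTORS["RCP"]])
            steps.append([_onehot(cell, k3)])
    else:  # full factorial main effects
        gcm, k_g = _codes(df, [FACTORS["GCM"]])
        rcp, k_r = _codes(df, [FACTORS["RCP"]])
        steps = [[_onehot(sdm, k_sdm)], [_onehot(gcm, k_g)], [_onehot(rcp, k_r)]]
        if include_interaction:
            cell, k3 = _codes(df, [FACTORS["SDM"], FACTORS["GCM"], FACTORS["RCP"]])
            steps.append([_onehot(cell, k3)])
    cum = list(base_cols)
    for step in steps:
        cum = cum + step
        mats.append(np.hstack(cum))
    return mats


def _rss_chain(y: np.ndarray, mats: list[np.ndarray]) -> list[float]:
    """Residual sum of squares of y regressed on each cumulative matrix."""
    yy = float(y @ y)
    out = []
    for X in mats:
        Q = orth(X)
        proj = Q.T @ y
        out.append(max(yy - float(proj @ proj), 0.0))
    return out


def _partition(df: pd.DataFrame, response: str, scheme: str,
               include_interaction: bool = False,
               block_col: str | None = None) -> DeviancePartition:
    work = df.dropna(subset=[response])
    n_dropped = len(df) - len(work)
    if len(work) < 2 or work[response].nunique() < 2:
        ss = {c: 0.0 for c in COMPONENTS}
        ss["residual"] = 0.0
        return DeviancePartition(ss=ss, total=0.0, n=len(work), scheme=scheme,
                                 meta={"dropped_rows": n_dropped, "degenerate": True})
    for comp in COMPONENTS:
        if work[FACTORS[comp]].nunique() < 2:
            warnings.warn(f"factor {comp} has a single level; its component is 0",
                          stacklevel=3)
    y = work[response].to_numpy(dtype=float)
    y = y - y.mean()
    total = float(y @ y)
    mats = _term_matrices(work, scheme, include_interaction, block_col)
    rss = _rss_chain(y, mats)
    prev = total
    deltas = []
    for r in rss:
        deltas.append(max(prev - r, 0.0))
        prev = r
    ss = {"SDM": deltas[0], "GCM": deltas[1], "RCP": deltas[2]}
    interaction = deltas[3] if include_interaction else None
    ss["residual"] = rss[-1]
    return DeviancePartition(ss=ss, total=total, n=len(work), scheme=scheme,
                             interaction_ss=interaction,
                             meta={"dropped_rows": n_dropped, "block": block_col})


def nested_partition(table: pd.DataFrame, response: str = "value",
                     include_interaction: bool = False,
                     block_col: str | None = None) -> DeviancePartition:
    """Sequential sums of squares under the nested scheme SDM / GCM:RCP.

    ``table`` needs columns ``algorithm``, ``gcm``, ``rcp`` and the response;
    NaN responses are dropped (count logged in ``meta``).  A constant response
    yields zero total deviance with all shares undefined.
    """
    return _partition(table, response, "nested", include_interaction, block_col)


def full_factorial_partition(table: pd.DataFrame, response: str = "value",
                             include_interaction: bool = False,
                             block_col: str | None = None) -> DeviancePartition:
    """Sequential sums of squares with SDM + GCM + RCP as crossed main effects."""
    return _partition(table, response, "factorial", include_interaction, block_col)


# ------------------------------------------------------------- grouped sweeps

def partition_per_pixel(pixel_table: pd.DataFrame, response: str,
                        scheme: str = "nested") -> pd.DataFrame:
    """Run the partition per (row, col, taxon, period) pixel cell.

    Returns a tidy frame with one row per pixel and component carrying the
    absolute deviance and both relative shares; pixels whose table is
    degenerate are reported with NaN shares.
    """
    fn = nested_partition if scheme == "nested" else full_factorial_partition
    out = []
    for (r, c, taxon, period), sub in pixel_table.groupby(["row", "col", "taxon", "period"]):
        part = fn(sub, response=response)
        frame = part.to_frame()
        frame["row"], frame["col"], frame["taxon"], frame["period"] = r, c, taxon, period
        out.append(frame)
    if not out:
        raise PartitionError("empty pixel table")
    return pd.concat(out, ignore_index=True)


def share_maps(per_pixel: pd.DataFrame, shape: tuple[int, int],
               taxon: str, period: str) -> dict[str, np.ndarray]:
    """Reshape a per-pixel partition frame into share-of-explained maps."""
    maps = {c: np.full(shape, np.nan) for c in COMPONENTS}
    maps["total"] = np.full(shape, np.nan)
    sel = per_pixel[(per_pixel["taxon"] == taxon) & (per_pixel["period"] == period)]
    for rec in sel.to_dict("records"):
        r, c = int(rec["row"]), int(rec["col"])
        if rec["component"] in maps:
            maps[rec["component"]][r, c] = rec["share_of_explained"]
        maps["total"][r, c] = rec["total_deviance"]
    return maps


def partition_by_range_bin(species_table: pd.DataFrame, bin_labels: pd.Series,
                           response: str, scheme: str = "nested") -> pd.DataFrame:
    """Partition each range-size bin's pooled species table separately."""
    fn = nested_partition if scheme == "nested" else full_factorial_partition
    tab = species_table.merge(bin_labels.rename("bin"), left_on="species_id",
                              right_index=True, how="left")
    out = []
    for b, sub in tab.groupby("bin"):
        if sub.empty:
            warnings.warn(f"range-size bin {b} is empty; skipped", stacklevel=2)
            continue
        frame = fn(sub, response=response).to_frame()
        frame["bin"] = b
        frame["n_species"] = sub["species_id"].nunique()
        out.append(frame)
    return pd.concat(out, ignore_index=True)


def threshold_sensitivity(species_table: pd.DataFrame, thresholds: tuple[float, ...],
                          response: str, scheme: str = "nested") -> pd.DataFrame:
    """Partition the same metric under several TSS retention thresholds.

    ``species_table`` must carry each record's model TSS (column ``tss``); for
    each threshold, records from models below it are dropped and the partition
    re-run, so the three columns are comparable side by side.
    """
    fn = nested_partition if scheme == "nested" else full_factorial_partition
    out = []
    for thr in thresholds:
        sub = species_table[species_table["tss"] >= thr]
        if sub.empty:
            warnings.warn(f"TSS threshold {thr} retains zero models; column empty",
                          stacklevel=2)
            continue
        frame = fn(sub, response=response).to_frame()
        frame["tss_threshold"] = thr
        frame["n_rows"] = len(sub)
        out.append(frame)
    if not out:
        raise PartitionError("no threshold retained any model")
    return pd.concat(out, ignore_index=True)
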