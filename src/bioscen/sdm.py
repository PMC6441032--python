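"""SDM ensemble: training sets, four algorithm families, TSS scoring, projection.

For each species, presences are all range cells and pseudo-absences are drawn
inside a taxon-specific geographic buffer around the range (sampling absences
from the whole globe inflates apparent accuracy).  Each of the four algorithm
families (GLM, GAM, BRT, RF) is fitted on a random 70% of the observations and
scored on the held-out 30% with the true skill statistic,
``TSS = sensitivity + specificity - 1``; the split is re-drawn for each of the
four cross-validation repetitions.  Continuous outputs are binarized at the
TSS-maximizing cutoff on the evaluation split, and models below a TSS
retention threshold are excluded from projection ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler

from .dispersal import limited_dispersal_mask
from .world import (
    VARIABLES,
    ClimateCube,
    ClimateLayers,
    Grid,
    VirtualSpecies,
)

ALGORITHMS = ("GLM", "GAM", "BRT", "RF")
N_REPETITIONS = 4
SPLIT_FRACTION = 0.7
TSS_THRESHOLDS = (0.4, 0.6, 0.7)


class SDMError(ValueError):
    pass


class SingleClassSplitError(SDMError):
    """A random 70/30 split left one side with a single class; re-split with a
    different repetition seed."""


@dataclass
class TrainingTable:
    """Presence/absence rows with their climate covariates for one species."""

    species_id: str
    buffer_km: float
    cells: np.ndarray        # flat cell indices, presences first
    X: np.ndarray            # (n, 4) climate covariates, VARIABLES order
    y: np.ndarray            # 1 presence / 0 absence
    grid: Grid

    @property
    def n_presence(self) -> int:
        return int(self.y.sum())


def build_training_set(
    species: VirtualSpecies,
    climate: ClimateLayers,
    buffer_km: float,
    n_absences: int | None = None,
    seed: int = 0,
) -> TrainingTable:
    """All range cells as presences; absences sampled uniformly without
    replacement from the buffer ring around the range.

    ``n_absences`` defaults to ``min(10 * presences, all buffer cells)``.  If
    the buffer holds fewer candidates than requested, all candidates are used
    with a warning; an empty buffer (species occupying the whole grid) is an
    error.
    """
    if buffer_km <= 0:
        raise SDMError("buffer_km must be > 0")
    grid = climate.grid
    rng_mask = species.range_mask
    buffer = limited_dispersal_mask(rng_mask, grid, buffer_km, species.species_id).mask
    candidates = np.flatnonzero(buffer.ravel() & ~rng_mask.ravel())
    if candidates.size == 0:
        raise SDMError(f"{species.species_id}: no absence candidates within {buffer_km} km buffer")
    n_pres = int(rng_mask.sum())
    if n_absences is None:
        n_absences = min(10 * n_pres, candidates.size)
    if candidates.size < n_absences:
        warnings.warn(
            f"{species.species_id}: only {candidates.size} buffer cells for "
            f"{n_absences} requested absences; using all",
            stacklevel=2,
        )
        n_absences = candidates.size
    rng = default_rng(SeedSequence([int(seed), 0xAB5]))
    absences = np.sort(rng.choice(candidates, size=n_absences, replace=False))
    presences = np.flatnonzero(rng_mask.ravel())
    cells = np.concatenate([presences, absences])
    flat = climate.as_matrix()
    y = np.concatenate([np.ones(presences.size, dtype=int), np.zeros(n_absences, dtype=int)])
    return TrainingTable(species.species_id, float(buffer_km), cells, flat[cells], y, grid)


def evaluate_tss(predicted: np.ndarray, observed: np.ndarray) -> float:
    """True skill statistic, sensitivity + specificity - 1, in [-1, 1]."""
    predicted = np.asarray(predicted)
    observed = np.asarray(observed)
    if predicted.shape != observed.shape:
        raise SDMError("predicted and observed must have equal length")
    pos = observed == 1
    neg = observed == 0
    if not pos.any():
        raise SDMError("observed contains no presences; sensitivity undefined")
    if not neg.any():
        raise SDMError("observed contains no absences; specificity undefined")
    sensitivity = float((predicted[pos] == 1).mean())
    specificity = float((predicted[neg] == 0).mean())
    return sensitivity + specificity - 1.0


def select_cutoff(scores: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    """TSS-maximizing binarization cutoff on an evaluation split.

    Candidates are the unique scores and the midpoints between consecutive
    unique scores; the prediction rule is ``score >= cutoff``.  Ties are broken
    towards the smallest optimal cutoff.  Returns ``(cutoff, tss)``.
    """
    scores = np.asarray(scores, dtype=float)
    observed = np.asarray(observed)
    uniq = np.unique(scores)
    if uniq.size == 1:
        warnings.warn("degenerate constant scores; returning cutoff 0.5", stacklevel=2)
        return 0.5, evaluate_tss((scores >= 0.5).astype(int), observed)
    mid = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.sort(np.unique(np.concatenate([uniq, mid])))
    best_cut, best_tss = candidates[0], -np.inf
    for c in candidates:
        tss = evaluate_tss((scores >= c).astype(int), observed)
        if tss > best_tss + 1e-12:
            best_cut, best_tss = float(c), tss
    if best_tss <= 0:
        warnings.warn(f"optimal TSS {best_tss:.3f} <= 0: anti-learned or skill-free model",
                      stacklevel=2)
    return best_cut, float(best_tss)


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "GLM":
        # logistic regression with linear + quadratic terms
        return Pipeline([
            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=2000)),
        ])
    if algorithm == "GAM":
        # additive cubic-spline basis per covariate + logistic link
        return Pipeline([
            ("scale", StandardScaler()),
            ("spline", SplineTransformer(n_knots=5, degree=3)),
            ("clf", LogisticRegression(max_iter=2000)),
        ])
    if algorithm == "BRT":
        return GradientBoostingClassifier(
            n_estimators=150, learning_rate=0.05, max_depth=3, subsample=0.8,
            random_state=seed,
        )
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=200, min_samples_leaf=2, random_state=seed, n_jobs=1
        )
    raise SDMError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


@dataclass
class FittedSDM:
    species_id: str
    algorithm: str
    repetition: int
    estimator: object
    tss_score: float
    cutoff: float
    converged: bool = True

    def predict_continuous(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(X)[:, 1]


def fit_sdm(
    training: TrainingTable,
    algorithm: str,
    split_fraction: float = SPLIT_FRACTION,
    repetition_seed: int = 0,
) -> FittedSDM:
    """Fit one algorithm on a random 70% split and score it on the 30% hold-out.

    The TSS-maximizing cutoff on the hold-out is stored for binarization.
    Deterministic given ``repetition_seed``.
    """
    if algorithm not in ALGORITHMS:
        raise SDMError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    n = training.y.size
    rng = default_rng(SeedSequence([int(repetition_seed), 0xF17]))
    order = rng.permutation(n)
    n_train = int(round(split_fraction * n))
    train_idx, test_idx = order[:n_train], order[n_train:]
    y_train, y_test = training.y[train_idx], training.y[test_idx]
    for part, name in ((y_train, "70% calibration"), (y_test, "30% evaluation")):
        if len(np.unique(part)) < 2:
            raise SingleClassSplitError(
                f"{training.species_id}/{algorithm}: {name} split holds a single class;"
                " re-split with a different repetition_seed"
            )
    est = _make_estimator(algorithm, seed=int(repetition_seed) % (2**31))
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(training.X[train_idx], y_train)
        scores = est.predict_proba(training.X[test_idx])[:, 1]
        cutoff, tss = select_cutoff(scores, y_test)
    except Exception:  # non-convergent / degenerate fit: flag, exclude downstream
        converged = False
        cutoff, tss = 0.5, -1.0
    return FittedSDM(training.species_id, algorithm, int(repetition_seed), est,
                     float(tss), float(cutoff), converged)


def project(model: FittedSDM, layers: ClimateLayers, domain: np.ndarray) -> np.ndarray:
    """Binary suitability map: prediction binarized at the stored cutoff inside
    ``domain``, NaN outside."""
    if domain.shape != layers.grid.shape:
        raise SDMError(f"domain shape {domain.shape} != grid {layers.grid.shape}")
    out = np.full(layers.grid.shape, np.nan)
    idx = np.flatnonzero(domain.ravel())
    if idx.size == 0:
        return out
    X = layers.as_matrix()[idx]
    p = model.predict_continuous(X)
    out.ravel()[idx] = (p >= model.cutoff).astype(float)
    return out


@dataclass(frozen=True)
class TSSThresholdPolicy:
    """Models with hold-out TSS below ``threshold`` are dropped from ensembles."""

    threshold: float = 0.7

    def __post_init__(self) -> None:
        if not (-1.0 <= self.threshold <= 1.01):
            raise SDMError("TSS threshold must lie within [-1, 1] (1.01 allowed for vacuous tests)")

    def retains(self, model: FittedSDM) -> bool:
        return model.converged and model.tss_score >= self.threshold


@dataclass
class SpeciesProjections:
    """All projections for one species' retained models."""

    species: VirtualSpecies
    models: list[FittedSDM]                      # retained models only
    current: dict[tuple[str, int], np.ndarray]   # (algorithm, rep) -> binary map
    future: dict[tuple[str, int, str, str, str], np.ndarray]  # (+ gcm, rcp, period)
    domain: np.ndarray                           # limited-dispersal mask used

    @property
    def n_future(self) -> int:
        return len(self.future)


@dataclass
class ProjectionCube:
    """Binary suitability maps for every retained (species, algorithm, rep,
    scenario) cell of the design, plus the model registry with TSS scores."""

    grid: Grid
    species: dict[str, SpeciesProjections]
    registry: pd.DataFrame  # one row per fitted model (retained or not)
    excluded_species: list[str] = field(default_factory=list)

    def future_count(self, species_id: str) -> int:
        return self.species[species_id].n_future


def fit_species_models(
    species: VirtualSpecies,
    climate: ClimateLayers,
    buffer_km: float,
    n_repetitions: int = N_REPETITIONS,
    algorithms: tuple[str, ...] = ALGORITHMS,
    seed: int = 0,
    n_absences: int | None = None,
) -> tuple[TrainingTable, list[FittedSDM]]:
    """One absence sample per species, one 70/30 re-split per repetition."""
    training = build_training_set(species, climate, buffer_km, n_absences=n_absences, seed=seed)
    models = []
    for rep in range(1, n_repetitions + 1):
        rep_seed = int(SeedSequence([int(seed), rep]).generate_state(1)[0] % (2**31))
        for alg in algorithms:
            try:
                m = fit_sdm(training, alg, repetition_seed=rep_seed)
            except SingleClassSplitError:
                # retry once with a perturbed seed, else flag as non-converged
                try:
                    m = fit_sdm(training, alg, repetition_seed=rep_seed + 1)
                except SingleClassSplitError:
                    m = FittedSDM(species.species_id, alg, rep_seed, None, -1.0, 0.5, False)
            m.repetition = rep
            models.append(m)
    return training, models


def run_ensemble(
    species_list: list[VirtualSpecies],
    cube: ClimateCube,
    policy: TSSThresholdPolicy,
    buffer_km_by_taxon: dict[str, float],
    n_repetitions: int = N_REPETITIONS,
    algorithms: tuple[str, ...] = ALGORITHMS,
    seed: int = 0,
    n_absences: int | None = None,
) -> ProjectionCube:
    """Fit, filter and project the full ensemble.

    Per species: fit ``algorithms x n_repetitions`` models, drop those below
    the TSS policy, and project every retained model onto the current layers
    and every (gcm, rcp, period) scenario within the species'
    limited-dispersal domain.  Species with zero retained models are logged
    and excluded.
    """
    grid = cube.grid
    registry_rows = []
    projections: dict[str, SpeciesProjections] = {}
    excluded: list[str] = []
    for si, sp in enumerate(species_list):
        buffer_km = buffer_km_by_taxon[sp.taxon]
        sp_seed = int(SeedSequence([int(seed), 0xE5E, si]).generate_state(1)[0] % (2**31))
        _, models = fit_species_models(
            sp, cube.current, buffer_km, n_repetitions, algorithms, sp_seed, n_absences
        )
        retained = [m for m in models if policy.retains(m)]
        for m in models:
            registry_rows.append({
                "species_id": sp.species_id, "taxon": sp.taxon,
                "algorithm": m.algorithm, "repetition": m.repetition,
                "tss": m.tss_score, "cutoff": m.cutoff,
                "converged": m.converged, "retained": policy.retains(m),
            })
        if not retained:
            warnings.warn(f"{sp.species_id}: zero models at TSS >= {policy.threshold};"
                          " species excluded", stacklevel=2)
            excluded.append(sp.species_id)
            continue
        domain = limited_dispersal_mask(sp.range_mask, grid, buffer_km, sp.species_id).mask
        current = {}
        future = {}
        for m in retained:
            current[(m.algorithm, m.repetition)] = project(m, cube.current, domain)
            for key, layers in cube.future.items():
                future[(m.algorithm, m.repetition) + key] = project(m, layers, domain)
        projections[sp.species_id] = SpeciesProjections(sp, retained, current, future, domain)
    registry = pd.DataFrame(registry_rows)
    return ProjectionCube(grid=grid, species=projections, registry=registry,
                          excluded_species=excluded)
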