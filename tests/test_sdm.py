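"""SDM ensemble: TSS arithmetic and oracle, cutoff selection, buffered absence
sampling, split-sample fitting, projection accuracy and retention rules."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioscen.dispersal import DEFAULT_BUFFER_KM
from bioscen.sdm import (
    ALGORITHMS,
    SDMError,
    SingleClassSplitError,
    TSSThresholdPolicy,
    build_training_set,
    evaluate_tss,
    fit_sdm,
    fit_species_models,
    project,
    run_ensemble,
    select_cutoff,
)
from bioscen.world import (
    Grid,
    ScenarioDesign,
    ScenarioEffectConfig,
    VirtualSpecies,
    simulate_current_climate,
    simulate_scenario_climate,
    simulate_species,
)


# ------------------------------------------------------------------- TSS

def test_tss_hand_values():
    # perfect skill
    assert evaluate_tss(np.r_[np.ones(10), np.zeros(10)],
                        np.r_[np.ones(10), np.zeros(10)]) == pytest.approx(1.0)
    # all-presence prediction on a half/half sample: sens 1, spec 0
    assert evaluate_tss(np.ones(10), np.r_[np.ones(5), np.zeros(5)]) == pytest.approx(0.0)
    # TP=8 FN=2 TN=6 FP=4 -> 0.8 + 0.6 - 1 = 0.4
    obs = np.r_[np.ones(10), np.zeros(10)]
    pred = np.r_[np.ones(8), np.zeros(2), np.ones(4), np.zeros(6)]
    assert evaluate_tss(pred, obs) == pytest.approx(0.4)


def test_tss_single_class_errors():
    with pytest.raises(SDMError, match="absence"):
        evaluate_tss(np.ones(4), np.ones(4))
    with pytest.raises(SDMError, match="presence"):
        evaluate_tss(np.zeros(4), np.zeros(4))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_tss_matches_confusion_matrix_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 60))
    obs = rng.integers(0, 2, n)
    if obs.min() == obs.max():
        obs[0] = 1 - obs[0]
    pred = rng.integers(0, 2, n)
    tp = np.sum((pred == 1) & (obs == 1))
    fn = np.sum((pred == 0) & (obs == 1))
    tn = np.sum((pred == 0) & (obs == 0))
    fp = np.sum((pred == 1) & (obs == 0))
    oracle = tp / (tp + fn) + tn / (tn + fp) - 1.0
    assert evaluate_tss(pred, obs) == pytest.approx(oracle)


# ---------------------------------------------------------------- cutoff

def test_cutoff_brute_force_separable():
    scores = np.array([0.1, 0.4, 0.6, 0.9])
    labels = np.array([0, 0, 1, 1])
    cut, tss = select_cutoff(scores, labels)
    assert 0.4 < cut <= 0.6
    assert tss == pytest.approx(1.0)
    # brute force over a fine grid confirms no better cutoff exists
    best = max(evaluate_tss((scores >= c).astype(int), labels)
               for c in np.linspace(0, 1, 1001))
    assert best == pytest.approx(tss)


def test_cutoff_scores_equal_labels_returns_smallest_optimal():
    cut, tss = select_cutoff(np.array([0.0, 1.0, 0.0, 1.0]),
                             np.array([0, 1, 0, 1]))
    assert tss == pytest.approx(1.0)
    assert cut == pytest.approx(0.5)  # smallest evaluated candidate in (0,1)


def test_cutoff_degenerate_and_reversed_warn():
    with pytest.warns(UserWarning, match="degenerate"):
        cut, _ = select_cutoff(np.full(6, 0.3), np.array([0, 1, 0, 1, 0, 1]))
    assert cut == 0.5
    with pytest.warns(UserWarning, match="anti-learned|skill-free"):
        _, tss = select_cutoff(np.array([0.9, 0.6, 0.4, 0.1]),
                               np.array([0, 0, 1, 1]))
    assert tss <= 0


# --------------------------------------------------------- training tables

def _block_species(grid, r0, r1, c0, c1, taxon="mammal"):
    mask = np.zeros(grid.shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    opt = {v: 0.0 for v in ("mean_temp", "temp_range", "precip_sum", "precip_cv")}
    brd = {v: 1.0 for v in opt}
    return VirtualSpecies("spX", taxon, opt, brd, 0.1, mask)


def test_absences_confined_to_buffer_ring():
    grid = Grid(40, 40, cell_size_km=100.0)
    climate = simulate_current_climate(grid, seed=0)
    sp = _block_species(grid, 15, 25, 15, 25)
    table = build_training_set(sp, climate, buffer_km=500.0, n_absences=100, seed=1)
    assert table.n_presence == 100
    centers = grid.cell_centers_km()
    src = centers[sp.range_mask.ravel()]
    for cell in table.cells[table.y == 0]:
        assert not sp.range_mask.ravel()[cell]
        d = np.sqrt(((src - centers[cell]) ** 2).sum(axis=1)).min()
        assert d <= 500.0 + 1e-6


def test_whole_grid_species_has_no_absence_candidates():
    grid = Grid(8, 8)
    climate = simulate_current_climate(grid, seed=0)
    sp = _block_species(grid, 0, 8, 0, 8)
    with pytest.raises(SDMError, match="no absence candidates"):
        build_training_set(sp, climate, buffer_km=300.0, seed=0)


def test_small_buffer_warns_and_returns_all_candidates():
    grid = Grid(20, 20)
    climate = simulate_current_climate(grid, seed=0)
    sp = _block_species(grid, 8, 13, 8, 13)  # 5x5 block, 25 cells
    with pytest.warns(UserWarning, match="buffer cells"):
        table = build_training_set(sp, climate, buffer_km=100.0,
                                   n_absences=500, seed=0)
    # one-cell buffer: only the edge-adjacent ring (diagonal neighbours are at
    # 100*sqrt(2) > 100 km, so the four-neighbour ring only)
    assert set(table.cells[table.y == 0]) <= set(
        np.flatnonzero(~sp.range_mask.ravel()))
    assert (table.y == 0).sum() == 20  # 4 sides x 5 cells, no diagonals


# ------------------------------------------------------------------ fitting

def _axis_separable_climate(grid):
    """mean_temp varies along rows only, so any row band is exactly separable
    by a single axis-aligned threshold (trees and splines alike)."""
    from bioscen.world import ClimateLayers

    rows = np.linspace(-12.0, 27.0, grid.n_rows)[:, None] * np.ones((1, grid.n_cols))
    cols = np.linspace(100.0, 2000.0, grid.n_cols)[None, :] * np.ones((grid.n_rows, 1))
    return ClimateLayers(grid, {
        "mean_temp": rows,
        "temp_range": np.full(grid.shape, 20.0),
        "precip_sum": cols,
        "precip_cv": np.full(grid.shape, 50.0),
    })


@pytest.fixture(scope="module")
def separable_training():
    """Disjoint climate supports: presences cold, absences warm."""
    grid = Grid(30, 30)
    climate = _axis_separable_climate(grid)
    sp = _block_species(grid, 0, 6, 0, 30)  # one climatic extreme
    return build_training_set(sp, climate, buffer_km=3000.0, seed=3)


@pytest.mark.parametrize("algorithm", ALGORITHMS)
def test_separable_species_reach_perfect_tss(separable_training, algorithm):
    m = fit_sdm(separable_training, algorithm, repetition_seed=1)
    assert m.tss_score == pytest.approx(1.0)


def test_fit_deterministic_under_seed(separable_training):
    a = fit_sdm(separable_training, "BRT", repetition_seed=7)
    b = fit_sdm(separable_training, "BRT", repetition_seed=7)
    assert a.tss_score == b.tss_score and a.cutoff == b.cutoff


def test_permuted_labels_give_no_skill():
    """Permutation null: mean hold-out TSS across 20 re-labelings ~ 0.

    The cutoff search maximizes TSS on the hold-out, which biases single-run
    scores slightly upward, so the null needs a reasonably large evaluation
    split for the mean to settle near zero."""
    grid = Grid(40, 40)
    climate = _axis_separable_climate(grid)
    sp = _block_species(grid, 0, 10, 0, 40)
    base = build_training_set(sp, climate, buffer_km=4000.0, seed=0)
    rng = np.random.default_rng(0)
    scores = []
    for seed in range(20):
        shuffled = base.__class__(
            species_id="null", buffer_km=base.buffer_km, cells=base.cells,
            X=base.X, y=rng.permutation(base.y), grid=base.grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores.append(fit_sdm(shuffled, "GLM", repetition_seed=seed).tss_score)
    assert abs(np.mean(scores)) < 0.1


def test_single_class_split_refused(separable_training):
    t = separable_training
    few = t.__class__(species_id="few", buffer_km=t.buffer_km,
                      cells=t.cells[178:], X=t.X[178:], y=t.y[178:], grid=t.grid)
    # only 2 presences among many absences: most splits strand them together
    with pytest.raises(SingleClassSplitError):
        for seed in range(50):
            fit_sdm(few, "GLM", repetition_seed=seed)


# --------------------------------------------------------------- projection

@pytest.fixture(scope="module")
def small_world():
    grid = Grid(20, 20)
    climate = simulate_current_climate(grid, seed=8)
    species = simulate_species(climate, n_species=4,
                               prevalence_range=(0.1, 0.25), seed=8)
    return grid, climate, species


def test_projection_recovers_true_range(small_world):
    grid, climate, species = small_world
    sp = species[0]
    _, models = fit_species_models(sp, climate, buffer_km=2000.0, seed=1)
    best = max(models, key=lambda m: m.tss_score)
    domain = np.ones(grid.shape, dtype=bool)
    pred = project(best, climate, domain)
    truth = sp.range_mask.ravel().astype(int)
    tss_vs_truth = evaluate_tss(pred.ravel().astype(int), truth)
    assert tss_vs_truth >= 0.9


def test_projection_domain_masking(small_world):
    grid, climate, species = small_world
    _, models = fit_species_models(species[0], climate, buffer_km=2000.0, seed=1)
    m = models[0]
    empty = project(m, climate, np.zeros(grid.shape, dtype=bool))
    assert np.isnan(empty).all()
    single = np.zeros(grid.shape, dtype=bool)
    single[4, 4] = True
    one = project(m, climate, single)
    assert np.isnan(one).sum() == grid.n_cells - 1
    assert one[4, 4] in (0.0, 1.0)
    with pytest.raises(SDMError):
        project(m, climate, np.ones((3, 3), dtype=bool))


# ----------------------------------------------------------------- ensemble

def test_run_ensemble_counts_and_retention(small_world):
    grid, climate, species = small_world
    design = ScenarioDesign(gcm_ids=("A", "B"), rcp_ids=("RCP2.6", "RCP8.5"),
                            combos=(("A", "RCP2.6"), ("A", "RCP8.5"),
                                    ("B", "RCP8.5")),
                            periods=("2041-2060",))
    effects = ScenarioEffectConfig()
    cube = simulate_scenario_climate(climate, design, effects, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = run_ensemble(species[:2], cube, TSSThresholdPolicy(-1.0),
                           DEFAULT_BUFFER_KM, seed=4)
    # no model can fall below TSS >= -1: full design count per species
    for sid, proj in out.species.items():
        assert proj.n_future == 4 * 4 * len(design.combos) * 1

    registry = out.registry
    kept = {thr: set(map(tuple, registry[registry["tss"] >= thr]
                         [["species_id", "algorithm", "repetition"]].to_numpy()))
            for thr in (0.4, 0.7)}
    assert kept[0.7] <= kept[0.4]  # retention monotonicity

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vacuous = run_ensemble(species[:1], cube, TSSThresholdPolicy(1.01),
                               DEFAULT_BUFFER_KM, seed=4)
    assert vacuous.species == {}
    assert vacuous.excluded_species == [species[0].species_id]
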