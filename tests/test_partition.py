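"""Deviance partition engine: conservation, oracle equivalence against both a
group-means decomposition and statsmodels' sequential ANOVA, null calibration,
variance recovery, and the grouped sweeps (pixels, bins, thresholds)."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.anova import anova_lm

from bioscen.experiments import make_effect_table, null_calibration, variance_recovery
from bioscen.partition import (
    CONSERVATION_RTOL,
    full_factorial_partition,
    nested_partition,
    partition_by_range_bin,
    partition_per_pixel,
    share_maps,
    threshold_sensitivity,
)


def _random_table(seed, n_sdm=3, n_gcm=3, n_rcp=2, n_reps=2, combos=None):
    return make_effect_table(n_sdm=n_sdm, n_gcm=n_gcm, n_rcp=n_rcp,
                             n_reps=n_reps, noise_sd=1.0, seed=seed,
                             combos=combos)


# ------------------------------------------------------------ core identities

def test_pure_sdm_signal_attributed_entirely_to_sdm():
    rows = [{"algorithm": f"S{i}", "gcm": f"G{j}", "rcp": f"R{k}",
             "repetition": r, "value": float(i)}
            for i in range(4) for j in range(3) for k in range(2) for r in range(2)]
    part = nested_partition(pd.DataFrame(rows))
    soe = part.share_of_explained()
    assert soe["SDM"] == pytest.approx(100.0)
    assert soe["GCM"] == pytest.approx(0.0, abs=1e-9)
    assert soe["RCP"] == pytest.approx(0.0, abs=1e-9)
    ff = full_factorial_partition(pd.DataFrame(rows))
    assert ff.share_of_explained()["SDM"] == pytest.approx(100.0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_conservation_on_random_tables(seed):
    """Component SS + residual SS = total SS for both engines."""
    tab = _random_table(seed)
    for engine in (nested_partition, full_factorial_partition):
        part = engine(tab)
        recon = sum(part.ss[c] for c in ("SDM", "GCM", "RCP")) + part.ss["residual"]
        assert recon == pytest.approx(part.total, rel=CONSERVATION_RTOL)
        soe = part.share_of_explained()
        assert sum(soe.values()) == pytest.approx(100.0, abs=1e-6)


@pytest.mark.parametrize("engine", [nested_partition, full_factorial_partition])
def test_group_means_oracle_on_small_tables(engine):
    """Sequential SS match the direct group-means decomposition on balanced
    tables up to 4 x 3 x 2 with 5 replicates."""
    for (n_sdm, n_gcm, n_rcp) in itertools.product((2, 4), (2, 3), (2,)):
        tab = make_effect_table(n_sdm=n_sdm, n_gcm=n_gcm, n_rcp=n_rcp,
                                n_reps=5, noise_sd=1.0, seed=n_sdm * 10 + n_gcm)
        part = engine(tab)
        grand = tab["value"].mean()
        ss_sdm = sum(len(s) * (s["value"].mean() - grand) ** 2
                     for _, s in tab.groupby("algorithm"))
        assert part.ss["SDM"] == pytest.approx(ss_sdm)
        if engine is nested_partition:
            sdm_means = tab.groupby("algorithm")["value"].mean()
            ss_gcm = sum(len(s) * (s["value"].mean() - sdm_means[a]) ** 2
                         for (a, _), s in tab.groupby(["algorithm", "gcm"]))
            ss_rcp = sum(len(s) * (s["value"].mean() - sdm_means[a]) ** 2
                         for (a, _), s in tab.groupby(["algorithm", "rcp"]))
        else:
            ss_gcm = sum(len(s) * (s["value"].mean() - grand) ** 2
                         for _, s in tab.groupby("gcm"))
            ss_rcp = sum(len(s) * (s["value"].mean() - grand) ** 2
                         for _, s in tab.groupby("rcp"))
        assert part.ss["GCM"] == pytest.approx(ss_gcm)
        assert part.ss["RCP"] == pytest.approx(ss_rcp)


@pytest.mark.parametrize("combos", [None, [(g, r) for g in range(5) for r in range(4)][:14]])
def test_statsmodels_sequential_anova_oracle(combos):
    """Both engines reproduce statsmodels' type-I sums of squares, on the
    balanced full factorial and on the unbalanced 14-combo design."""
    tab = _random_table(11, n_sdm=4, n_gcm=5, n_rcp=4, combos=combos)
    nested = nested_partition(tab)
    sm_nested = anova_lm(
        smf.ols("value ~ C(algorithm) + C(algorithm):C(gcm) + C(algorithm):C(rcp)",
                data=tab).fit(), typ=1)["sum_sq"]
    assert nested.ss["SDM"] == pytest.approx(sm_nested["C(algorithm)"])
    assert nested.ss["GCM"] == pytest.approx(sm_nested["C(algorithm):C(gcm)"])
    assert nested.ss["RCP"] == pytest.approx(sm_nested["C(algorithm):C(rcp)"])
    assert nested.ss["residual"] == pytest.approx(sm_nested["Residual"])

    fact = full_factorial_partition(tab)
    sm_fact = anova_lm(
        smf.ols("value ~ C(algorithm) + C(gcm) + C(rcp)", data=tab).fit(),
        typ=1)["sum_sq"]
    assert fact.ss["SDM"] == pytest.approx(sm_fact["C(algorithm)"])
    assert fact.ss["GCM"] == pytest.approx(sm_fact["C(gcm)"])
    assert fact.ss["RCP"] == pytest.approx(sm_fact["C(rcp)"])

    if combos is not None:  # unbalanced: schemes differ but both conserve
        assert not np.isclose(nested.ss["GCM"], fact.ss["GCM"])


def test_balanced_design_order_invariance():
    """On a balanced complete design, sequential main-effect SS are orthogonal:
    refitting with factors relabelled (order permuted) leaves each SS alone."""
    tab = _random_table(21, n_sdm=3, n_gcm=4, n_rcp=2, n_reps=3)
    base = full_factorial_partition(tab)
    swapped = tab.rename(columns={"gcm": "rcp", "rcp": "gcm"})
    alt = full_factorial_partition(swapped)
    assert base.ss["GCM"] == pytest.approx(alt.ss["RCP"])
    assert base.ss["RCP"] == pytest.approx(alt.ss["GCM"])
    assert base.ss["SDM"] == pytest.approx(alt.ss["SDM"])


def test_degenerate_inputs_flagged():
    tab = _random_table(0)
    const = tab.assign(value=1.0)
    part = nested_partition(const)
    assert part.degenerate and part.total == 0.0
    assert all(np.isnan(v) for v in part.share_of_explained().values())
    single = tab[tab["algorithm"] == "S0"]
    with pytest.warns(UserWarning, match="single level"):
        p1 = nested_partition(single)
    assert p1.ss["SDM"] == pytest.approx(0.0, abs=1e-9)


def test_missing_responses_dropped_and_logged():
    tab = _random_table(5)
    tab.loc[tab.index[:7], "value"] = np.nan
    part = nested_partition(tab)
    assert part.meta["dropped_rows"] == 7
    assert part.n == len(tab) - 7


# --------------------------------------------------------------- calibration

def test_null_calibration_matches_df_fractions():
    """Pure-noise tables: each component's mean share of total deviance equals
    its degrees-of-freedom fraction (3/319, 16/319, 12/319 on 4x5x4 x4)."""
    out = null_calibration(n_tables=150, seed=0)
    n_tot = 4 * 5 * 4 * 4 - 1
    assert out["SDM"] == pytest.approx(100 * 3 / n_tot, abs=0.5)
    assert out["GCM"] == pytest.approx(100 * 4 * 4 / n_tot, abs=0.7)
    assert out["RCP"] == pytest.approx(100 * 4 * 3 / n_tot, abs=0.7)


def test_variance_ratio_recovery():
    """Planted 9:4:1 effect variances on balanced 4x5x4 designs recover shares
    9/14, 4/14, 1/14 of explained deviance within 5 points over 30 seeds."""
    out = variance_recovery(n_seeds=30, seed=0)
    assert out["SDM"] == pytest.approx(100 * 9 / 14, abs=5.0)
    assert out["GCM"] == pytest.approx(100 * 4 / 14, abs=5.0)
    assert out["RCP"] == pytest.approx(100 * 1 / 14, abs=5.0)


def test_replicates_are_exchangeable():
    """Adding the cross-validation replicate id as a blocking term explains
    under 1% of total deviance when replicates are exchangeable."""
    tab = _random_table(9, n_sdm=4, n_gcm=5, n_rcp=4, n_reps=4)
    plain = nested_partition(tab)
    blocked = nested_partition(tab, block_col="repetition")
    rep_ss = plain.ss["residual"] - blocked.ss["residual"] \
        + sum(plain.ss[c] - blocked.ss[c] for c in ("SDM", "GCM", "RCP"))
    assert rep_ss / plain.total < 0.01


def test_interaction_term_optional():
    tab = _random_table(13, n_sdm=3, n_gcm=3, n_rcp=2, n_reps=3)
    base = nested_partition(tab)
    with_int = nested_partition(tab, include_interaction=True)
    assert with_int.interaction_ss is not None
    assert with_int.ss["residual"] <= base.ss["residual"] + 1e-9
    recon = (sum(with_int.ss[c] for c in ("SDM", "GCM", "RCP"))
             + with_int.interaction_ss + with_int.ss["residual"])
    assert recon == pytest.approx(with_int.total, rel=CONSERVATION_RTOL)


# ------------------------------------------------------------- grouped sweeps

def _pixel_table(seed, southern_rcp=True, n_rows=6, n_cols=4):
    """Pixel records where the RCP effect acts only on the southern half."""
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_rows):
        south = r >= n_rows // 2
        for c in range(n_cols):
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        for rep in range(2):
                            y = rng.normal(0, 0.3) + 0.5 * i
                            if south and southern_rcp:
                                y += 2.0 * k
                            rows.append({"row": r, "col": c, "taxon": "bird",
                                         "period": "2041-2060",
                                         "algorithm": f"S{i}", "gcm": f"G{j}",
                                         "rcp": f"R{k}", "repetition": rep,
                                         "delta_alpha": y})
    return pd.DataFrame(rows)


def test_per_pixel_partition_localizes_rcp_effect():
    tab = _pixel_table(0)
    out = partition_per_pixel(tab, response="delta_alpha")
    rcp = out[out["component"] == "RCP"]
    south = rcp[rcp["row"] >= 3]["share_of_explained"].mean()
    north = rcp[rcp["row"] < 3]["share_of_explained"].mean()
    assert south > north
    shares = out[out["component"].isin(["SDM", "GCM", "RCP"])]
    grp = shares.groupby(["row", "col"])["share_of_explained"].sum()
    assert np.allclose(grp, 100.0)
    maps = share_maps(out, (6, 4), "bird", "2041-2060")
    assert maps["RCP"][4, 0] > maps["RCP"][0, 0]


def test_partition_by_range_bin_single_bin_equals_pooled():
    tab = _random_table(17).assign(species_id="spA", tss=1.0)
    labels = pd.Series({"spA": 0})
    per_bin = partition_by_range_bin(tab, labels, response="value")
    pooled = nested_partition(tab).to_frame()
    got = per_bin[per_bin["component"] == "SDM"]["deviance"].iloc[0]
    want = pooled[pooled["component"] == "SDM"]["deviance"].iloc[0]
    assert got == pytest.approx(want)
    shares = per_bin[per_bin["component"].isin(["SDM", "GCM", "RCP"])]
    assert shares["share_of_explained"].sum() == pytest.approx(100.0, abs=1e-6)


def test_threshold_sensitivity_drops_planted_bad_algorithm():
    """An algorithm with label-noise-level skill (TSS 0.5) and divergent
    responses shows up at threshold 0.4 but not 0.7, shifting the SDM share."""
    good = _random_table(19, n_sdm=3).assign(tss=0.95)
    rng = np.random.default_rng(19)
    bad = good[good["algorithm"] == "S0"].copy()
    bad["algorithm"] = "S_noisy"
    bad["tss"] = 0.5
    # systematic divergence: the weak model projects a very different response
    bad["value"] = 8.0 + rng.normal(0, 1.0, len(bad))
    tab = pd.concat([good, bad], ignore_index=True)
    out = threshold_sensitivity(tab, (0.4, 0.6, 0.7), response="value")
    n_rows = out.groupby("tss_threshold")["n_rows"].first().sort_index()
    assert (n_rows.diff().dropna() <= 0).all()  # retention monotonicity
    sdm = out[out["component"] == "SDM"].set_index("tss_threshold")["share_of_explained"]
    assert sdm.loc[0.4] > sdm.loc[0.7]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        all_perfect = good.copy()
        same = threshold_sensitivity(all_perfect, (0.4, 0.6, 0.7), response="value")
    piv = same.pivot_table(index="component", columns="tss_threshold",
                           values="deviance")
    assert np.allclose(piv[0.4], piv[0.7])  # identical retained sets
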