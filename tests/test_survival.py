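"""NNLS deconvolution, quartile stratification, Kaplan-Meier and log-rank."""

import numpy as np
import pandas as pd
import pytest

from atlaskit import (AtlasConfig, CohortConfig, km_estimate, logrank_test,
                      nnls_deconvolve, simulate_atlas, simulate_cohort,
                      stratify_quartiles)
from atlaskit.synthetic import cluster_profiles


def _signatures():
    genes = [f"G{j}" for j in range(6)]
    S = pd.DataFrame({"A": [5.0, 1, 0, 2, 1, 0], "B": [0.0, 2, 4, 1, 0, 3]}, index=genes)
    return S


# ---------------------------------------------------------------------------
# deconvolution

def test_nnls_pure_signature_recovered():
    S = _signatures()
    bulk = pd.DataFrame([S["A"].to_numpy()], columns=S.index, index=["s1"])
    res = nnls_deconvolve(bulk, S)
    assert res.proportions.loc["s1", "A"] == pytest.approx(1.0, abs=1e-10)


def test_nnls_noiseless_mixture_exact():
    S = _signatures()
    mix = 0.3 * S["A"] + 0.7 * S["B"]
    bulk = pd.DataFrame([mix.to_numpy()], columns=S.index, index=["s1"])
    res = nnls_deconvolve(bulk, S)
    np.testing.assert_allclose(res.proportions.loc["s1"].to_numpy(), [0.3, 0.7],
                               atol=1e-6)


def test_nnls_synthetic_cohort_recovery(default_atlas, atlas_profiles):
    co = simulate_cohort(CohortConfig(n_samples=100, seed=4), default_atlas)
    res = nnls_deconvolve(co.expression, atlas_profiles.T)
    err = res.proportions[co.proportions_true.columns] - co.proportions_true
    rmse = float(np.sqrt((err.to_numpy() ** 2).mean()))
    assert rmse < 0.05


def test_build_signatures_normalized_means(default_atlas):
    from atlaskit.survival import build_signatures
    S = build_signatures(default_atlas, "cluster")
    assert set(S.columns) == set(default_atlas.obs["cluster"].unique())
    assert list(S.index) == list(default_atlas.var_names)
    with pytest.raises(ValueError):
        build_signatures(default_atlas, "cluster", scale="bogus")


def test_nnls_all_zero_sample_flagged():
    S = _signatures()
    bulk = pd.DataFrame([[0.0] * 6], columns=S.index, index=["empty"])
    res = nnls_deconvolve(bulk, S)
    assert "empty" in res.undefined_samples
    assert res.proportions.loc["empty"].isna().all()


def test_nnls_gene_weights_change_fit():
    S = _signatures()
    noisy = 0.5 * S["A"] + 0.5 * S["B"]
    noisy.iloc[0] += 3.0   # corrupt one gene
    bulk = pd.DataFrame([noisy.to_numpy()], columns=S.index, index=["s"])
    plain = nnls_deconvolve(bulk, S).proportions.loc["s"]
    down = nnls_deconvolve(bulk, S, weights=[0.01, 1, 1, 1, 1, 1]).proportions.loc["s"]
    # down-weighting the corrupted gene pulls the fit back toward 50/50
    assert abs(down["A"] - 0.5) < abs(plain["A"] - 0.5)


# ---------------------------------------------------------------------------
# stratification

def test_stratify_quartiles_worked_example():
    groups = stratify_quartiles(pd.Series(np.arange(1.0, 9.0)))
    assert set(groups[groups == "high"].index) == {6, 7}    # values 7, 8
    assert set(groups[groups == "low"].index) == {0, 1}     # values 1, 2
    assert (groups == "excluded").sum() == 4


def test_stratify_quartiles_counts_at_n100(rng):
    groups = stratify_quartiles(pd.Series(rng.permutation(100).astype(float)))
    assert (groups == "high").sum() == 25
    assert (groups == "low").sum() == 25


def test_stratify_quartiles_errors():
    with pytest.raises(ValueError):
        stratify_quartiles([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        stratify_quartiles([2.0] * 10)


# ---------------------------------------------------------------------------
# Kaplan-Meier

def test_km_no_events_flat_at_one():
    fit = km_estimate([1, 2, 3, 4], [0, 0, 0, 0])
    assert fit.curves["all"].empty or (fit.curves["all"]["survival"] == 1).all()


def test_km_all_events_product_limit_by_hand():
    fit = km_estimate([1, 2, 3], [1, 1, 1])
    curve = fit.curves["all"]
    np.testing.assert_allclose(curve["survival"].to_numpy(),
                               [2 / 3, 1 / 3, 0.0], atol=1e-12)


def test_km_censoring_shrinks_risk_set():
    # times [1, 2+, 3]: S(1) = 2/3, S(3) = 2/3 * (1 - 1/1) = 0
    fit = km_estimate([1, 2, 3], [1, 0, 1])
    curve = fit.curves["all"]
    np.testing.assert_allclose(curve["survival"].to_numpy(), [2 / 3, 0.0], atol=1e-12)


def test_km_matches_lifelines(rng):
    from lifelines import KaplanMeierFitter
    times = rng.exponential(5.0, 80)
    events = rng.integers(0, 2, 80)
    fit = km_estimate(times, events)
    curve = fit.curves["all"]
    kmf = KaplanMeierFitter().fit(times, events)
    for _, row in curve.iterrows():
        assert row["survival"] == pytest.approx(
            float(kmf.survival_function_at_times(row["time"]).iloc[0]), abs=1e-10)


def test_km_curves_monotone_in_unit_interval(rng):
    times = rng.exponential(3.0, 60)
    events = rng.integers(0, 2, 60)
    curve = km_estimate(times, events).curves["all"]
    s = curve["survival"].to_numpy()
    assert np.all((0 <= s) & (s <= 1))
    assert np.all(np.diff(s) <= 1e-12)


def test_km_negative_time_errors():
    with pytest.raises(ValueError):
        km_estimate([-1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# log-rank

def _logrank_oracle(times, events, g1):
    """Hand-style O/E/V hypergeometric tables."""
    o_e, v = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at = times >= t
        n, n1 = at.sum(), (at & g1).sum()
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        o_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_e ** 2 / v if v > 0 else 0.0


def test_logrank_identical_groups_null():
    times = np.array([1.0, 2, 3, 1, 2, 3])
    events = np.array([1, 1, 0, 1, 1, 0])
    chi2, p = logrank_test(times, events, np.repeat(["a", "b"], 3))
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_separated_groups_matches_hand_tables():
    times = np.array([1.0, 2, 3, 4, 5, 6])
    events = np.ones(6, dtype=int)
    groups = np.repeat(["A", "B"], 3)
    chi2, p = logrank_test(times, events, groups)
    expected = _logrank_oracle(times, events, groups == "A")
    assert chi2 == pytest.approx(expected, rel=1e-12)
    from scipy.stats import chi2 as chi2_dist
    assert p == pytest.approx(chi2_dist.sf(expected, 1), rel=1e-12)


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test as ll_logrank
    times = rng.exponential(5.0, 100)
    events = rng.integers(0, 2, 100)
    groups = rng.integers(0, 2, 100)
    chi2, p = logrank_test(times, events, groups)
    ref = ll_logrank(times[groups == 0], times[groups == 1],
                     events[groups == 0], events[groups == 1])
    assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
    assert p == pytest.approx(ref.p_value, rel=1e-8)


def test_logrank_requires_two_groups():
    with pytest.raises(ValueError):
        logrank_test([1, 2], [1, 1], ["a", "a"])


def test_end_to_end_survival_detects_planted_hazard(default_atlas, atlas_profiles):
    co = simulate_cohort(CohortConfig(seed=8), default_atlas)
    dec = nnls_deconvolve(co.expression, atlas_profiles.T)
    groups = stratify_quartiles(dec.proportions[co.hazard_cluster])
    m = groups != "excluded"
    chi2, p = logrank_test(co.survival["time"][m].to_numpy(),
                           co.survival["event"][m].to_numpy(),
                           groups[m].to_numpy())
    assert p < 0.05
    # high-proportion stratum should fare worse (positive planted log-HR)
    fit = km_estimate(co.survival["time"][m], co.survival["event"][m], groups[m])
    t = min(c["time"].max() for c in fit.curves.values())
    s_at = {g: c[c["time"] <= t]["survival"].iloc[-1] for g, c in fit.curves.items()}
    assert s_at["high"] < s_at["low"]
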