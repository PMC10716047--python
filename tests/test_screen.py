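"""Size factors, dispersion estimation and the NB Wald depletion test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from orfscreen.screen import (
    ScreenDepletionModel,
    control_size_factors,
    estimate_dispersion,
    moderate_dispersion,
    nb_wald_test,
    pooled_dispersion,
)


def _conditions(n0=3, n1=6):
    samples = [f"D0_{i}" for i in range(n0)] + [f"D21_{i}" for i in range(n1)]
    return pd.Series(["day0"] * n0 + ["day21"] * n1, index=samples)


def _null_matrix(rng, n_rows=2000, depth=300, dispersion=0.05, n0=3, n1=6):
    cond = _conditions(n0, n1)
    base = depth * rng.lognormal(0, 1, n_rows)
    base *= depth / base.mean()
    r = 1 / dispersion
    counts = pd.DataFrame(
        {s: rng.negative_binomial(r, r / (r + base)) for s in cond.index},
        index=[f"g{i}" for i in range(n_rows)],
    )
    return counts, cond


def test_size_factors_identity_and_scale_equivariance():
    counts = pd.DataFrame(
        {"a": [10, 20, 30], "b": [10, 20, 30], "c": [10, 20, 30]},
        index=["g1", "g2", "g3"],
    )
    sf = control_size_factors(counts)
    assert np.allclose(sf, 1.0)
    doubled = counts.copy()
    doubled["b"] *= 2
    sf2 = control_size_factors(doubled)
    assert sf2["b"] == pytest.approx(2.0)
    assert sf2["a"] == sf2["c"] == pytest.approx(1.0)


def test_size_factors_match_direct_formula(rng):
    counts = pd.DataFrame(
        rng.negative_binomial(20, 0.1, size=(300, 6)),
        index=[f"g{i}" for i in range(300)],
        columns=list("abcdef"),
    )
    controls = [f"g{i}" for i in range(100)]
    sf = control_size_factors(counts, controls)
    # independent brute-force median-of-ratios
    sub = counts.loc[controls].to_numpy(dtype=float)
    sub = sub[(sub > 0).all(axis=1)]
    geo = np.exp(np.mean(np.log(sub), axis=1))
    raw = np.array(
        [np.median(sub[:, j] / geo) for j in range(len(counts.columns))]
    )
    expected = raw / np.median(raw)
    for j, col in enumerate(counts.columns):
        assert sf[col] == pytest.approx(expected[j])


def test_size_factors_require_usable_controls():
    counts = pd.DataFrame({"a": [0, 1], "b": [1, 0]}, index=["g1", "g2"])
    with pytest.raises(ValueError, match="no usable controls"):
        control_size_factors(counts)


def test_dispersion_poisson_near_zero(rng):
    cond = _conditions(3, 3)
    counts = pd.DataFrame(
        rng.poisson(500, size=(2000, 6)), columns=cond.index
    )
    sf = control_size_factors(counts)
    alpha = estimate_dispersion(counts, sf, cond)
    assert alpha.median() <= 0.05


def test_dispersion_recovers_planted_alpha(rng):
    counts, cond = _null_matrix(rng, n_rows=10_000, dispersion=0.1)
    sf = control_size_factors(counts)
    alpha = estimate_dispersion(counts, sf, cond)
    assert 0.05 <= alpha.median() <= 0.2
    assert 0.05 <= pooled_dispersion(counts, sf, cond) <= 0.2


def test_dispersion_constant_row_floored():
    cond = _conditions(2, 2)
    counts = pd.DataFrame(
        {s: [7, 0] for s in cond.index}, index=["flat", "zero"]
    )
    sf = pd.Series(1.0, index=cond.index)
    alpha = estimate_dispersion(counts, sf, cond)
    assert alpha["flat"] == pytest.approx(1e-8)  # clipped to 0, floored
    assert alpha["zero"] == 0.0


def test_wald_identical_means_gives_null_result():
    cond = _conditions(3, 3)
    counts = pd.DataFrame({s: [100, 50] for s in cond.index}, index=["a", "b"])
    sf = pd.Series(1.0, index=cond.index)
    alpha = pd.Series(0.0, index=counts.index)
    stats = nb_wald_test(counts, sf, alpha, cond)
    assert np.allclose(stats["log2fc"], 0)
    assert np.allclose(stats["p"], 1)


def test_wald_zero_rows_excluded_from_bh():
    cond = _conditions(2, 2)
    counts = pd.DataFrame(
        {s: [100, 0] for s in cond.index}, index=["expressed", "empty"]
    )
    sf = pd.Series(1.0, index=cond.index)
    alpha = pd.Series([0.01, 0.0], index=counts.index)
    stats = nb_wald_test(counts, sf, alpha, cond)
    assert np.isnan(stats.loc["empty", "p"]) and np.isnan(stats.loc["empty", "fdr"])
    assert not np.isnan(stats.loc["expressed", "p"])


def test_wald_degenerate_design_errors():
    cond = pd.Series(["day0"] * 3, index=["a", "b", "c"])
    counts = pd.DataFrame({s: [5] for s in cond.index})
    sf = pd.Series(1.0, index=cond.index)
    with pytest.raises(ValueError):
        nb_wald_test(counts, sf, pd.Series([0.0]), cond)


def test_sample_scaling_invariance(rng):
    """Scaling one sample (controls included) leaves log2fc and p unchanged.

    The scaled sample must not be the median anchor of the factors, else the
    global normalization constant legitimately moves; scaling the deepest
    sample keeps the anchor fixed and the absorption is exact.
    """
    counts, cond = _null_matrix(rng, n_rows=500)
    sf = control_size_factors(counts)
    alpha = estimate_dispersion(counts, sf, cond)
    base = nb_wald_test(counts, sf, alpha, cond)
    deepest = sf.idxmax()
    scaled = counts.copy()
    scaled[deepest] *= 3
    sf2 = control_size_factors(scaled)
    assert sf2[deepest] == pytest.approx(3 * sf[deepest])
    stats2 = nb_wald_test(scaled, sf2, alpha, cond)
    assert np.allclose(stats2["log2fc"], base["log2fc"])
    assert np.allclose(stats2["p"], base["p"])


def test_wald_poisson_limit_agreement(rng):
    """With alpha=0 and large counts the Wald p tracks the Poisson closed form."""
    cond = _conditions(3, 3)
    sf = pd.Series(1.0, index=cond.index)
    rows = rng.poisson(2000, size=(200, 6))
    counts = pd.DataFrame(rows, columns=cond.index)
    alpha = pd.Series(0.0, index=counts.index)
    stats = nb_wald_test(counts, sf, alpha, cond)
    k0 = rows[:, :3].sum(axis=1).astype(float)
    k1 = rows[:, 3:].sum(axis=1).astype(float)
    # Poisson-limit Wald on log2 ratio: se^2 = (1/k0 + 1/k1)/ln2^2
    lfc = np.log2(k1 / k0)
    se = np.sqrt(1 / k0 + 1 / k1) / np.log(2)
    p_ref = 2 * sps.norm.sf(np.abs(lfc / se))
    ok = p_ref > 1e-10
    rel = np.abs(stats["p"].to_numpy()[ok] - p_ref[ok]) / p_ref[ok]
    assert np.quantile(rel, 0.95) < 0.10


def test_type_one_error_calibrated(rng):
    counts, cond = _null_matrix(rng, n_rows=4000)
    model = ScreenDepletionModel(counts, cond)
    res = model.fit()
    frac = (res.stats["p"] < 0.05).mean()
    assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / len(counts))


def test_power_on_planted_depletion(rng):
    """4-fold depleted rows: median log2fc within 0.3 of -2, >=90% significant."""
    cond = _conditions(3, 6)
    n, n_dep = 800, 200
    base = 500 * rng.lognormal(0, 1, n)
    base *= 500 / base.mean()
    effect = np.where(np.arange(n) < n_dep, 0.25, 1.0)
    r = 1 / 0.05
    cols = {}
    for s in cond.index:
        mean = base * (effect if cond[s] == "day21" else 1.0)
        cols[s] = rng.negative_binomial(r, r / (r + mean))
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
    controls = [f"g{i}" for i in range(n_dep, n)]  # unaffected guides anchor
    res = ScreenDepletionModel(counts, cond, control_rows=controls).fit()
    dep = res.stats.iloc[:n_dep]
    assert abs(dep["log2fc"].median() + 2) <= 0.3
    sig = (dep["p"] < 0.05) & (dep["log2fc"] <= -np.log2(1.5))
    assert sig.mean() >= 0.90


def test_bh_universe_and_results_summary(screen_bundle):
    b = screen_bundle
    model = ScreenDepletionModel(
        b.counts, b.conditions,
        control_rows=[g.guide_id for g in b.library.by_class("negative_control")],
    )
    res = model.fit()
    text = res.summary()
    assert "NB Wald" in text and "day21" in text
    tested = res.stats["p"].notna()
    assert np.array_equal(
        res.stats.loc[tested, "fdr"].to_numpy(),
        # BH recomputed over exactly the tested rows
        __import__("orfscreen")._stats.bh_adjust(
            res.stats.loc[tested, "p"].to_numpy()
        ),
    )


def test_moderation_keeps_zero_rows_zero(rng):
    counts, cond = _null_matrix(rng, n_rows=50)
    counts.iloc[0] = 0
    sf = control_size_factors(counts.iloc[1:])
    sf = sf  # factors from nonzero rows
    raw = estimate_dispersion(counts, sf, cond)
    mod = moderate_dispersion(raw, counts, sf, cond)
    assert mod.iloc[0] == 0.0
    assert (mod.iloc[1:] > 0).all()
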