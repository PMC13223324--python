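"""Hierarchical partitioning and stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from ecoserv.drivers import (hierarchical_partition, hp_order_averaging_oracle,
                             ols_r2, stepwise, driver_table)
from ecoserv.synthetic import synthetic_service_panel


def test_exact_linear_relation_r2_one():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(30, 2))
    y = 2 * x[:, 0] - x[:, 1] + 3
    assert ols_r2(y, x) == pytest.approx(1.0)


def test_pure_noise_r2_near_zero():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(2000, 1))
    y = rng.normal(size=2000)
    assert ols_r2(y, x) == pytest.approx(0.0, abs=0.05)


def test_single_predictor_r2_is_squared_pearson():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(size=40)
    from ecoserv.tradeoffs import pearson
    r, _, _ = pearson(x, y)
    assert ols_r2(y, x[:, None]) == pytest.approx(r**2)


def test_hp_single_predictor_degenerate():
    rng = np.random.default_rng(3)
    x = pd.DataFrame({"x1": rng.normal(size=30)})
    y = x["x1"] * 2 + rng.normal(size=30)
    res = hierarchical_partition(y, x)
    assert res.independent["x1"] == pytest.approx(ols_r2(y, x))
    assert res.joint["x1"] == pytest.approx(0.0, abs=1e-12)


def test_hp_orthogonal_predictors_no_joint():
    n = 64
    t = np.arange(n)
    x = pd.DataFrame({"a": np.cos(2 * np.pi * t / n),
                      "b": np.sin(2 * np.pi * t / n)})
    y = 3 * x["a"] + 1 * x["b"] + 0.0
    res = hierarchical_partition(y, x)
    assert res.independent["a"] == pytest.approx(ols_r2(y, x[["a"]]), abs=1e-10)
    assert res.joint.abs().max() < 1e-10


def test_hp_matches_order_averaging_oracle():
    rng = np.random.default_rng(4)
    x = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
    # correlated design to exercise joint contributions
    x["b"] = x["b"] + 0.8 * x["a"]
    y = x["a"] + 0.5 * x["b"] - 0.3 * x["c"] + rng.normal(size=25)
    res = hierarchical_partition(y, x)
    oracle = hp_order_averaging_oracle(y, x)
    pd.testing.assert_series_equal(res.independent, oracle, atol=1e-10,
                                   check_names=False)


def test_hp_k4_exhaustive_oracle_equality():
    rng = np.random.default_rng(5)
    x = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
    y = rng.normal(size=40) + x.sum(axis=1)
    res = hierarchical_partition(y, x)
    oracle = hp_order_averaging_oracle(y, x)
    np.testing.assert_allclose(res.independent, oracle, atol=1e-10)


def test_hp_independent_sums_to_full_r2():
    rng = np.random.default_rng(6)
    x = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
    y = x["a"] - x["c"] + rng.normal(size=50)
    res = hierarchical_partition(y, x)
    assert res.independent.sum() == pytest.approx(res.full_r2, abs=1e-8)
    assert res.percent.sum() == pytest.approx(100.0, abs=1e-6)


def test_hp_collinear_proportions_still_partition():
    """Predictors summing to one (a compositional design) keep ΣI = R²."""
    _, props = synthetic_service_panel(
        pd.DataFrame({"forest": [1.0]}, index=["s"]), seed=7)
    rng = np.random.default_rng(7)
    y = 3 * props["forest"] + rng.normal(0, 0.05, len(props))
    res = hierarchical_partition(y.to_numpy(), props)
    assert res.independent.sum() == pytest.approx(res.full_r2, abs=1e-8)
    assert res.percent.idxmax() == "forest"


def test_hp_too_many_predictors_rejected():
    x = pd.DataFrame(np.zeros((30, 13)))
    with pytest.raises(ValueError, match="subset"):
        hierarchical_partition(np.zeros(30), x)


def test_stepwise_recovers_single_true_driver():
    rng = np.random.default_rng(8)
    x = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
    y = 2.0 * x["a"]
    res = stepwise(y.to_numpy(), x)
    assert res.predictors == ["a"]
    assert res.coefficients["a"] == pytest.approx(2.0)
    assert res.r2 == pytest.approx(1.0)


def test_stepwise_null_intercept_only_rate_matches_theory():
    """Under the global null (n = 29, 7 independent noise predictors), the
    chance that no predictor enters at α_in = 0.05 is (1−α)^7 ≈ 0.70 —
    the familywise inflation of testing the minimum of 7 p-values.  The
    simulated rate over 500 replicates must sit within binomial noise of
    that value."""
    rng = np.random.default_rng(9)
    empty = 0
    reps = 500
    for _ in range(reps):
        x = pd.DataFrame(rng.normal(size=(29, 7)))
        y = rng.normal(size=29)
        if not stepwise(y, x).predictors:
            empty += 1
    rate = empty / reps
    assert abs(rate - 0.95**7) < 0.07  # ±~3.5 binomial sd


def test_stepwise_duplicate_column_enters_once():
    rng = np.random.default_rng(10)
    a = rng.normal(size=35)
    x = pd.DataFrame({"a": a, "dup": a, "noise": rng.normal(size=35)})
    y = 3 * a + rng.normal(0, 0.1, 35)
    res = stepwise(y, x)
    assert len(res.predictors) == 1
    assert res.predictors[0] in ("a", "dup")


def test_stepwise_support_and_coefficient_recovery_at_high_snr():
    """With services linear in proportions (n = 116 = 29×4) and SNR ≥ 5,
    selection recovers the planted support and coefficients within 10%."""
    coeffs = pd.DataFrame(
        {"intercept": [10.0], "forest": [40.0], "urban_rural": [-25.0]},
        index=["svc"])
    # signal sd across the Dirichlet draw is a few units; noise sd 0.45
    # keeps the sd ratio comfortably above 5
    panel, props = synthetic_service_panel(coeffs, noise_sd=0.45, seed=11)
    y = panel["svc"].to_numpy()
    res = stepwise(y, props)
    assert set(res.predictors) >= {"forest", "urban_rural"}
    assert res.coefficients["forest"] == pytest.approx(40.0, rel=0.10)
    assert res.coefficients["urban_rural"] == pytest.approx(-25.0, rel=0.10)


def test_stepwise_alpha_order_enforced():
    with pytest.raises(ValueError):
        stepwise(np.zeros(10), pd.DataFrame(np.zeros((10, 1))),
                 alpha_in=0.2, alpha_out=0.1)


def test_driver_table_planted_single_driver_dominates():
    coeffs = pd.DataFrame({"intercept": [5.0], "forest": [30.0]},
                          index=["carbon_t_hm2"])
    panel, props = synthetic_service_panel(coeffs, noise_sd=1e-6, seed=12)
    contrib, equations = driver_table(panel, props, ["carbon_t_hm2"],
                                      ["1990", "2000", "2010", "2020"])
    assert contrib.loc["forest", "carbon_t_hm2"] > 60.0
    assert contrib.loc["forest", "carbon_t_hm2"] == contrib["carbon_t_hm2"].max()
    assert (equations["r2"] > 0.99).all()


def test_driver_table_disjoint_drivers_separated():
    coeffs = pd.DataFrame(
        {"forest": [30.0, 0.0], "paddy": [0.0, 20.0]},
        index=["svc_a", "svc_b"])
    panel, props = synthetic_service_panel(coeffs, noise_sd=0.01, seed=13)
    contrib, _ = driver_table(panel, props, ["svc_a", "svc_b"],
                              ["1990", "2000"])
    assert contrib["svc_a"].idxmax() == "forest"
    assert contrib["svc_b"].idxmax() == "paddy"


def test_driver_table_single_year_equals_per_year_hp():
    coeffs = pd.DataFrame({"forest": [10.0]}, index=["svc"])
    panel, props = synthetic_service_panel(coeffs, noise_sd=0.2, seed=14)
    contrib, _ = driver_table(panel, props, ["svc"], ["2010"])
    sv = panel.xs("2010", level="year")["svc"]
    pr = props.xs("2010", level="year")
    direct = hierarchical_partition(sv.to_numpy(), pr).percent
    np.testing.assert_allclose(contrib["svc"], direct, atol=1e-12)
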