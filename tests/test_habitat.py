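"""Habitat quality: influence decay, degradation aggregation, saturation curve."""

import numpy as np
import pytest

from ecoserv.grids import FOREST, URBAN
from ecoserv.habitat import (HabitatParams, degradation, habitat_quality,
                             regional_mean_quality, threat_influence)
from .conftest import toy_raster


def test_influence_one_at_source_zero_at_dmax():
    mask = np.zeros((1, 7), dtype=bool)
    mask[0, 0] = True
    infl = threat_influence(mask, d_max_km=3.0, decay="linear")
    assert infl[0, 0] == 1.0
    assert infl[0, 3] == 0.0
    assert infl[0, 1] == pytest.approx(2 / 3)
    assert infl[0, 2] == pytest.approx(1 / 3)


def test_exponential_decay_form():
    mask = np.zeros((1, 5), dtype=bool)
    mask[0, 0] = True
    infl = threat_influence(mask, d_max_km=2.0, decay="exponential")
    assert infl[0, 2] == pytest.approx(np.exp(-2.99))


def test_no_threat_cells_zero_influence():
    assert (threat_influence(np.zeros((3, 3), bool), 3.0, "linear") == 0).all()


def test_no_threats_zero_degradation(threats, sensitivity):
    lu = toy_raster(np.full((5, 5), FOREST))
    assert (degradation(lu, threats, sensitivity) == 0).all()


def test_single_urban_neighbour_scalar_oracle(threats, sensitivity):
    codes = np.full((1, 5), FOREST)
    codes[0, 0] = URBAN
    lu = toy_raster(codes)
    d = degradation(lu, threats, sensitivity)
    w_total = float(threats.table.weight.sum())  # 1 + 1 + 0.5 + 0.5 = 3
    # forest cell at distance 1 from the lone urban cell, no other threats
    infl = 1.0 - 1.0 / 12.0
    expected = (1.0 / w_total) * infl * 0.8
    assert d[0, 1] == pytest.approx(expected)


def test_insensitive_habitat_untouched(threats, sensitivity):
    zeroed = sensitivity.table.copy()
    zeroed.loc["forest", ["urban_rural", "unused", "paddy", "dry"]] = 0.0
    from ecoserv.params import SensitivityRecord
    sens0 = SensitivityRecord(zeroed)
    codes = np.full((1, 4), FOREST)
    codes[0, 0] = URBAN
    d = degradation(toy_raster(codes), threats, sens0)
    assert (d[0, 1:] == 0).all()


def test_quality_equals_suitability_without_degradation(sensitivity):
    lu = toy_raster(np.full((2, 2), FOREST))
    res = habitat_quality(np.zeros((2, 2)), lu, sensitivity)
    assert np.allclose(res.quality, 1.0)  # forest suitability 1


def test_half_saturation_halves_quality(sensitivity):
    lu = toy_raster(np.full((1, 2), FOREST))
    d = np.array([[0.4, 0.2]])  # max 0.4 → k = 0.2; second cell sits at D = k
    res = habitat_quality(d, lu, sensitivity)
    assert res.k == pytest.approx(0.2)
    assert res.quality[0, 1] == pytest.approx(0.5)


def test_threat_source_classes_zero_quality(threats, sensitivity):
    codes = np.full((3, 3), URBAN)
    lu = toy_raster(codes)
    d = degradation(lu, threats, sensitivity)
    res = habitat_quality(d, lu, sensitivity)
    assert (res.quality == 0).all()  # urban suitability 0


def test_quality_bounded_by_suitability(small_landuse, threats, sensitivity):
    d = degradation(small_landuse, threats, sensitivity)
    res = habitat_quality(d, small_landuse, sensitivity)
    assert (res.quality >= 0).all()
    for cls in sensitivity.table.index:
        from ecoserv.grids import NAME_TO_CODE
        m = small_landuse.codes == NAME_TO_CODE[cls]
        if m.any():
            assert res.quality[m].max() <= sensitivity.suitability(cls) + 1e-12


def test_quality_monotone_in_degradation(sensitivity):
    lu = toy_raster(np.full((1, 4), FOREST))
    d = np.array([[0.0, 0.1, 0.3, 0.6]])
    res = habitat_quality(d, lu, sensitivity, HabitatParams(k_override=0.3))
    q = res.quality[0]
    assert (np.diff(q) < 0).all()


def test_adding_threats_never_raises_quality(threats, sensitivity):
    codes = np.full((6, 6), FOREST)
    codes[0, 0] = URBAN
    lu1 = toy_raster(codes.copy())
    codes[5, 5] = URBAN
    lu2 = toy_raster(codes)
    k = 0.5  # fixed k so the runs are comparable
    q1 = habitat_quality(degradation(lu1, threats, sensitivity), lu1,
                         sensitivity, HabitatParams(k_override=k)).quality
    q2 = habitat_quality(degradation(lu2, threats, sensitivity), lu2,
                         sensitivity, HabitatParams(k_override=k)).quality
    assert (q2 <= q1 + 1e-12).all()


def test_missing_sensitivity_rejected(threats, sensitivity):
    from ecoserv.params import SensitivityRecord
    partial = SensitivityRecord(sensitivity.table.drop(index="forest"))
    lu = toy_raster(np.full((2, 2), FOREST))
    with pytest.raises(KeyError, match="forest"):
        degradation(lu, threats, partial)


def test_zero_degradation_warns_and_returns_suitability(sensitivity, caplog):
    import logging
    lu = toy_raster(np.full((2, 2), FOREST))
    with caplog.at_level(logging.WARNING):
        res = habitat_quality(np.zeros((2, 2)), lu, sensitivity)
    assert "override" in caplog.text
    assert np.allclose(res.quality, 1.0)


def test_regional_mean_two_ways(threats, sensitivity):
    """Cell-mean regional quality equals the area-weighted class mean on a
    homogeneous two-class split."""
    from ecoserv.grids import RegionPartition
    codes = np.full((4, 4), FOREST)
    codes[:, 2:] = URBAN
    lu = toy_raster(codes)
    d = degradation(lu, threats, sensitivity)
    res = habitat_quality(d, lu, sensitivity)
    regions = RegionPartition(np.zeros((4, 4), dtype=np.int64))
    cell_mean = regional_mean_quality(res, lu, regions)[0]
    forest_q = res.quality[codes == FOREST].mean()
    urban_q = res.quality[codes == URBAN].mean()
    assert cell_mean == pytest.approx(0.5 * forest_q + 0.5 * urban_q)
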