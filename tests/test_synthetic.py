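"""Generator contracts: determinism, proportion control, spatial structure."""

import numpy as np
import pytest

from ecoserv.accounting import class_areas, transfer_matrix
from ecoserv.grids import DRY, URBAN, CLASS_NAMES
from ecoserv.synthetic import (LandscapeSpec, advance_landuse, generate_climate,
                               generate_landuse, generate_regions,
                               generate_soil_terrain, landuse_series, morans_i)


def test_degenerate_proportions_single_class():
    spec = LandscapeSpec(grid_rows=20, grid_cols=20,
                         class_proportions={"dry": 1.0}, seed=0)
    lu = generate_landuse(spec)
    assert (lu.codes == DRY).all()


def test_same_seed_bit_identical():
    spec = LandscapeSpec(grid_rows=40, grid_cols=40, seed=11)
    a, b = generate_landuse(spec), generate_landuse(spec)
    assert np.array_equal(a.codes, b.codes)


def test_different_seed_differs():
    spec = LandscapeSpec(grid_rows=40, grid_cols=40, seed=11)
    other = generate_landuse(spec, seed=12)
    assert not np.array_equal(generate_landuse(spec).codes, other.codes)


def test_invalid_proportions_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        LandscapeSpec(class_proportions={"dry": 0.5, "paddy": 0.4})


def test_realized_proportions_within_two_points():
    # 2020-era shares: cropland-dominated with merged remainder on water
    props = {"dry": 0.512, "paddy": 0.205, "urban_rural": 0.165,
             "forest": 0.097, "water": 0.021}
    spec = LandscapeSpec(grid_rows=200, grid_cols=200,
                         class_proportions=props, seed=3)
    lu = generate_landuse(spec)
    realized = class_areas(lu) / (200 * 200)
    for name, target in props.items():
        assert abs(realized[name] - target) <= 0.02


def test_patches_spatially_autocorrelated(small_landuse):
    # every non-trivial class indicator clusters on the 4-neighbour lattice
    for code in np.unique(small_landuse.codes):
        indicator = small_landuse.codes == code
        if 0 < indicator.mean() < 1:
            assert morans_i(indicator) > 0


def test_advance_empty_rules_identity(small_landuse):
    out = advance_landuse(small_landuse, [], seed=1)
    assert np.array_equal(out.codes, small_landuse.codes)


def test_advance_exact_cell_counts(small_landuse):
    n_paddy = int((small_landuse.codes == 6).sum())
    out = advance_landuse(small_landuse, [("paddy", "urban_rural", 0.05)], seed=2)
    changed = small_landuse.codes != out.codes
    assert changed.sum() == round(0.05 * n_paddy)
    # all changed cells were paddy and became urban
    assert (small_landuse.codes[changed] == 6).all()
    assert (out.codes[changed] == URBAN).all()


def test_advance_conservation_via_transfer_matrix(small_landuse):
    rules = [("paddy", "urban_rural", 0.05), ("dry", "urban_rural", 0.02)]
    out = advance_landuse(small_landuse, rules, seed=3)
    tm = transfer_matrix(small_landuse, out)
    off_diag = tm.total_area - np.trace(tm.matrix.to_numpy())
    assert off_diag == (small_landuse.codes != out.codes).sum()
    assert tm.total_area == small_landuse.codes.size


def test_advance_overdraw_converts_all(small_landuse, caplog):
    out = advance_landuse(small_landuse, [("unused", "dry", 5.0)], seed=4)
    assert (out.codes == 5).sum() == 0


def test_advance_prefers_adjacency(small_landuse):
    """Converted cells sit closer to the target class than the average source cell."""
    from scipy import ndimage
    out = advance_landuse(small_landuse, [("dry", "urban_rural", 0.1)], seed=5)
    dist = ndimage.distance_transform_edt(~(small_landuse.codes == URBAN))
    changed = (small_landuse.codes == DRY) & (out.codes == URBAN)
    untouched = (small_landuse.codes == DRY) & (out.codes == DRY)
    assert dist[changed].mean() < dist[untouched].mean()


def test_landuse_series_is_deterministic():
    spec = LandscapeSpec(grid_rows=40, grid_cols=40, seed=9,
                         years=("1990", "2000"))
    s1, s2 = landuse_series(spec), landuse_series(spec)
    for year in spec.years:
        assert np.array_equal(s1[year].codes, s2[year].codes)


def test_climate_zero_gradient_constant_field():
    spec = LandscapeSpec(grid_rows=30, grid_cols=30, precip_gradient=0.0, seed=0)
    clim = generate_climate(spec)
    assert np.allclose(clim.annual_precip, spec.precip_mean_mm)


def test_climate_domain_mean_within_one_percent():
    spec = LandscapeSpec(grid_rows=80, grid_cols=80, seed=0)
    clim = generate_climate(spec)
    assert abs(clim.annual_precip.mean() - 992.9) <= 9.9


def test_climate_gradient_monotone_and_consistent():
    spec = LandscapeSpec(grid_rows=60, grid_cols=40, precip_gradient=3.0, seed=1)
    clim = generate_climate(spec)
    row_means = clim.annual_precip.mean(axis=1)
    assert (np.diff(row_means) > 0).all()
    # annual equals monthly sum per cell
    assert np.allclose(clim.monthly_precip.sum(axis=0), clim.annual_precip,
                       atol=1e-6)


def test_soil_terrain_ranges():
    spec = LandscapeSpec(grid_rows=40, grid_cols=40, seed=2)
    soil = generate_soil_terrain(spec)
    assert (soil.k_factor >= 0).all() and (soil.ls_factor >= 0).all()
    assert ((soil.pawc >= 0) & (soil.pawc <= 1)).all()


def test_regions_contiguous_exhaustive_29():
    from scipy import ndimage
    spec = LandscapeSpec(grid_rows=200, grid_cols=200, n_regions=29, seed=5)
    reg = generate_regions(spec)
    labels = np.unique(reg.region_id)
    assert len(labels) == 29
    assert reg.region_id.min() >= 0  # exhaustive: every cell labelled
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for lab in labels:
        _, n_components = ndimage.label(reg.region_id == lab, structure=structure)
        assert n_components == 1


def test_nonpositive_grid_rejected():
    with pytest.raises(ValueError):
        LandscapeSpec(grid_rows=0, grid_cols=10)
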