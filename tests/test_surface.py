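"""Variogram fitting, kriging, Simpson's-diversity surfaces, edges, transects."""

import numpy as np
import pytest

from admixscape import surface
from admixscape.surface import (
    AncestrySurface,
    Raster,
    RasterSpec,
    Variogram,
    build_ancestry_surface,
    extract_edges,
    extract_transect,
    fit_variogram,
    idw_layer,
    krige_layer,
    krige_points,
    read_esri_ascii,
    simpson_surface,
    write_esri_ascii,
)

from .oracles import dense_ok_predict


def gaussian_field(rng, points, range_km, sill=1.0):
    """Draw one realization of a smooth random field at the given points."""
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    cov = sill * np.exp(-d / range_km) + 1e-9 * np.eye(len(points))
    return rng.multivariate_normal(np.zeros(len(points)), cov)


class TestVariogram:
    def test_constant_values_flat_variogram(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, size=(40, 2))
        v = fit_variogram(pts, np.full(40, 3.3))
        assert v.nugget == pytest.approx(0.0, abs=1e-9)
        assert v.sill < 1e-6

    def test_iid_values_show_no_spatial_structure(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 10, size=(120, 2))
        vals = rng.normal(size=120)
        v = fit_variogram(pts, vals)
        extent = 10 * np.sqrt(2)
        # either negligible range or a near-pure-nugget fit
        assert (v.range_ < 0.15 * extent) or (v.nugget > 0.6 * (v.nugget + v.sill))

    def test_known_range_recovered_within_factor_two(self):
        true_range = 2.0
        fitted = []
        for seed in range(9):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(0, 12, size=(130, 2))
            vals = gaussian_field(rng, pts, true_range)
            fitted.append(fit_variogram(pts, vals).range_)
        med = np.median(fitted)
        assert true_range / 2 <= med <= true_range * 2

    def test_coincident_points_rejected(self):
        pts = np.zeros((12, 2))
        with pytest.raises(ValueError, match="coincident"):
            fit_variogram(pts, np.arange(12.0))


class TestKriging:
    def test_constant_values_flat_surface(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 5, size=(20, 2))
        spec = RasterSpec(0.0, 0.0, 1.0, 5, 5)
        vgm = Variogram(0.0, 1.0, 2.0)
        r = krige_layer(pts, np.full(20, 0.7), vgm, spec)
        np.testing.assert_allclose(r.values, 0.7, atol=1e-9)

    def test_exact_interpolation_at_data_points(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 8, size=(25, 2))
        vals = rng.normal(size=25)
        vgm = Variogram(0.0, 1.0, 3.0)  # zero nugget
        pred = krige_points(pts, vals, vgm, pts)
        np.testing.assert_allclose(pred, vals, atol=1e-6)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_dense_solve_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30  # below the default neighborhood, so no truncation
        pts = rng.uniform(0, 10, size=(n, 2))
        vals = gaussian_field(rng, pts, 3.0)
        vgm = Variogram(0.05, 1.0, 3.0)
        targets = rng.uniform(0, 10, size=(15, 2))
        mine = krige_points(pts, vals, vgm, targets)
        oracle = dense_ok_predict(pts, vals, vgm, targets)
        np.testing.assert_allclose(mine, oracle, atol=1e-6)

    def test_duplicate_points_jitter_and_retry(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 0.5],
                        [0.5, 2.0]])
        vals = np.array([1.0, 1.0, 2.0, 3.0, 0.5])
        vgm = Variogram(0.0, 1.0, 1.0)
        pred = krige_points(pts, vals, vgm, np.array([[0.5, 0.5]]))
        assert np.isfinite(pred).all()

    def test_idw_exact_at_points_and_bounded(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 4, size=(15, 2))
        vals = rng.uniform(0, 1, 15)
        spec = RasterSpec(0.0, 0.0, 0.5, 8, 8)
        r = idw_layer(pts, vals, spec)
        assert r.values.min() >= vals.min() - 1e-12
        assert r.values.max() <= vals.max() + 1e-12


class TestAncestrySurface:
    def test_pure_population_gives_constant_layers(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 10, size=(30, 2))
        Q = np.tile([1.0, 0.0], (30, 1))
        surf = build_ancestry_surface(Q, coords, method="idw", n_cells_long=20)
        s = surf.stack()
        m = ~np.isnan(s[0])
        np.testing.assert_allclose(s[0][m], 1.0, atol=1e-9)
        np.testing.assert_allclose(s[1][m], 0.0, atol=1e-9)

    def test_cell_sums_renormalized_to_one(self, two_pool_dataset):
        tt = two_pool_dataset["truth_table"]
        md = two_pool_dataset["md"]
        Q = tt[["q0", "q1"]].to_numpy()
        surf = build_ancestry_surface(Q, md.coords(), method="ok", n_cells_long=25)
        s = surf.stack()
        m = ~np.isnan(s[0])
        np.testing.assert_allclose(s.sum(axis=0)[m], 1.0, atol=1e-6)

    def test_two_blocks_recovered(self):
        """Pure ancestry blocks map to near-0/1 plateaus on the kriged surface."""
        rng = np.random.default_rng(11)
        coords = np.column_stack([rng.uniform(0, 10, 80), rng.uniform(0, 4, 80)])
        qa = np.clip(np.where(coords[:, 0] < 5, 0.97, 0.03)
                     + rng.normal(0, 0.02, 80), 0, 1)
        Q = np.column_stack([qa, 1 - qa])
        surf = build_ancestry_surface(Q, coords, method="ok", n_cells_long=30)
        layer0 = surf.layers[0].values
        centers = surf.spec.cell_centers()[:, 0].reshape(layer0.shape)
        west = layer0[(centers < 3.0) & ~np.isnan(layer0)]
        east = layer0[(centers > 7.0) & ~np.isnan(layer0)]
        assert np.median(west) > 0.9
        assert np.median(east) < 0.1

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            build_ancestry_surface(np.ones((10, 1)), np.random.rand(10, 2))


class TestSimpson:
    def test_identities(self):
        spec = RasterSpec(0, 0, 1.0, 1, 3)
        cases = {
            # (p-vector) -> expected D
            (1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0): 0.0,
            tuple([1 / 8] * 8): 0.875,
            (0.5, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0): 0.5,
        }
        layers = []
        probs = np.array(list(cases.keys()))  # 3 cells × 8 clusters
        for k in range(8):
            layers.append(Raster(spec, probs[:, k].reshape(1, 3)))
        D = simpson_surface(AncestrySurface(layers))
        np.testing.assert_allclose(D.values.ravel(), list(cases.values()),
                                   atol=1e-12)

    def test_bounds_and_permutation_invariance(self):
        rng = np.random.default_rng(8)
        spec = RasterSpec(0, 0, 1.0, 4, 4)
        p = rng.dirichlet(np.ones(5), size=16).reshape(4, 4, 5)
        surf = AncestrySurface([Raster(spec, p[:, :, k]) for k in range(5)])
        D = simpson_surface(surf).values
        assert D.min() >= 0 and D.max() <= 1 - 1 / 5 + 1e-12
        perm = rng.permutation(5)
        surf_p = AncestrySurface([Raster(spec, p[:, :, k]) for k in perm])
        np.testing.assert_allclose(simpson_surface(surf_p).values, D, atol=1e-12)


class TestEdges:
    def _diag_ridge(self):
        spec = RasterSpec(0, 0, 1.0, 20, 20)
        y, x = np.mgrid[0:20, 0:20]
        vals = np.exp(-((x - 10) ** 2) / 8.0)  # vertical ridge at x=10
        return Raster(spec, vals)

    def test_flat_surface_warns_and_empty(self):
        spec = RasterSpec(0, 0, 1.0, 5, 5)
        with pytest.warns(UserWarning, match="flat"):
            edges = extract_edges(Raster(spec, np.full((5, 5), 0.4)))
        assert not edges.cells.any()

    def test_ridge_located_on_maximum(self):
        edges = extract_edges(self._diag_ridge(), percentile=90)
        rows, cols = np.nonzero(edges.ridge)
        assert len(rows) > 0
        assert np.abs(cols - 10).max() <= 1

    def test_higher_percentile_shrinks_edge_set(self):
        r = self._diag_ridge()
        lo = extract_edges(r, percentile=80)
        hi = extract_edges(r, percentile=95)
        assert hi.cells.sum() <= lo.cells.sum()
        assert not (hi.cells & ~lo.cells).any()

    def test_displacement_zero_against_itself(self):
        edges = extract_edges(self._diag_ridge())
        assert surface.edge_displacement(edges, edges) == 0.0


class TestTransect:
    def _setup(self):
        rng = np.random.default_rng(9)
        coords = np.column_stack([rng.uniform(0, 10, 60), rng.uniform(0, 4, 60)])
        qa = np.clip(1 - coords[:, 0] / 10 + rng.normal(0, 0.05, 60), 0, 1)
        Q = np.column_stack([qa, 1 - qa])
        return Q, coords

    def test_members_split_by_threshold(self):
        Q, coords = self._setup()
        tr = extract_transect(Q, coords, 0, 1, ((0, 2), (10, 2)), half_width=2.0,
                              q_min=0.8)
        assert np.all(Q[tr.parental_a, 0] >= 0.8)
        assert np.all(Q[tr.parental_b, 1] >= 0.8)
        assert len(set(tr.parental_a) & set(tr.parental_b)) == 0

    def test_boundary_individual_is_intermediate(self):
        Q = np.array([[0.79, 0.21]] + [[0.95, 0.05]] * 5 + [[0.05, 0.95]] * 5)
        coords = np.column_stack([np.linspace(0, 10, 11), np.zeros(11)])
        tr = extract_transect(Q, coords, 0, 1, ((0, 0), (10, 0)), half_width=1.0,
                              q_min=0.80)
        assert 0 in tr.intermediate

    def test_one_sided_transect_rejected(self):
        Q = np.tile([0.95, 0.05], (20, 1))
        coords = np.column_stack([np.linspace(0, 10, 20), np.zeros(20)])
        with pytest.raises(ValueError, match="parental"):
            extract_transect(Q, coords, 0, 1, ((0, 0), (10, 0)), half_width=1.0)

    def test_corridor_geometry_respected(self):
        Q, coords = self._setup()
        tr = extract_transect(Q, coords, 0, 1, ((0, 2), (10, 2)), half_width=1.0)
        assert np.all(np.abs(coords[tr.members, 1] - 2.0) <= 1.0 + 1e-12)


class TestRasterIO:
    def test_esri_ascii_roundtrip(self, tmp_path):
        rng = np.random.default_rng(10)
        spec = RasterSpec(2.5, -1.0, 0.5, 6, 4)
        vals = rng.normal(size=(6, 4)).round(4)
        vals[0, 0] = np.nan
        path = tmp_path / "layer.asc"
        write_esri_ascii(Raster(spec, vals), str(path))
        back = read_esri_ascii(str(path))
        assert back.spec == spec
        np.testing.assert_allclose(back.values, vals, atol=1e-9, equal_nan=True)
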