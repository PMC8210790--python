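"""Forward-simulator behavior: founder model, drift, barriers, export."""

import numpy as np
import pytest

from admixscape import simdata
from admixscape.simdata import (
    Barrier,
    LandscapeModel,
    SimParams,
    TranslocationEvent,
    export_dataset,
    run_simulation,
    simulate_founder_freqs,
)

from .oracles import wc_fst


class TestFounderFreqs:
    def test_theta_limit_collapses_pools(self):
        """As θ→0 the Balding–Nichols pools converge on the ancestral freqs."""
        f = simulate_founder_freqs(K=5, L=200, theta=1e-4, seed=0)
        assert np.max(f.max(axis=0) - f.min(axis=0)) < 0.05

    def test_single_pool_has_zero_fst(self):
        f = simulate_founder_freqs(K=1, L=50, theta=0.2, seed=0)
        assert f.shape == (1, 50)

    def test_theta_matches_wc_fst(self):
        """θ plays the role of FST among pools: Weir–Cockerham agrees ±0.03."""
        theta = 0.15
        f = simulate_founder_freqs(K=4, L=2000, theta=theta, seed=7)
        rng = np.random.default_rng(8)
        per_pool = 60
        g = np.concatenate(
            [rng.binomial(2, f[k], size=(per_pool, f.shape[1])) for k in range(4)]
        ).astype(np.int8)
        pops = np.repeat(np.arange(4), per_pool)
        assert wc_fst(g, pops) == pytest.approx(theta, abs=0.03)

    @pytest.mark.parametrize("bad", [{"theta": 0.0}, {"theta": 1.0}, {"K": 0}])
    def test_invalid_parameters_raise(self, bad):
        kwargs = {"K": 2, "L": 10, "theta": 0.2, **bad}
        with pytest.raises(ValueError):
            simulate_founder_freqs(**kwargs)


def _strip_landscape(nx=6, ny=1, **kw):
    return LandscapeModel(
        grid_nx=nx,
        grid_ny=ny,
        founder_regions=[
            [(ix, 0) for ix in range(nx // 2)],
            [(ix, 0) for ix in range(nx // 2, nx)],
        ],
        **kw,
    )


class TestRunSimulation:
    def test_no_migration_freezes_ancestry(self):
        land = _strip_landscape()
        params = SimParams(K=2, L=20, theta=0.2, Ne=50, m=0.0, T=25,
                           n_samples=10, seed=3)
        truth = run_simulation(land, params)
        expected = np.zeros((6, 2))
        expected[:3, 0] = 1.0
        expected[3:, 1] = 1.0
        np.testing.assert_allclose(truth.ancestry, expected, atol=1e-12)

    def test_strong_mixing_homogenizes_ancestry(self):
        land = _strip_landscape()
        params = SimParams(K=2, L=20, theta=0.2, Ne=200, m=0.25, T=300,
                           n_samples=10, seed=3)
        truth = run_simulation(land, params)
        assert np.ptp(truth.ancestry[:, 0]) < 1e-3

    def test_ancestry_rows_sum_to_one(self, two_pool_dataset):
        truth = two_pool_dataset["truth"]
        occ = truth.occupied
        np.testing.assert_allclose(truth.ancestry[occ].sum(axis=1), 1.0, atol=1e-9)

    def test_frequencies_stay_in_unit_interval(self, two_pool_dataset):
        truth = two_pool_dataset["truth"]
        p = truth.freqs[truth.occupied]
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_impermeable_barrier_preserves_divergence(self):
        """FST across a hard barrier exceeds FST within the sides."""
        nx, ny = 8, 3
        land = LandscapeModel(
            grid_nx=nx, grid_ny=ny,
            barriers=[Barrier((4.0, -1.0), (4.0, ny + 1.0), 0.0)],
            founder_regions=[
                [(ix, iy) for ix in range(4) for iy in range(ny)],
                [(ix, iy) for ix in range(4, nx) for iy in range(ny)],
            ],
        )
        params = SimParams(K=2, L=300, theta=0.2, Ne=100, m=0.1, T=100,
                           n_samples=120, seed=11)
        truth = run_simulation(land, params)
        gm, md, tt = export_dataset(truth, seed=12)
        side = (md.coords()[:, 0] > 4.0).astype(int)
        across = wc_fst(gm.genotypes, side)
        # within one side: split it in half
        left = md.coords()[:, 0] <= 4.0
        sub = gm.genotypes[left]
        half = (md.coords()[left, 0] > 2.0).astype(int)
        within = wc_fst(sub, half)
        assert across > within

    def test_fixation_absorbing_without_migration(self):
        land = LandscapeModel(grid_nx=2, grid_ny=1,
                              founder_regions=[[(0, 0)], [(1, 0)]])
        params = SimParams(K=2, L=100, theta=0.5, Ne=5, m=0.0, T=400,
                           n_samples=4, seed=5)
        truth = run_simulation(land, params)
        fixed = (truth.freqs == 0.0) | (truth.freqs == 1.0)
        assert fixed.mean() > 0.95  # tiny demes fix almost everywhere

    def test_drift_variance_scaling(self):
        """Across isolated demes, Var(p) after T gens ≈ p0(1−p0)(1−(1−1/2Ne)^T)."""
        n_demes = 300
        land = LandscapeModel(
            grid_nx=n_demes, grid_ny=1,
            founder_regions=[[(ix, 0) for ix in range(n_demes)]],
        )
        Ne, T = 40, 25
        params = SimParams(K=1, L=150, theta=0.2, Ne=Ne, m=0.0, T=T,
                           n_samples=4, seed=21)
        truth = run_simulation(land, params)
        p0 = truth.founder_freqs[0]
        expected = p0 * (1 - p0) * (1 - (1 - 1 / (2 * Ne)) ** T)
        observed = truth.freqs.var(axis=0)
        ratio = observed.mean() / expected.mean()
        assert 0.85 < ratio < 1.15

    def test_translocation_event_mixes_pools(self):
        land = LandscapeModel(
            grid_nx=2, grid_ny=1,
            founder_regions=[[(0, 0)], [(1, 0)]],
            translocation_events=[TranslocationEvent(2, (0, 0), (1, 0), 0.5)],
        )
        params = SimParams(K=2, L=50, theta=0.3, Ne=10**6, m=0.0, T=3,
                           n_samples=4, seed=2)
        truth = run_simulation(land, params)
        np.testing.assert_allclose(truth.ancestry[1], [0.5, 0.5], atol=1e-9)

    def test_expansion_colonizes_whole_grid(self):
        land = LandscapeModel(
            grid_nx=8, grid_ny=2,
            founder_regions=[[(0, 0), (0, 1)]],
        )
        params = SimParams(K=1, L=30, theta=0.2, Ne=50, m=0.1, T=15,
                           n_samples=10, seed=6)
        truth = run_simulation(land, params)
        assert truth.occupied.all()

    def test_no_founder_region_rejected(self):
        with pytest.raises(ValueError):
            LandscapeModel(grid_nx=3, grid_ny=3, founder_regions=[])

    def test_k_mismatch_rejected(self):
        land = _strip_landscape()
        params = SimParams(K=3, L=10, theta=0.2, Ne=10, m=0.0, T=1, n_samples=2)
        with pytest.raises(ValueError, match="founder regions"):
            run_simulation(land, params)


class TestBarrierGeometry:
    def test_edge_permeability_multiplies_on_crossing(self):
        land = _strip_landscape(barriers=[Barrier((3.0, -1.0), (3.0, 2.0), 0.25)])
        perms = {(a, b): p for a, b, p in land.edges()}
        assert perms[(2, 3)] == 0.25  # crossing edge
        assert perms[(0, 1)] == 1.0  # interior edge

    def test_two_stacked_barriers_compound(self):
        land = _strip_landscape(
            barriers=[
                Barrier((3.0, -1.0), (3.0, 2.0), 0.5),
                Barrier((3.0, -1.0), (3.0, 2.0), 0.2),
            ]
        )
        perms = {(a, b): p for a, b, p in land.edges()}
        assert perms[(2, 3)] == pytest.approx(0.1)


class TestExport:
    def test_fixed_frequencies_give_homozygous_genotypes(self):
        land = LandscapeModel(grid_nx=1, grid_ny=1, founder_regions=[[(0, 0)]])
        params = SimParams(K=1, L=20, theta=0.2, Ne=10, m=0.0, T=0,
                           n_samples=6, seed=1)
        truth = run_simulation(land, params)
        truth.freqs[:] = 1.0
        gm, md, tt = export_dataset(truth, seed=2)
        assert (gm.genotypes == 2).all()

    def test_zero_jitter_collapses_coordinates(self):
        land = LandscapeModel(grid_nx=1, grid_ny=1, founder_regions=[[(0, 0)]])
        params = SimParams(K=1, L=10, theta=0.2, Ne=10, m=0.0, T=0,
                           n_samples=5, seed=1, jitter_km=0.0)
        truth = run_simulation(land, params)
        gm, md, tt = export_dataset(truth, seed=2)
        assert np.ptp(md.coords(), axis=0).max() == 0.0

    def test_capacity_limit_enforced(self):
        land = LandscapeModel(grid_nx=1, grid_ny=1, founder_regions=[[(0, 0)]])
        params = SimParams(K=1, L=10, theta=0.2, Ne=3, m=0.0, T=0,
                           n_samples=10, seed=1)
        truth = run_simulation(land, params)
        with pytest.raises(ValueError, match="capacity"):
            export_dataset(truth, seed=2)

    def test_translocated_samples_are_genetic_outsiders(self):
        """Displaced genotypes are less similar to coordinate-neighbors than residents."""
        from admixscape.dispersal import prevosti_matrix

        land = LandscapeModel(
            grid_nx=10, grid_ny=1,
            founder_regions=[
                [(ix, 0) for ix in range(5)],
                [(ix, 0) for ix in range(5, 10)],
            ],
        )
        params = SimParams(K=2, L=200, theta=0.4, Ne=100, m=0.05, T=30,
                           n_samples=40, seed=9)
        truth = run_simulation(land, params)
        gm, md, tt = export_dataset(truth, seed=10,
                                    displaced=[((0, 0), (9, 0), 4)])
        dmat = prevosti_matrix(gm)
        coords = md.coords()
        trans = tt["translocated"].to_numpy()

        def mean_nbr_dist(i):
            d_geo = np.linalg.norm(coords - coords[i], axis=1)
            nbrs = np.argsort(d_geo)[1:6]
            return dmat[i, nbrs].mean()

        d_trans = np.mean([mean_nbr_dist(i) for i in np.flatnonzero(trans)])
        d_res = np.mean([mean_nbr_dist(i) for i in np.flatnonzero(~trans)])
        assert d_trans > d_res

    def test_seed_determinism_byte_identical(self, two_pool_dataset):
        land = two_pool_dataset["land"]
        params = two_pool_dataset["params"]
        t1 = run_simulation(land, params)
        t2 = run_simulation(land, params)
        np.testing.assert_array_equal(t1.freqs, t2.freqs)
        g1, m1, tt1 = export_dataset(t1, seed=5)
        g2, m2, tt2 = export_dataset(t2, seed=5)
        np.testing.assert_array_equal(g1.genotypes, g2.genotypes)
        assert m1.table.equals(m2.table)


class TestScenarioConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = """
landscape:
  grid_nx: 6
  grid_ny: 2
  cell_km: 1.0
  barriers:
    - {p1: [3.0, -1.0], p2: [3.0, 3.0], permeability: 0.1}
  founder_regions:
    - [[0, 0], [0, 1]]
    - [[5, 0], [5, 1]]
  translocation_events:
    - {generation: 3, source: [0, 0], target: [5, 0], fraction: 0.2}
params:
  K: 2
  L: 40
  theta: 0.2
  Ne: 30
  m: 0.1
  T: 10
  n_samples: 12
  seed: 4
"""
        path = tmp_path / "scenario.yaml"
        path.write_text(cfg)
        land, params = simdata.load_scenario(str(path))
        truth = run_simulation(land, params)
        assert truth.occupied.all()
        assert land.barriers[0].permeability == 0.1
        assert params.K == 2

    def test_displace_coordinates_moves_by_magnitude(self):
        from .conftest import make_md

        md = make_md(np.zeros((4, 2)))
        mags = np.array([0.0, 1.0, 2.0, 3.0])
        md2 = simdata.displace_coordinates(md, mags, seed=0)
        moved = np.linalg.norm(md2.coords() - md.coords(), axis=1)
        np.testing.assert_allclose(moved, mags, atol=1e-12)
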