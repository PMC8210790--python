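"""Self-contained validation experiments run on simulated study scenarios.

Each function simulates a scenario with the bundled forward model, runs the
relevant pipeline stages exactly as a user would, and returns the summary
quantities a validation study cares about.  The test suite asserts on these
and the acceptance script reports them; both therefore share one definition
of every experiment's conditions.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import pearsonr

from . import admix, clines, dispersal, genio, simdata, surface

__all__ = [
    "k3_admixture_recovery",
    "k3_cv_selection",
    "cline_parameter_recovery",
    "null_outlier_fraction",
    "scenario_transect_classification",
    "edge_robustness",
    "dispersal_experiment",
]


def _k3_dataset(seed: int):
    """Three founder pools on a 12×12 grid with contact-zone admixture."""
    nx = ny = 12
    regions = [
        [(ix, iy) for ix in range(4) for iy in range(ny)],
        [(ix, iy) for ix in range(4, 8) for iy in range(ny)],
        [(ix, iy) for ix in range(8, 12) for iy in range(ny)],
    ]
    land = simdata.LandscapeModel(grid_nx=nx, grid_ny=ny, founder_regions=regions)
    params = simdata.SimParams(K=3, L=500, theta=0.2, Ne=100, m=0.05, T=30,
                               n_samples=150, seed=seed)
    truth = simdata.run_simulation(land, params)
    gm, md, tt = simdata.export_dataset(truth, seed=seed + 1)
    q_true = tt[["q0", "q1", "q2"]].to_numpy()
    return gm, md, q_true


def k3_admixture_recovery(seed: int) -> float:
    """Mean |Q̂ − Q_true| after label alignment on the K=3 scenario."""
    gm, _, q_true = _k3_dataset(seed)
    fit = admix.fit_admixture(gm, 3, seed=seed + 2)
    _, perms = admix.align_replicates([q_true, fit.Q])
    return float(np.abs(fit.Q[:, perms[1]] - q_true).mean())


def k3_cv_selection(seed: int, K_range=range(1, 7), folds: int = 2) -> int:
    """K recommended by masked-entry cross-validation on the K=3 scenario."""
    gm, _, _ = _k3_dataset(seed)
    res = admix.cross_validate_K(gm, K_range, folds=folds, seed=seed + 3,
                                 tol=1e-3, max_iter=200)
    return int(res.recommended_K)


def cline_parameter_recovery(
    seed: int,
    L: int = 300,
    N: int = 60,
    iters: int = 20_000,
    burnin: int = 10_000,
    chains: int = 4,
) -> dict:
    """Correlation between true and fitted (α, β) on cline-model data."""
    rng = np.random.default_rng(seed)
    alpha = rng.uniform(-1, 1, L)
    beta = rng.uniform(-1, 1, L)
    p0 = np.full(L, 0.05)
    p1 = np.full(L, 0.95)
    h_true = np.concatenate(
        [np.zeros(N // 6), np.ones(N // 6), rng.uniform(0, 1, N - 2 * (N // 6))]
    )
    g = clines.simulate_cline_genotypes(h_true, alpha, beta, p0, p1,
                                        seed=seed + 1)
    pf = clines.ParentalFreqs(p0, p1, np.arange(L))
    hi = clines.estimate_hybrid_index(g, pf)
    fit = clines.fit_genomic_clines(g, pf, hi.h, iters=iters, burnin=burnin,
                                    thin=10, chains=chains, seed=seed + 2)
    return {
        "r_alpha": float(pearsonr(fit.alpha_med, alpha)[0]),
        "r_beta": float(pearsonr(fit.beta_med, beta)[0]),
        "accept_rate": fit.accept_rate,
    }


def null_outlier_fraction(
    seed: int, L: int = 200, N: int = 60, iters: int = 6000, burnin: int = 3000
) -> float:
    """Fraction of loci flagged as α-outliers when no locus deviates."""
    rng = np.random.default_rng(seed)
    p0 = np.full(L, 0.05)
    p1 = np.full(L, 0.95)
    h = np.concatenate([np.zeros(8), np.ones(8), rng.uniform(0, 1, N - 16)])
    g = clines.simulate_cline_genotypes(h, np.zeros(L), np.zeros(L), p0, p1,
                                        seed=seed + 1)
    pf = clines.ParentalFreqs(p0, p1, np.arange(L))
    fit = clines.fit_genomic_clines(g, pf, h, iters=iters, burnin=burnin,
                                    thin=10, chains=2, seed=seed + 2)
    clines.designate_outliers(fit, level=0.95)
    return float(fit.alpha_outlier.mean())


def scenario_transect_classification(
    kind: str,
    seed: int,
    iters: int = 3000,
    burnin: int = 1500,
) -> clines.TransectClassification:
    """Full transect pipeline on a barrier or expansion scenario.

    Simulates the landscape, estimates Q by EM, defines the transect from
    the estimated ancestry (probability threshold 0.8), filters loci,
    estimates hybrid indices, fits genomic clines, and classifies the
    transect by its α/β spread ratio.
    """
    if kind == "barrier":
        land, params = simdata.barrier_scenario(seed)
    elif kind == "expansion":
        land, params = simdata.expansion_scenario(seed)
    else:
        raise ValueError("kind must be 'barrier' or 'expansion'")
    truth = simdata.run_simulation(land, params)
    weights = simdata.transect_weights(land)
    gm, md, tt = simdata.export_dataset(truth, seed=seed + 1000,
                                        deme_weights=weights)
    fitq = admix.fit_admixture(gm, 2, seed=seed + 7, tol=1e-3, max_iter=300)
    q_true = tt[["q0", "q1"]].to_numpy()
    q = fitq.Q
    if np.corrcoef(q[:, 1], q_true[:, 1])[0, 1] < 0:
        q = q[:, ::-1]
    ny = land.grid_ny
    tr = surface.extract_transect(
        q, md.coords(), 0, 1,
        ((0.5, ny / 2.0), (land.grid_nx - 0.5, ny / 2.0)),
        half_width=float(ny), q_min=0.8,
    )
    g = gm.genotypes[tr.members]
    ia = np.flatnonzero(np.isin(tr.members, tr.parental_a))
    ib = np.flatnonzero(np.isin(tr.members, tr.parental_b))
    pf = clines.parental_freqs_and_filter(g, ia, ib)
    hi = clines.estimate_hybrid_index(g, pf)
    fit = clines.fit_genomic_clines(g, pf, hi.h, iters=iters, burnin=burnin,
                                    thin=10, chains=2, seed=seed + 5)
    return clines.classify_transect(fit)


def edge_robustness(seed: int, n_cells_long: int = 60) -> dict:
    """Stability of the diversity ridge versus IBD under 10% translocation.

    Runs the surface pipeline twice on one barrier landscape: once with all
    samples resident, once with 10% of them long-distance transfers, and
    measures how far the Simpson's-diversity ridge moves (raster cells)
    against how much the Mantel isolation-by-distance correlation degrades.
    """
    land, params = simdata.barrier_scenario(seed, L=400, n_samples=135)
    truth = simdata.run_simulation(land, params)
    n_trans = 15  # 10% of 150
    half = n_trans // 2
    transfers = (
        [((1, 2), (land.grid_nx - 2, 2), n_trans - half)]
        + [((land.grid_nx - 2, 3), (1, 3), half)]
    )
    base_params = simdata.SimParams(**{**params.__dict__, "n_samples": 150})
    gm0, md0, _ = simdata.export_dataset(truth, base_params, seed=seed + 1)
    gm1, md1, _ = simdata.export_dataset(truth, params, seed=seed + 1,
                                         displaced=transfers)
    spec = surface.RasterSpec.from_points(
        np.array([[0.0, 0.0], [land.grid_nx * land.cell_km,
                               land.grid_ny * land.cell_km]]),
        n_cells_long=n_cells_long,
    )

    def ridge(gm, md):
        fit = admix.fit_admixture(gm, 2, seed=seed + 11, tol=1e-4, max_iter=600)
        surf = surface.build_ancestry_surface(
            fit.Q, md.coords(), raster_spec=spec, method="ok",
            buffer_km=3.0 * land.cell_km,
        )
        return surface.extract_edges(surface.simpson_surface(surf), percentile=90)

    e0 = ridge(gm0, md0)
    e1 = ridge(gm1, md1)
    return {
        "ridge_shift_cells": surface.edge_displacement(e0, e1),
        "mantel_resident": dispersal.ibd_correlation(gm0, md0.coords()),
        "mantel_translocated": dispersal.ibd_correlation(gm1, md1.coords()),
    }


def dispersal_experiment(
    seed: int,
    B: int = 60,
    disp_f: float = 3.5,
    disp_m: float = 7.0,
    bandwidth_frac: float = 0.1,
) -> dict:
    """Geolocation-based dispersal study on the quadrant landscape.

    Residents disperse from their natal deme by sex-specific distances
    (males twice as far); 16 individuals are independent long-distance
    transfers; sampling effort is 8× denser in the west half.  Returns the
    translocation, density and sex-ratio summaries.
    """
    land, params = simdata.dispersal_scenario(seed)
    truth = simdata.run_simulation(land, params)
    centers = land.centers_km()
    half_x = land.grid_nx * land.cell_km / 2.0
    weights = np.where(centers[:, 0] < half_x, 8.0, 1.0)
    transfers = simdata.random_transfers(land, n_events=16, min_km=12.0,
                                         seed=seed + 1)
    gm, md, tt = simdata.export_dataset(truth, seed=seed + 2,
                                        displaced=transfers,
                                        deme_weights=weights)
    panel = genio.select_geolocation_panel(gm, min_maf=0.10, n=400, seed=seed)
    dmat = dispersal.prevosti_matrix(panel)
    iu = np.triu_indices(len(dmat), k=1)
    bandwidth = bandwidth_frac * float(np.median(dmat[iu]))
    is_res = ~tt["translocated"].to_numpy()

    # realized leave-one-out error measured before any dispersal movement
    res0 = dispersal.geolocate_all(panel, md.coords(), md, B=20,
                                   bandwidth=bandwidth, seed=seed + 3)
    gene_x = centers[tt["gene_deme"].to_numpy(), 0]
    dense = res0.loc[is_res & (gene_x < half_x), "dispersal"]
    sparse = res0.loc[is_res & (gene_x >= half_x), "dispersal"]

    # residents then disperse (males twice as far as females)
    rng = np.random.default_rng(seed + 4)
    sex = md.table["sex"].to_numpy()
    mags = np.where(sex == "M", disp_m, disp_f) * rng.lognormal(0, 0.2, len(sex))
    mags[~is_res] = 0.0
    md_disp = simdata.displace_coordinates(md, mags, seed=seed + 5)
    res = dispersal.geolocate_all(panel, md_disp.coords(), md_disp, B=B,
                                  bandwidth=bandwidth, seed=seed + 3)
    res["translocated"] = ~is_res
    resid = res[is_res]
    trans = res[~is_res]
    kept = dispersal.dispersal_distances(resid, error_threshold=10.0)
    tests = dispersal.cohort_tests(kept.assign(age_class="all"))
    mean_m = float(kept.loc[kept["sex"] == "M", "dispersal"].mean())
    mean_f = float(kept.loc[kept["sex"] == "F", "dispersal"].mean())
    return {
        "resident_median_dispersal": float(resid["dispersal"].median()),
        "translocated_median_dispersal": float(trans["dispersal"].median()),
        "loo_error_dense": float(dense.median()),
        "loo_error_sparse": float(sparse.median()),
        "male_female_ratio": mean_m / mean_f,
        "welch_p": float(tests["p"].iloc[0]),
        "n_kept": int(len(kept)),
    }
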