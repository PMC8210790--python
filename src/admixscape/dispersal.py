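"""Genotype-based geolocation and relative dispersal inference.

Each individual's geographic origin is predicted from genotype similarity
to every other sample (leave-one-out): the prediction is the
Prevosti-distance-weighted centroid of the reference coordinates, with
weights exp(−d_P/bandwidth).  Uncertainty comes from bootstrap
pseudo-replicates over the SNP panel; individuals whose bootstrap cloud is
too dispersed (mean distance from its centroid above an error threshold,
10 km by default) are excluded.  Dispersal distance is the Euclidean
distance between the sampling locality and the bootstrap centroid —
lifetime dispersal under the assumption that genotype marks natal origin.
Cohort comparisons (male vs female within age class) use Welch t-tests,
and a Prevosti dissimilarity-to-neighbors profile provides an independent
relatedness-decay view of recent immigration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr, ttest_ind

from .genio import MISSING, GenotypeMatrix, SampleMetadata

__all__ = [
    "GeolocationResult",
    "prevosti_distance",
    "prevosti_matrix",
    "geolocate_loo",
    "geolocate_all",
    "dispersal_distances",
    "dissimilarity_profile",
    "cohort_tests",
    "ibd_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class GeolocationResult:
    """Prediction, bootstrap cloud, and error summary for one individual."""

    index: int
    predicted: np.ndarray  # (2,) full-panel prediction
    bootstrap: np.ndarray  # (B, 2) pseudo-replicate predictions
    centroid: np.ndarray  # (2,) bootstrap centroid
    error: float  # mean distance of bootstrap predictions from centroid (km)
    dispersal: float  # distance from sampling locality to centroid (km)


def _geno_array(G) -> np.ndarray:
    if isinstance(G, GenotypeMatrix):
        return G.genotypes
    return np.asarray(G)


def prevosti_distance(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Prevosti dissimilarity between two diploid genotype vectors.

    d = mean over loci observed in both of |g_a − g_b| / 2, in [0, 1];
    0 iff the shared loci are identical.
    """
    g_a = np.asarray(g_a)
    g_b = np.asarray(g_b)
    shared = (g_a != MISSING) & (g_b != MISSING)
    if not shared.any():
        raise ValueError("no loci observed in both individuals")
    return float(np.abs(g_a[shared] - g_b[shared]).mean() / 2.0)


def prevosti_matrix(G) -> np.ndarray:
    """Pairwise Prevosti distances (N×N, zero diagonal)."""
    g = _geno_array(G)
    n = g.shape[0]
    obs = g != MISSING
    gf = np.where(obs, g, 0).astype(np.float64)
    out = np.zeros((n, n))
    for i in range(n):
        both = obs[i] & obs
        diff = np.abs(gf[i] - gf) * both
        cnt = both.sum(axis=1)
        if (cnt == 0).any():
            bad = int(np.flatnonzero(cnt == 0)[0])
            if bad != i:
                raise ValueError(f"samples {i} and {bad} share no observed loci")
        out[i] = diff.sum(axis=1) / (2.0 * np.maximum(cnt, 1))
        out[i, i] = 0.0
    return out


def _weighted_centroid(d: np.ndarray, coords: np.ndarray,
                       bandwidth: float) -> np.ndarray:
    w = np.exp(-d / bandwidth)
    s = w.sum()
    if s <= 0 or not np.isfinite(s):
        w = (d == d.min()).astype(float)
        s = w.sum()
    return (w @ coords) / s


def geolocate_loo(
    G_panel,
    coords: np.ndarray,
    focal: int,
    B: int = 100,
    bandwidth: float | None = None,
    seed: int | None = None,
    _dmat: np.ndarray | None = None,
) -> GeolocationResult:
    """Leave-one-out geolocation of one individual with SNP-bootstrap error.

    References are all other samples; the point prediction is their
    coordinate centroid weighted by exp(−d_P/bandwidth) where d_P is the
    Prevosti distance on the panel.  The default bandwidth is half the
    median pairwise panel distance.  Each of the ``B`` bootstrap
    pseudo-replicates resamples panel SNPs with replacement and re-predicts,
    giving the bootstrap centroid, the mean bootstrap-to-centroid distance
    ``error`` and the locality-to-centroid ``dispersal``.
    """
    g = _geno_array(G_panel)
    coords = np.asarray(coords, dtype=float)
    n, L = g.shape
    if not 0 <= focal < n:
        raise ValueError(f"focal index {focal} not in panel of {n} samples")
    if n - 1 < 10:
        raise ValueError("need at least 10 reference samples")
    dmat = prevosti_matrix(g) if _dmat is None else _dmat
    if bandwidth is None:
        bandwidth = 0.5 * float(np.median(dmat[np.triu_indices(n, k=1)]))
    bandwidth = max(bandwidth, 1e-6)
    refs = np.array([i for i in range(n) if i != focal])
    ref_coords = coords[refs]
    pred = _weighted_centroid(dmat[focal, refs], ref_coords, bandwidth)

    obs_f = g[focal] != MISSING
    obs_r = g[refs] != MISSING
    both = obs_r & obs_f[None, :]
    absdiff = np.abs(
        np.where(both, g[refs].astype(float) - g[focal].astype(float), 0.0)
    ) / 2.0
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(L, np.full(L, 1.0 / L), size=B).T  # (L, B)
    num = absdiff @ counts  # (R, B)
    den = both.astype(float) @ counts
    boot = np.empty((B, 2))
    for b in range(B):
        with np.errstate(invalid="ignore", divide="ignore"):
            d_b = np.where(den[:, b] > 0, num[:, b] / np.maximum(den[:, b], 1), 1.0)
        boot[b] = _weighted_centroid(d_b, ref_coords, bandwidth)
    centroid = boot.mean(axis=0)
    error = float(np.linalg.norm(boot - centroid, axis=1).mean())
    dispersal = float(np.linalg.norm(coords[focal] - centroid))
    return GeolocationResult(focal, pred, boot, centroid, error, dispersal)


def geolocate_all(
    G_panel,
    coords: np.ndarray,
    metadata: SampleMetadata | None = None,
    B: int = 100,
    bandwidth: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Leave-one-out geolocation of every sample; one row per individual.

    Columns: id (when metadata given), pred_x/pred_y, cent_x/cent_y,
    error (km), dispersal (km), plus sex and age_class from the metadata.
    """
    g = _geno_array(G_panel)
    coords = np.asarray(coords, dtype=float)
    n = g.shape[0]
    dmat = prevosti_matrix(g)
    if bandwidth is None:
        bandwidth = 0.5 * float(np.median(dmat[np.triu_indices(n, k=1)]))
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        res = geolocate_loo(
            g, coords, i, B=B, bandwidth=bandwidth,
            seed=int(rng.integers(2**31)), _dmat=dmat,
        )
        rows.append(
            {
                "index": i,
                "pred_x": res.predicted[0],
                "pred_y": res.predicted[1],
                "cent_x": res.centroid[0],
                "cent_y": res.centroid[1],
                "error": res.error,
                "dispersal": res.dispersal,
            }
        )
    table = pd.DataFrame(rows)
    if metadata is not None:
        meta = metadata.table.reset_index(drop=True)
        table.insert(0, "id", meta["id"])
        table["sex"] = meta["sex"].to_numpy()
        table["age_class"] = meta["age_class"].to_numpy()
    return table


def dispersal_distances(
    results: pd.DataFrame, error_threshold: float = 10.0
) -> pd.DataFrame:
    """Keep individuals whose bootstrap-centroid error is within threshold.

    A conservative error cut (10 km by default) restricts dispersal
    estimates to confidently geolocated individuals.
    """
    kept = results[results["error"] <= error_threshold].reset_index(drop=True)
    logger.info(
        "dispersal_distances: %d of %d pass the %.0f km error filter",
        len(kept), len(results), error_threshold,
    )
    return kept


def dissimilarity_profile(
    G,
    coords: np.ndarray,
    metadata: SampleMetadata,
    radius: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean Prevosti dissimilarity to neighbors within ``radius`` km.

    Focal individuals without any neighbor in the radius are excluded
    (sparsely sampled regions make relatedness-vs-distance unreliable).
    Returns (per-individual profile, age×sex cohort summary).
    """
    g = _geno_array(G)
    coords = np.asarray(coords, dtype=float)
    dmat = prevosti_matrix(g)
    tree = cKDTree(coords)
    meta = metadata.table.reset_index(drop=True)
    rows = []
    for i in range(len(coords)):
        nbrs = [j for j in tree.query_ball_point(coords[i], radius) if j != i]
        if not nbrs:
            continue
        rows.append(
            {
                "id": meta.loc[i, "id"],
                "n_neighbors": len(nbrs),
                "mean_dissimilarity": float(dmat[i, nbrs].mean()),
                "sex": meta.loc[i, "sex"],
                "age_class": meta.loc[i, "age_class"],
            }
        )
    profile = pd.DataFrame(rows)
    if profile.empty:
        return profile, pd.DataFrame()
    cohorts = (
        profile.groupby(["age_class", "sex"], observed=True)["mean_dissimilarity"]
        .agg(["count", "mean"])
        .reset_index()
        .rename(columns={"count": "n", "mean": "mean_dissimilarity"})
    )
    return profile, cohorts


def cohort_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Welch two-sample t-tests of male vs female dispersal within age class.

    Returns one row per age class: group sizes, means, t and p (NaN with a
    reason when a group has fewer than 2 individuals).
    """
    rows = []
    for age, grp in table.groupby("age_class", observed=True):
        d_m = grp.loc[grp["sex"] == "M", "dispersal"].to_numpy(dtype=float)
        d_f = grp.loc[grp["sex"] == "F", "dispersal"].to_numpy(dtype=float)
        row = {
            "age_class": age,
            "n_M": len(d_m),
            "n_F": len(d_f),
            "mean_M": d_m.mean() if len(d_m) else np.nan,
            "mean_F": d_f.mean() if len(d_f) else np.nan,
            "t": np.nan,
            "p": np.nan,
            "note": "",
        }
        if len(d_m) < 2 or len(d_f) < 2:
            row["note"] = "group n < 2; test skipped"
        elif np.ptp(d_m) == 0 and np.ptp(d_f) == 0 and d_m.mean() == d_f.mean():
            row["t"], row["p"] = 0.0, 1.0
        else:
            t, p = ttest_ind(d_m, d_f, equal_var=False)
            row["t"], row["p"] = float(t), float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def ibd_correlation(G, coords: np.ndarray) -> float:
    """Mantel-type isolation-by-distance statistic.

    Pearson correlation between the condensed Prevosti genetic distances and
    Euclidean geographic distances; translocation decouples genotype from
    location and drives this toward zero.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    iu = np.triu_indices(n, k=1)
    gd = prevosti_matrix(G)[iu]
    geo = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)[iu]
    return float(pearsonr(gd, geo)[0])
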