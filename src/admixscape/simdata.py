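"""Forward stepping-stone simulator with barriers, expansion, and translocation.

Simulates K founder gene pools diverged under a Balding–Nichols model and
propagated forward on a 2-D grid of demes exchanging migrants with their
four neighbors (Wright–Fisher drift within demes).  Three landscape
features relevant to heavily managed wildlife are modeled:

* **linear barriers** (rivers, highways) that multiply migration rates on
  crossing edges by a permeability in [0, 1];
* **refugial re-expansion**: initially empty demes are colonized from
  occupied neighbors with a small founder size, producing allele-surfing
  drift at the expansion front;
* **translocation events**: scheduled admixture pulses that replace a
  fraction of a target deme's gene pool with a distant source's, emulating
  stock-replenishment programs.

Simulation is at the allele-frequency level (loci independent, no LD);
individuals are instantiated only at sampling time, which is all the
downstream genotype-based analyses require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString

from .genio import GenotypeMatrix, SampleMetadata

__all__ = [
    "Barrier",
    "TranslocationEvent",
    "LandscapeModel",
    "SimParams",
    "SimTruth",
    "simulate_founder_freqs",
    "run_simulation",
    "export_dataset",
    "barrier_scenario",
    "expansion_scenario",
    "dispersal_scenario",
    "random_transfers",
    "displace_coordinates",
    "transect_weights",
    "load_scenario",
]

Deme = tuple[int, int]  # (ix, iy) grid indices


@dataclass
class Barrier:
    """Line segment in grid coordinates with a migration permeability."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    permeability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.permeability <= 1.0:
            raise ValueError("permeability must be in [0, 1]")


@dataclass
class TranslocationEvent:
    """At ``generation``, mix fraction ``c`` of the source pool into the target."""

    generation: int
    source: Deme
    target: Deme
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("translocation fraction must be in [0, 1]")


@dataclass
class LandscapeModel:
    """Grid geometry, barriers, founder regions, occupancy and scheduled events.

    Deme centers sit at ``((ix + 0.5), (iy + 0.5))`` in grid coordinates and
    at ``cell_km`` times that in km.  ``founder_regions[k]`` lists the demes
    seeded from gene pool ``k``.  Initial occupancy is the union of founder
    regions, optionally restricted to ``occupied0`` (a subset of founder
    demes) for refugial-expansion scenarios; every other deme starts empty
    and is colonized from occupied neighbors as the simulation runs.
    """

    grid_nx: int
    grid_ny: int
    cell_km: float = 1.0
    barriers: list[Barrier] = field(default_factory=list)
    founder_regions: list[list[Deme]] = field(default_factory=list)
    translocation_events: list[TranslocationEvent] = field(default_factory=list)
    occupied0: list[Deme] | None = None  # None: founder demes only

    def __post_init__(self) -> None:
        if self.grid_nx < 1 or self.grid_ny < 1 or self.cell_km <= 0:
            raise ValueError("invalid grid geometry")
        seen: set[Deme] = set()
        for region in self.founder_regions:
            overlap = seen & set(region)
            if overlap:
                raise ValueError(f"founder regions overlap at {sorted(overlap)}")
            seen |= set(region)
        if not seen:
            raise ValueError("at least one founder region is required")
        gens = [e.generation for e in self.translocation_events]
        if gens != sorted(gens):
            raise ValueError("translocation events must be sorted by generation")
        for d in seen:
            self._check_deme(d)

    def _check_deme(self, d: Deme) -> None:
        ix, iy = d
        if not (0 <= ix < self.grid_nx and 0 <= iy < self.grid_ny):
            raise ValueError(f"deme {d} outside the grid")

    @property
    def n_demes(self) -> int:
        return self.grid_nx * self.grid_ny

    def flat(self, d: Deme) -> int:
        return d[1] * self.grid_nx + d[0]

    def centers_km(self) -> np.ndarray:
        """(n_demes, 2) deme center coordinates in km, flat order."""
        iy, ix = np.divmod(np.arange(self.n_demes), self.grid_nx)
        return np.column_stack(((ix + 0.5) * self.cell_km, (iy + 0.5) * self.cell_km))

    def edges(self) -> list[tuple[int, int, float]]:
        """Adjacent deme pairs (flat indices, each direction once) with permeability.

        An edge's permeability is the product over barriers whose segment
        intersects the center-to-center segment of the edge.
        """
        segs = [
            (LineString([b.p1, b.p2]), b.permeability) for b in self.barriers
        ]
        out: list[tuple[int, int, float]] = []
        for iy in range(self.grid_ny):
            for ix in range(self.grid_nx):
                a = (ix, iy)
                for b in ((ix + 1, iy), (ix, iy + 1)):
                    if b[0] >= self.grid_nx or b[1] >= self.grid_ny:
                        continue
                    edge = LineString(
                        [(a[0] + 0.5, a[1] + 0.5), (b[0] + 0.5, b[1] + 0.5)]
                    )
                    perm = 1.0
                    for seg, p in segs:
                        if edge.intersects(seg):
                            perm *= p
                    fa, fb = self.flat(a), self.flat(b)
                    out.append((fa, fb, perm))
                    out.append((fb, fa, perm))
        return out


@dataclass
class SimParams:
    """Demographic and genetic parameters of one simulation."""

    K: int
    L: int
    theta: float = 0.15
    Ne: int = 100
    m: float = 0.05
    T: int = 50
    n_samples: int = 200
    jitter_km: float = 0.4
    seed: int = 0
    Ne_found: int | None = None  # colonization founder size; default Ne // 10

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0, 1)")
        if not 0.0 <= self.m <= 0.25:
            raise ValueError("m must be in [0, 0.25] (4-neighbor stepping stone)")
        if self.Ne < 1 or self.K < 1 or self.L < 1 or self.T < 0:
            raise ValueError("K, L, Ne must be positive and T non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.Ne_found is None:
            self.Ne_found = max(1, self.Ne // 10)


@dataclass
class SimTruth:
    """Final state of a simulation plus everything tests need as ground truth."""

    landscape: LandscapeModel
    params: SimParams
    founder_freqs: np.ndarray  # (K, L)
    freqs: np.ndarray  # (n_demes, L) allele frequencies, NaN where empty
    ancestry: np.ndarray  # (n_demes, K) founder-ancestry proportions
    occupied: np.ndarray  # (n_demes,) bool


def simulate_founder_freqs(
    K: int, L: int, theta: float, seed: int | None = None
) -> np.ndarray:
    """Balding–Nichols founder pools: K×L allele frequencies.

    Ancestral frequencies are Uniform(0.05, 0.95); each pool's frequency is
    Beta(p(1−θ)/θ, (1−p)(1−θ)/θ), giving between-pool variance θ·p(1−p),
    i.e. θ plays the role of FST among the founder pools.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must be in (0, 1)")
    if K < 1 or L < 1:
        raise ValueError("K and L must be positive")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=L)
    scale = (1.0 - theta) / theta
    f = rng.beta(p * scale, (1.0 - p) * scale, size=(K, L))
    return np.clip(f, 1e-12, 1.0 - 1e-12)


def _migration_matrix(
    landscape: LandscapeModel, m: float, occupied: np.ndarray
) -> np.ndarray:
    """Row-stochastic deme×deme matrix; migrants only flow between occupied demes."""
    D = landscape.n_demes
    M = np.zeros((D, D))
    for a, b, perm in landscape.edges():
        if occupied[a] and occupied[b]:
            M[a, b] = m * perm
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))
    if np.any(np.diag(M) < -1e-12):
        raise ValueError("total emigration exceeds 1; reduce m")
    return M


def run_simulation(landscape: LandscapeModel, params: SimParams) -> SimTruth:
    """Run the forward simulation and return the final state with ground truth.

    Per generation the update order is fixed: migration → drift →
    translocation → colonization.  Allele frequencies take binomial drift
    noise (2·Ne draws per deme per locus); ancestry proportions follow the
    identical linear recursion without noise, so they stay on the simplex
    to machine precision and provide a deterministic truth for admixture
    recovery tests.
    """
    if params.K != len(landscape.founder_regions):
        raise ValueError(
            f"params.K={params.K} but landscape has "
            f"{len(landscape.founder_regions)} founder regions"
        )
    rng = np.random.default_rng(params.seed)
    f = simulate_founder_freqs(params.K, params.L, params.theta, rng.integers(2**31))
    D = landscape.n_demes
    p = np.full((D, params.L), np.nan)
    a = np.zeros((D, params.K))
    occupied = np.zeros(D, dtype=bool)
    for k, region in enumerate(landscape.founder_regions):
        for d in region:
            i = landscape.flat(d)
            p[i] = f[k]
            a[i, k] = 1.0
            occupied[i] = True
    if landscape.occupied0 is not None:
        keep = np.zeros(D, dtype=bool)
        for d in landscape.occupied0:
            i = landscape.flat(d)
            if not occupied[i]:
                raise ValueError(
                    f"occupied0 deme {d} has no founder region to draw genes from"
                )
            keep[i] = True
        p[~keep] = np.nan
        a[~keep] = 0.0
        occupied = keep

    events = list(landscape.translocation_events)
    # static edge weights for colonization (occupancy-independent part)
    edge_w: dict[int, list[tuple[int, float]]] = {i: [] for i in range(D)}
    for src, dst, perm in landscape.edges():
        edge_w[dst].append((src, params.m * perm))

    M = _migration_matrix(landscape, params.m, occupied)
    occ_dirty = False
    for t in range(params.T):
        if occ_dirty:
            M = _migration_matrix(landscape, params.m, occupied)
            occ_dirty = False
        # migration (deterministic expectation)
        p[occupied] = (M @ np.nan_to_num(p))[occupied]
        a = M @ a
        # drift
        occ_idx = np.flatnonzero(occupied)
        counts = rng.binomial(2 * params.Ne, np.clip(p[occ_idx], 0.0, 1.0))
        p[occ_idx] = counts / (2.0 * params.Ne)
        # translocation
        while events and events[0].generation == t:
            ev = events.pop(0)
            s, g = landscape.flat(ev.source), landscape.flat(ev.target)
            if not (occupied[s] and occupied[g]):
                raise ValueError(f"translocation at t={t} touches an empty deme")
            c = ev.fraction
            p[g] = (1.0 - c) * p[g] + c * p[s]
            a[g] = (1.0 - c) * a[g] + c * a[s]
        # colonization of empty demes with occupied neighbors
        if not occupied.all():
            new_p, new_a, new_idx = [], [], []
            for d in np.flatnonzero(~occupied):
                nbrs = [(s, w) for s, w in edge_w[d] if occupied[s] and w > 0]
                if not nbrs:
                    continue
                w = np.array([wt for _, wt in nbrs])
                w = w / w.sum()
                src = np.array([s for s, _ in nbrs])
                fp = w @ p[src]
                fa = w @ a[src]
                fp = rng.binomial(
                    2 * params.Ne_found, np.clip(fp, 0.0, 1.0)
                ) / (2.0 * params.Ne_found)
                new_idx.append(d)
                new_p.append(fp)
                new_a.append(fa)
            if new_idx:
                idx = np.array(new_idx)
                p[idx] = np.array(new_p)
                a[idx] = np.array(new_a)
                occupied[idx] = True
                occ_dirty = True

    if not np.allclose(a[occupied].sum(axis=1), 1.0, atol=1e-9):
        raise AssertionError("ancestry simplex violated")  # pragma: no cover
    return SimTruth(landscape, params, f, p, a, occupied)


def export_dataset(
    truth: SimTruth,
    params: SimParams | None = None,
    seed: int | None = None,
    displaced: list[tuple[Deme, Deme, int]] | None = None,
    deme_weights: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, SampleMetadata, pd.DataFrame]:
    """Draw individuals from the final state and package them for the pipeline.

    Samples are assigned to occupied demes uniformly at random; genotypes are
    Binomial(2, p_deme) per locus and coordinates are the deme center plus
    uniform jitter.  ``displaced`` entries ``((sx, sy), (tx, ty), n)`` add
    ``n`` translocated individuals whose *genotypes* come from the source
    deme while their *coordinates* come from the target deme — the defining
    decoupling of human-moved animals.  ``deme_weights`` (length n_demes)
    biases sampling effort spatially, e.g. toward a study transect.
    Returns the genotype matrix, the metadata table, and a per-sample truth
    table (true deme, true ancestry, translocated flag).
    """
    params = truth.params if params is None else params
    rng = np.random.default_rng(params.seed if seed is None else seed)
    land = truth.landscape
    occ = np.flatnonzero(truth.occupied)
    capacity = len(occ) * params.Ne
    n_displaced = sum(n for _, _, n in displaced) if displaced else 0
    if params.n_samples + n_displaced > capacity:
        raise ValueError(
            f"requested {params.n_samples + n_displaced} samples exceeds "
            f"capacity {capacity} ({len(occ)} occupied demes × Ne)"
        )

    if deme_weights is not None:
        w = np.asarray(deme_weights, dtype=float)[occ]
        if w.sum() <= 0:
            raise ValueError("deme_weights vanish on every occupied deme")
        probs = w / w.sum()
    else:
        probs = None
    gene_demes = list(rng.choice(occ, size=params.n_samples, p=probs))
    coord_demes = list(gene_demes)
    translocated = [False] * params.n_samples
    if displaced:
        for src, tgt, n in displaced:
            s, g = land.flat(src), land.flat(tgt)
            if not (truth.occupied[s] and truth.occupied[g]):
                raise ValueError("displacement touches an empty deme")
            gene_demes += [s] * n
            coord_demes += [g] * n
            translocated += [True] * n

    n_total = len(gene_demes)
    gene_demes = np.array(gene_demes)
    coord_demes = np.array(coord_demes)
    genotypes = rng.binomial(2, truth.freqs[gene_demes]).astype(np.int8)
    centers = land.centers_km()[coord_demes]
    jitter = rng.uniform(-params.jitter_km, params.jitter_km, size=(n_total, 2))
    coords = centers + jitter

    ids = [f"S{i:04d}" for i in range(n_total)]
    sex = rng.choice(["M", "F"], size=n_total)
    age = rng.choice(["Y0-1", "Y1-1.5", "Y2-2.5", "Y3-4.5", "Y5+"], size=n_total)
    loci = pd.DataFrame(
        {
            "tag": [f"loc{j}" for j in range(params.L)],
            "pos": np.ones(params.L, dtype=int),
            "ref": "A",
            "alt": "T",
        }
    )
    gm = GenotypeMatrix(genotypes, ids, loci)
    md = SampleMetadata(
        pd.DataFrame(
            {
                "id": ids,
                "x": coords[:, 0],
                "y": coords[:, 1],
                "sex": sex,
                "age_class": age,
                "status": "sim",
            }
        )
    )
    truth_table = pd.DataFrame(
        {
            "id": ids,
            "gene_deme": gene_demes,
            "coord_deme": coord_demes,
            "translocated": translocated,
        }
    )
    for k in range(params.K):
        truth_table[f"q{k}"] = truth.ancestry[gene_demes, k]
    return gm, md, truth_table


# ---------------------------------------------------------------------------
# Named study scenarios
#
# These are the package's reference conditions for validating the analysis
# stages; tests and the acceptance script share them.  Parameter choices are
# discussed in the methods note.


def barrier_scenario(
    seed: int,
    nx: int = 20,
    ny: int = 5,
    permeability: float = 0.2,
    Ne: int = 30,
    m: float = 0.15,
    T: int = 200,
    L: int = 600,
    theta: float = 0.5,
    n_samples: int = 150,
) -> tuple[LandscapeModel, SimParams]:
    """Two diverged pools abutting a semipermeable river bisecting the grid.

    Restricted crossing plus small-Ne drift at the contact maintains a
    narrow admixture zone pinned at the barrier — the landscape predicted
    to produce locus-wise variation in cline steepness (β).
    """
    land = LandscapeModel(
        grid_nx=nx,
        grid_ny=ny,
        barriers=[Barrier((nx / 2, -1.0), (nx / 2, ny + 1.0), permeability)],
        founder_regions=[
            [(ix, iy) for ix in range(nx // 2) for iy in range(ny)],
            [(ix, iy) for ix in range(nx // 2, nx) for iy in range(ny)],
        ],
    )
    params = SimParams(K=2, L=L, theta=theta, Ne=Ne, m=m, T=T,
                       n_samples=n_samples, seed=seed)
    return land, params


def expansion_scenario(
    seed: int,
    nx: int = 20,
    ny: int = 5,
    Ne: int = 200,
    Ne_found: int = 2,
    m: float = 0.1,
    T: int = 45,
    L: int = 600,
    theta: float = 0.5,
    n_samples: int = 150,
) -> tuple[LandscapeModel, SimParams]:
    """Two refugia at opposite grid edges re-expanding until secondary contact.

    Tiny colonization founder size produces allele surfing at the fronts —
    drift-driven directional deviations (α) without a physical barrier.
    Sampled shortly after the fronts meet, before migration erases the
    surfing signal.
    """
    land = LandscapeModel(
        grid_nx=nx,
        grid_ny=ny,
        founder_regions=[
            [(0, iy) for iy in range(ny)],
            [(nx - 1, iy) for iy in range(ny)],
        ],
    )
    params = SimParams(K=2, L=L, theta=theta, Ne=Ne, m=m, T=T,
                       n_samples=n_samples, seed=seed, Ne_found=Ne_found)
    return land, params


def dispersal_scenario(
    seed: int,
    n: int = 12,
    Ne: int = 30,
    m: float = 0.05,
    T: int = 150,
    L: int = 600,
    theta: float = 0.3,
    n_samples: int = 160,
) -> tuple[LandscapeModel, SimParams]:
    """Four quadrant gene pools with strong deme-level differentiation.

    Long drift at small deme size over a quadrant mosaic gives every deme a
    recognizable multilocus signature, the regime in which genotype-based
    geolocation is informative at the deme scale.
    """
    half = n // 2
    regions = [
        [(ix, iy) for ix in range(half) for iy in range(half)],
        [(ix, iy) for ix in range(half, n) for iy in range(half)],
        [(ix, iy) for ix in range(half) for iy in range(half, n)],
        [(ix, iy) for ix in range(half, n) for iy in range(half, n)],
    ]
    land = LandscapeModel(grid_nx=n, grid_ny=n, founder_regions=regions)
    params = SimParams(K=4, L=L, theta=theta, Ne=Ne, m=m, T=T,
                       n_samples=n_samples, seed=seed)
    return land, params


def random_transfers(
    land: LandscapeModel,
    n_events: int,
    min_km: float,
    seed: int,
) -> list[tuple[Deme, Deme, int]]:
    """Independent single-individual long-distance transfers.

    Each event moves one individual between uniformly drawn demes at least
    ``min_km`` apart — the roadkill-transport / stocking-truck pattern that
    decouples genotype from sampling coordinates.
    """
    rng = np.random.default_rng(seed)
    events: list[tuple[Deme, Deme, int]] = []
    for _ in range(n_events):
        while True:
            s = (int(rng.integers(land.grid_nx)), int(rng.integers(land.grid_ny)))
            g = (int(rng.integers(land.grid_nx)), int(rng.integers(land.grid_ny)))
            d = np.hypot(s[0] - g[0], s[1] - g[1]) * land.cell_km
            if d >= min_km:
                events.append((s, g, 1))
                break
    return events


def displace_coordinates(
    md: SampleMetadata, magnitudes_km: np.ndarray, seed: int | None = None
) -> SampleMetadata:
    """Move each sample's coordinates by its magnitude in a random direction.

    Emulates post-natal dispersal: the genotype stays put (it marks natal
    origin) while the sampling locality moves.  Magnitudes of zero leave a
    sample in place.
    """
    rng = np.random.default_rng(seed)
    mags = np.asarray(magnitudes_km, dtype=float)
    table = md.table.copy()
    if len(mags) != len(table):
        raise ValueError("one displacement magnitude per sample required")
    ang = rng.uniform(0.0, 2.0 * np.pi, len(table))
    table["x"] = table["x"].to_numpy() + mags * np.cos(ang)
    table["y"] = table["y"].to_numpy() + mags * np.sin(ang)
    return SampleMetadata(table)


def transect_weights(land: LandscapeModel, x_center: float | None = None,
                     scale: float = 3.0, floor: float = 0.2) -> np.ndarray:
    """Sampling-effort weights concentrated around a north–south transect line.

    Emulates a transect study design: effort decays exponentially with
    distance (in deme units) from ``x_center`` (grid midline by default),
    with a floor so the grid ends are still represented.
    """
    x_center = land.grid_nx / 2 if x_center is None else x_center
    centers = land.centers_km()
    xs = centers[:, 0] / land.cell_km
    return floor + np.exp(-np.abs(xs - x_center) / scale)


def load_scenario(path: str) -> tuple[LandscapeModel, SimParams]:
    """Load a YAML scenario file into a landscape and parameter set."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    lcfg = cfg["landscape"]
    land = LandscapeModel(
        grid_nx=lcfg["grid_nx"],
        grid_ny=lcfg["grid_ny"],
        cell_km=lcfg.get("cell_km", 1.0),
        barriers=[Barrier(tuple(b["p1"]), tuple(b["p2"]), b.get("permeability", 0.0))
                  for b in lcfg.get("barriers", [])],
        founder_regions=[[tuple(d) for d in region]
                         for region in lcfg["founder_regions"]],
        translocation_events=[
            TranslocationEvent(e["generation"], tuple(e["source"]),
                               tuple(e["target"]), e["fraction"])
            for e in lcfg.get("translocation_events", [])
        ],
        occupied0=[tuple(d) for d in lcfg["occupied0"]]
        if lcfg.get("occupied0") is not None
        else None,
    )
    params = SimParams(**cfg["params"])
    return land, params
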