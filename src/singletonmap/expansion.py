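"""Spatially explicit demic range-expansion simulation.

The simulator follows the classical two-phase design: a deterministic
forward-in-time demographic phase on a lattice of demes (logistic growth to a
carrying capacity ``C``, a fraction ``m`` of each deme emigrating to its
habitable von Neumann neighbours each generation), followed by a stochastic
backward-in-time coalescent conditioned on the recorded densities and migrant
flows.  Mutations are dropped on the resulting genealogies under the
infinite-sites model, one independent genealogy per locus.

Demography is real-valued and deterministic; all randomness lives in the
backward coalescent and the mutation process, which makes forward histories
reproducible and cheap to re-run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .genealogy import Genealogy
from .haplotypes import HaplotypeMatrix, concatenate
from .singletons import filter_monomorphic  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)

__all__ = [
    "HABITAT_CODES",
    "DemeGrid",
    "ExpansionScenario",
    "OccupancyHistory",
    "SpatialSample",
    "make_habitat_map",
    "run_forward_demography",
    "draw_sampling_design",
    "sample_backward_coalescent",
    "filter_monomorphic",
]

#: Habitat class codes used in habitat rasters.
HABITAT_CODES = {
    "sea": 0,
    "other": 1,
    "semi-desert": 2,
    "extreme-desert": 3,
    "rain-forest": 4,
}

#: Carrying capacity per habitat class for each named scenario kind.
_CAPACITY_SCHEMES = {
    "homogeneous": {"other": 100.0, "semi-desert": 100.0,
                    "extreme-desert": 100.0, "rain-forest": 100.0},
    "vegetation": {"other": 100.0, "semi-desert": 60.0,
                   "extreme-desert": 30.0, "rain-forest": 30.0},
    "abc-vegetation": {"other": 100.0, "semi-desert": 100.0,
                       "extreme-desert": 20.0, "rain-forest": 10.0},
}

# von Neumann neighbourhood; directions index the flow arrays
_DIRS = ((-1, 0), (1, 0), (0, 1), (0, -1))  # N, S, E, W


@dataclass
class DemeGrid:
    """Georeferenced lattice of demes (row 0 = northernmost row).

    ``capacity`` holds the per-deme carrying capacity (0 = sea /
    uninhabitable); ``habitat`` the habitat class codes of
    :data:`HABITAT_CODES`.  Georeferencing follows the ESRI ASCII
    convention: ``xllcorner``/``yllcorner`` locate the south-west corner,
    cell centres are offset by half a ``cellsize``.
    """

    capacity: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    habitat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.capacity = np.asarray(self.capacity, dtype=float)
        if self.capacity.ndim != 2:
            raise ValueError("capacity must be 2-D")
        if np.any(self.capacity < 0):
            raise ValueError("carrying capacities must be >= 0")
        if self.habitat is None:
            self.habitat = np.where(self.capacity > 0, 1, 0).astype(np.int8)
        else:
            self.habitat = np.asarray(self.habitat, dtype=np.int8)
            if self.habitat.shape != self.capacity.shape:
                raise ValueError("habitat and capacity shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.capacity.shape

    @property
    def n_cells(self) -> int:
        return self.capacity.size

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        nrows = self.shape[0]
        lon = self.xllcorner + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.yllcorner + (nrows - 1 - np.asarray(row) + 0.5) * self.cellsize
        return lon, lat

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        nrows, ncols = self.shape
        col = int(math.floor((lon - self.xllcorner) / self.cellsize))
        row = nrows - 1 - int(math.floor((lat - self.yllcorner) / self.cellsize))
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValueError(f"point ({lon}, {lat}) outside the grid")
        return row, col

    def is_habitable(self, row: int, col: int) -> bool:
        return self.capacity[row, col] > 0

    def nearest_habitable(self, lon: float, lat: float) -> tuple[int, int]:
        rows, cols = np.nonzero(self.capacity > 0)
        if rows.size == 0:
            raise ValueError("grid has no habitable cell")
        clon, clat = self.cell_center(rows, cols)
        d2 = (clon - lon) ** 2 + (clat - lat) ** 2
        k = int(np.argmin(d2))
        return int(rows[k]), int(cols[k])


def make_habitat_map(kind: str, base_grid: DemeGrid) -> DemeGrid:
    """Assign carrying capacities to a land/sea grid by habitat class.

    ``kind`` is one of ``homogeneous`` (C = 100 on all land),
    ``vegetation`` (C = 60 in tropical semi-desert, 30 in extreme desert
    and rain forest, 100 elsewhere) or ``abc-vegetation`` (C = 100
    semi-desert, 20 extreme desert, 10 rain forest).
    """
    if kind not in _CAPACITY_SCHEMES:
        raise ValueError(
            f"unknown habitat scheme {kind!r}; choose from "
            f"{sorted(_CAPACITY_SCHEMES)}"
        )
    scheme = _CAPACITY_SCHEMES[kind]
    hab = base_grid.habitat
    known = set(HABITAT_CODES.values())
    if not set(np.unique(hab)).issubset(known):
        raise ValueError("habitat grid contains unknown class codes")
    if not (hab > 0).any():
        raise ValueError("grid has no habitable (land) cell")
    cap = np.zeros_like(base_grid.capacity)
    for name, code in HABITAT_CODES.items():
        if name == "sea":
            continue
        cap[hab == code] = scheme[name]
    return DemeGrid(
        cap, base_grid.xllcorner, base_grid.yllcorner,
        base_grid.cellsize, hab.copy(),
    )


@dataclass
class ExpansionScenario:
    """Parameters of a single range-expansion scenario."""

    origin: tuple[float, float]  # (lon, lat)
    migration_rate: float = 0.07
    growth_rate: float = 0.1
    duration: int = 1600
    ancestral_size: float = 200.0
    lag: int = 200
    mutation_rate: float = 1e-5  # per locus per generation
    n_loci: int = 30_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration rate must lie in [0, 1]")
        if self.growth_rate < 0:
            raise ValueError("growth rate must be >= 0")
        if self.duration < 1 or self.ancestral_size <= 0:
            raise ValueError("invalid duration or ancestral size")

    def with_params(self, **kw) -> "ExpansionScenario":
        return replace(self, **kw)


@dataclass
class OccupancyHistory:
    """Recorded forward demography: densities and directed migrant flows.

    ``sizes[g]`` is the deme density after generation ``g`` (``sizes[0]`` is
    the initial state); ``flows[g, d]`` the migrants leaving each deme in
    direction ``d`` (N, S, E, W) during the step from ``g`` to ``g + 1``.
    """

    grid: DemeGrid
    scenario: ExpansionScenario
    sizes: np.ndarray
    flows: np.ndarray
    origin_cell: tuple[int, int]

    @property
    def n_generations(self) -> int:
        return self.flows.shape[0]

    def occupied_cells(self, generation: int = -1, threshold: float = 1.0):
        """(rows, cols) of cells with at least ``threshold`` individuals."""
        return np.nonzero(self.sizes[generation] >= threshold)


def _grow(N: np.ndarray, r: float, C: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(C > 0, N / np.where(C > 0, C, 1.0), 1.0)
    out = N + r * N * (1.0 - frac)
    return np.maximum(out, 0.0)


def _neighbor_counts(habitable: np.ndarray) -> np.ndarray:
    k = np.zeros(habitable.shape, dtype=float)
    for dr, dc in _DIRS:
        shifted = np.zeros_like(habitable)
        src = habitable.astype(float)
        if dr == -1:
            shifted[1:, :] = src[:-1, :]
        elif dr == 1:
            shifted[:-1, :] = src[1:, :]
        elif dc == 1:
            shifted[:, :-1] = src[:, 1:]
        else:
            shifted[:, 1:] = src[:, :-1]
        k += shifted
    return k


def _shift(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Move array contents by (dr, dc) with zero fill."""
    out = np.zeros_like(a)
    if dr == -1:
        out[:-1, :] = a[1:, :]
    elif dr == 1:
        out[1:, :] = a[:-1, :]
    elif dc == 1:
        out[:, 1:] = a[:, :-1]
    elif dc == -1:
        out[:, :-1] = a[:, 1:]
    else:
        out[:] = a
    return out


def run_forward_demography(
    grid: DemeGrid,
    scenario: ExpansionScenario,
    rng: np.random.Generator | None = None,
) -> OccupancyHistory:
    """Deterministic forward demographic phase.

    The origin deme is seeded with the ancestral population size (the
    pre-expansion lag is a constant-size phase handled by the backward
    coalescent).  Each generation every occupied deme grows logistically
    towards its carrying capacity and a fraction ``m`` of the grown deme
    emigrates, split equally among its habitable von Neumann neighbours.
    """
    lon, lat = scenario.origin
    try:
        cell = grid.cell_of(lon, lat)
    except ValueError:
        cell = None
    if cell is None or not grid.is_habitable(*cell):
        r, c = grid.nearest_habitable(lon, lat)
        slon, slat = grid.cell_center(np.array(r), np.array(c))
        raise ValueError(
            f"scenario origin ({lon}, {lat}) is not habitable; nearest "
            f"habitable cell centre is ({float(slon):.3f}, {float(slat):.3f})"
        )
    habitable = grid.capacity > 0
    nnbr = _neighbor_counts(habitable)
    m = scenario.migration_rate
    G = int(scenario.duration)
    sizes = np.zeros((G + 1,) + grid.shape, dtype=np.float64)
    flows = np.zeros((G, 4) + grid.shape, dtype=np.float64)
    N = np.zeros(grid.shape)
    N[cell] = scenario.ancestral_size
    sizes[0] = N
    for g in range(G):
        grown = _grow(N, scenario.growth_rate, grid.capacity)
        grown[~habitable] = 0.0
        can_emigrate = habitable & (nnbr > 0)
        out_total = np.where(can_emigrate, m * grown, 0.0)
        per_nbr = np.divide(
            out_total, nnbr, out=np.zeros_like(out_total), where=nnbr > 0
        )
        N_new = grown - out_total
        for d, (dr, dc) in enumerate(_DIRS):
            f = np.where(_shift(habitable, -dr, -dc), per_nbr, 0.0)
            flows[g, d] = f
            N_new += _shift(f, dr, dc)
        N_new[~habitable] = 0.0
        N = N_new
        sizes[g + 1] = N
    return OccupancyHistory(grid, scenario, sizes, flows, cell)


def backward_migration_probs(history: OccupancyHistory, g: int) -> np.ndarray:
    """Backward ancestry probabilities for the forward step ``g -> g+1``.

    Returns an array of shape ``(nrows, ncols, 5)``: for a lineage sitting in
    a deme at generation ``g+1``, the probability that its parent was in the
    same deme (column 0) or in the neighbour to the N, S, E, W (columns
    1..4), proportional to the recorded migrant flows into the deme.
    """
    grown = _grow(history.sizes[g], history.scenario.growth_rate,
                  history.grid.capacity)
    habitable = history.grid.capacity > 0
    grown[~habitable] = 0.0
    stay = grown - history.flows[g].sum(axis=0)
    P = np.zeros(history.grid.shape + (5,))
    P[:, :, 0] = stay
    # flow leaving neighbour i towards us appears shifted into our cell
    for d, (dr, dc) in enumerate(_DIRS):
        P[:, :, 1 + d] = _shift(history.flows[g, d], dr, dc)
    total = P.sum(axis=2)
    with np.errstate(invalid="ignore"):
        P = np.divide(P, total[:, :, None], out=np.zeros_like(P),
                      where=total[:, :, None] > 0)
    return P


# Backward choice 1+d means the parent emitted migrants in direction
# _DIRS[d] to reach this deme, so the parent deme lies at -_DIRS[d].
_PARENT_OFFSETS = np.array([(0, 0), (1, 0), (-1, 0), (0, -1), (0, 1)])


@dataclass
class SpatialSample:
    """Sampled chromosomes with their demes and recorded coordinates."""

    demes: np.ndarray  # (n, 2) row/col per chromosome
    lons: np.ndarray
    lats: np.ndarray
    chromosome_ids: list[str]
    site_labels: list[str]
    mode: str = "population"

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_ids)

    def site_groups(self):
        from .haplotypes import GroupAssignment

        return GroupAssignment.from_sequence(self.chromosome_ids, self.site_labels)


def _spread_sites(
    history: OccupancyHistory, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Quasi-uniformly spread occupied cells, chosen by k-means on cell
    centres of the occupied region (k = number of sites)."""
    from sklearn.cluster import KMeans

    rows, cols = history.occupied_cells()
    if rows.size < n_sites:
        raise ValueError(
            f"only {rows.size} occupied cells for {n_sites} requested sites"
        )
    lon, lat = history.grid.cell_center(rows, cols)
    pts = np.column_stack([lon, lat])
    km = KMeans(
        n_clusters=n_sites, n_init=4,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(pts)
    chosen = []
    for c in km.cluster_centers_:
        k = int(np.argmin(((pts - c) ** 2).sum(axis=1)))
        chosen.append(k)
    chosen = sorted(set(chosen))
    # k-means centroids can snap to duplicate cells; top up with the most
    # isolated remaining occupied cells
    while len(chosen) < n_sites:
        rest = np.setdiff1d(np.arange(len(pts)), chosen)
        d = ((pts[rest, None, :] - pts[chosen][None, :, :]) ** 2).sum(-1).min(1)
        chosen.append(int(rest[np.argmax(d)]))
    sel = np.asarray(chosen[:n_sites])
    return np.column_stack([rows[sel], cols[sel]])


def draw_sampling_design(
    history: OccupancyHistory,
    mode: str,
    rng: np.random.Generator,
    n_sites: int = 30,
    haploids_per_site: int = 10,
    jitter_sd: float = 2.0,
    max_attempts: int = 100,
) -> SpatialSample:
    """Draw a population- or individual-sampling design.

    Population mode places ``haploids_per_site`` chromosomes at each of
    ``n_sites`` spread sites.  Individual mode records one chromosome at
    ``n_sites * haploids_per_site`` distinct sites, each obtained from a
    population centre jittered by independent Gaussian noise (SD
    ``jitter_sd`` degrees) and snapped to the nearest occupied cell.
    """
    if mode not in ("population", "individual"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    sites = _spread_sites(history, n_sites, rng)
    grid = history.grid
    rows_o, cols_o = history.occupied_cells()
    olon, olat = grid.cell_center(rows_o, cols_o)

    demes, lons, lats, ids, labels = [], [], [], [], []
    if mode == "population":
        for s, (r, c) in enumerate(sites):
            lon, lat = grid.cell_center(np.array(r), np.array(c))
            for h in range(haploids_per_site):
                demes.append((r, c))
                lons.append(float(lon))
                lats.append(float(lat))
                ids.append(f"s{s:02d}_h{h:02d}")
                labels.append(f"site{s:02d}")
    else:
        search_radius = max(5.0 * jitter_sd, 2.0 * grid.cellsize)
        k = 0
        for s, (r, c) in enumerate(sites):
            lon0, lat0 = grid.cell_center(np.array(r), np.array(c))
            for h in range(haploids_per_site):
                for attempt in range(max_attempts):
                    jl = float(lon0) + rng.normal(0.0, jitter_sd)
                    jb = float(lat0) + rng.normal(0.0, jitter_sd)
                    d2 = (olon - jl) ** 2 + (olat - jb) ** 2
                    j = int(np.argmin(d2))
                    if math.sqrt(d2[j]) <= search_radius:
                        break
                    logger.debug(
                        "jittered point (%f, %f) had no occupied cell within "
                        "%.1f deg (attempt %d)", jl, jb, search_radius, attempt
                    )
                else:
                    raise RuntimeError("could not place a jittered sample site")
                demes.append((int(rows_o[j]), int(cols_o[j])))
                lons.append(jl)
                lats.append(jb)
                ids.append(f"i{k:03d}")
                labels.append(f"i{k:03d}")
                k += 1
    return SpatialSample(
        np.asarray(demes), np.asarray(lons), np.asarray(lats), ids, labels, mode
    )


def _ancestral_coalescent(
    k: int, N: float, rng: np.random.Generator
) -> list[tuple[float, int, int]]:
    """Merger schedule (waiting gens, i, j) for k lineages in a panmictic
    population of size N: per generation each pair coalesces w.p. 1/N."""
    events = []
    while k > 1:
        npairs = k * (k - 1) // 2
        p = -math.expm1(npairs * math.log1p(-min(1.0 / max(N, 1.0), 1.0)))
        dt = rng.geometric(min(max(p, 1e-12), 1.0))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        events.append((float(dt), min(i, j), max(i, j)))
        k -= 1
    return events


def sample_backward_coalescent(
    history: OccupancyHistory,
    sample: SpatialSample,
    scenario: ExpansionScenario | None = None,
    rng: np.random.Generator | None = None,
    n_loci: int | None = None,
    keep_trees: bool = False,
    drop_monomorphic: bool = False,
):
    """Coalescent + infinite-sites mutations conditioned on the history.

    Per locus (independently), lineages start in the sampled demes at the
    final generation and trace backward: the ancestry of a lineage follows
    the recorded migrant flows (backward migration probability from deme j
    to neighbour i proportional to the forward migrants i -> j that
    generation), and two lineages in a deme of recorded size N coalesce with
    probability 1/N per generation.  Lineages surviving to the start of the
    history coalesce in a panmictic ancestral population of the scenario's
    ancestral size.  Mutations are Poisson per branch with the per-locus
    per-generation mutation rate.

    Returns the haplotype matrix (and the genealogies if ``keep_trees``).
    """
    scenario = scenario or history.scenario
    if rng is None:
        raise ValueError("an rng is required")
    L = int(n_loci if n_loci is not None else scenario.n_loci)
    n = sample.n_chromosomes
    nr, nc = history.grid.shape
    G = history.n_generations
    sizes = history.sizes

    # flattened deme index per lineage; per-locus tree arrays
    parent2d = np.full((L, 2 * n - 1), -1, dtype=np.int32)
    time2d = np.zeros((L, 2 * n - 1), dtype=np.float64)
    nxt = np.full(L, n, dtype=np.int32)

    deme0 = sample.demes[:, 0] * nc + sample.demes[:, 1]
    lin_locus = np.repeat(np.arange(L, dtype=np.int32), n)
    lin_deme = np.tile(deme0.astype(np.int32), L)
    lin_node = np.tile(np.arange(n, dtype=np.int32), L)

    # verify sampled demes are occupied
    occ = sizes[-1].ravel()
    if np.any(occ[deme0] < 1.0):
        bad = deme0[occ[deme0] < 1.0][0]
        raise ValueError(
            f"sampled deme (row {bad // nc}, col {bad % nc}) is not occupied "
            "at sampling time"
        )

    for g in range(G - 1, -1, -1):
        back_t = float(G - 1 - g)  # age of generation g+1 lineages is G-1-g
        if lin_locus.size == 0:
            break
        # --- coalescence among lineages at generation g+1 ---------------- #
        Nrec = np.maximum(sizes[g + 1].ravel(), 1.0)
        key = lin_locus.astype(np.int64) * (nr * nc) + lin_deme
        order = np.argsort(key, kind="stable")
        sk = key[order]
        starts = np.flatnonzero(np.r_[True, sk[1:] != sk[:-1]])
        counts = np.diff(np.r_[starts, sk.size])
        multi = counts >= 2
        if multi.any():
            gsizes = counts[multi]
            gstarts = starts[multi]
            gdemes = lin_deme[order[gstarts]]
            npairs = gsizes * (gsizes - 1) // 2
            nmerge = rng.binomial(npairs, 1.0 / Nrec[gdemes])
            nmerge = np.minimum(nmerge, gsizes - 1)
            hot = np.flatnonzero(nmerge > 0)
            dead = []
            for h in hot:
                st, k, nm = gstarts[h], int(gsizes[h]), int(nmerge[h])
                members = list(order[st : st + k])
                rng.shuffle(members)
                loc = int(lin_locus[members[0]])
                for _ in range(nm):
                    a = members.pop()
                    b = members.pop()
                    v = int(nxt[loc])
                    nxt[loc] += 1
                    parent2d[loc, lin_node[a]] = v
                    parent2d[loc, lin_node[b]] = v
                    time2d[loc, v] = back_t
                    lin_node[a] = v  # a carries the merged lineage
                    dead.append(b)
                    members.append(a)
            if dead:
                alive = np.ones(lin_locus.size, dtype=bool)
                alive[dead] = False
                # drop loci that reached their MRCA
                lin_locus = lin_locus[alive]
                lin_deme = lin_deme[alive]
                lin_node = lin_node[alive]
                done = np.bincount(lin_locus, minlength=L) <= 1
                if done.any():
                    keep = ~done[lin_locus]
                    lin_locus = lin_locus[keep]
                    lin_deme = lin_deme[keep]
                    lin_node = lin_node[keep]
        if lin_locus.size == 0:
            break
        # --- backward migration to generation g --------------------------- #
        P = backward_migration_probs(history, g).reshape(nr * nc, 5)
        rowp = P[lin_deme]
        bad = rowp.sum(axis=1) <= 0
        if bad.any():
            b = int(lin_deme[np.flatnonzero(bad)[0]])
            raise RuntimeError(
                f"lineage stranded in empty deme (row {b // nc}, col {b % nc}) "
                f"at generation {g + 1}: inconsistent history"
            )
        u = rng.random(lin_deme.size)
        choice = (u[:, None] > np.cumsum(rowp, axis=1)).sum(axis=1)
        off = _PARENT_OFFSETS[choice]
        lin_deme = lin_deme + off[:, 0].astype(np.int32) * nc + off[:, 1].astype(
            np.int32
        )

    # --- panmictic ancestral phase -------------------------------------- #
    if lin_locus.size:
        base_t = float(G)
        for loc in np.unique(lin_locus):
            nodes = list(lin_node[lin_locus == loc])
            t = base_t
            for dt, i, j in _ancestral_coalescent(
                len(nodes), scenario.ancestral_size, rng
            ):
                t += dt
                v = int(nxt[loc])
                nxt[loc] += 1
                parent2d[loc, nodes[i]] = v
                parent2d[loc, nodes[j]] = v
                time2d[loc, v] = t
                nodes[j] = v
                nodes.pop(i)

    # --- assemble genealogies and drop mutations ------------------------- #
    from .coalescent import drop_mutations

    theta = 2.0 * scenario.mutation_rate  # Poisson rate mu per generation
    labels = list(sample.chromosome_ids)
    blocks, trees = [], []
    for loc in range(L):
        length = np.zeros(2 * n - 1)
        has_p = parent2d[loc] >= 0
        length[has_p] = time2d[loc][parent2d[loc][has_p]] - time2d[loc][has_p]
        tree = Genealogy(parent2d[loc].copy(), length, labels, units="generations")
        if keep_trees:
            trees.append(tree)
        blocks.append(drop_mutations(tree, theta, rng))
    matrix = concatenate(blocks)
    if drop_monomorphic:
        matrix = filter_monomorphic(matrix)
    return (matrix, trees) if keep_trees else matrix
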