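"""ABC inference of the geographic origin of a range expansion.

The observed data are reduced to a *singleton histogram*: chromosomes are
grouped into spatial clusters (k-means on their coordinates), and the
summary statistic is, per group, the mean number of singletons carried by a
group member divided by the total number of singletons in the sample.  A
reference table of prior-predictive range-expansion simulations maps origin
coordinates (plus nuisance parameters) to the same statistic; rejection
sampling with optional regression adjustment (local-linear or an ensemble of
feed-forward neural networks) yields the posterior for the origin.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .expansion import DemeGrid, ExpansionScenario, OccupancyHistory, SpatialSample
from .haplotypes import GroupAssignment, HaplotypeMatrix, MISSING
from .singletons import SingletonProfile, count_singletons

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "ReferenceTable",
    "PosteriorEstimate",
    "spatial_kmeans",
    "choose_k",
    "singleton_histogram",
    "mask_missing",
    "sample_prior",
    "build_reference_table",
    "abc_estimate",
    "validate_origin_recovery",
]

#: Default nuisance-parameter ranges (uniform priors).  These stand in for
#: unavailable published ranges and are deliberately wide; all are exposed.
DEFAULT_NUISANCE_RANGES = {
    "migration_rate": (0.01, 0.2),
    "growth_rate": (0.05, 0.5),
    "duration": (500, 3000),
    "ancestral_size": (50, 1000),
    "lag": (50, 500),
}


@dataclass
class PriorSpec:
    """Prior for the origin coordinates and nuisance parameters.

    The origin prior is uniform over the lon/lat box, down-weighted
    triangularly over the outer ``taper_fraction`` of each coordinate range
    (extreme latitudes and longitudes are less plausible origins), and
    restricted to habitable cells of ``grid``.
    """

    lon_range: tuple[float, float] = (-16.0, 40.0)
    lat_range: tuple[float, float] = (5.0, 30.0)
    taper_fraction: float = 0.2
    grid: DemeGrid | None = None
    nuisance_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_NUISANCE_RANGES)
    )

    def taper_weight(self, lon: float, lat: float) -> float:
        w = 1.0
        for x, (lo, hi) in ((lon, self.lon_range), (lat, self.lat_range)):
            if not lo <= x <= hi:
                return 0.0
            if self.taper_fraction > 0:
                edge = self.taper_fraction * (hi - lo)
                w *= min(1.0, min(x - lo, hi - x) / edge) if edge > 0 else 1.0
        return w

    def habitable(self, lon: float, lat: float) -> bool:
        if self.grid is None:
            return True
        try:
            r, c = self.grid.cell_of(lon, lat)
        except ValueError:
            return False
        return self.grid.is_habitable(r, c)


def sample_prior(spec: PriorSpec, rng: np.random.Generator) -> dict:
    """One draw from the prior: origin by rejection on the tapered,
    habitability-constrained density; nuisance parameters uniform."""
    for _ in range(100_000):
        lon = rng.uniform(*spec.lon_range)
        lat = rng.uniform(*spec.lat_range)
        if rng.random() >= spec.taper_weight(lon, lat):
            continue
        if spec.habitable(lon, lat):
            break
    else:
        raise RuntimeError("prior support appears empty (no habitable cell)")
    draw = {"lon": lon, "lat": lat}
    for name, (lo, hi) in spec.nuisance_ranges.items():
        draw[name] = float(rng.uniform(lo, hi))
    return draw


def spatial_kmeans(
    lons,
    lats,
    ids: list[str],
    k: int,
    rng: np.random.Generator,
    n_init: int = 10,
) -> GroupAssignment:
    """Group chromosomes into spatial clusters by k-means on coordinates.

    Lloyd's algorithm with k-means++ initialization, best of ``n_init``
    restarts; deterministic for a fixed rng state.
    """
    from sklearn.cluster import KMeans

    pts = np.column_stack([np.asarray(lons, float), np.asarray(lats, float)])
    if k > len(np.unique(pts, axis=0)):
        raise ValueError(f"k={k} exceeds the number of distinct coordinates")
    km = KMeans(n_clusters=k, n_init=n_init,
                random_state=int(rng.integers(2**31 - 1))).fit(pts)
    labels = [f"g{int(l):02d}" for l in km.labels_]
    ga = GroupAssignment.from_sequence(ids, labels)
    ga.group_order = sorted(ga.group_order)
    sizes = [len(ga.members(g)) for g in ga.group_order]
    logger.info("spatial_kmeans: k=%d, minimum group size %d", k, min(sizes))
    return ga


def choose_k(
    lons, lats, min_group_size: int, rng: np.random.Generator, k_max: int = 30
) -> int:
    """Largest k whose smallest k-means cluster still has ``min_group_size``
    members (more clusters give a finer histogram; the floor keeps group
    means stable)."""
    ids = [str(i) for i in range(len(lons))]
    for k in range(min(k_max, len(ids)), 1, -1):
        ga = spatial_kmeans(lons, lats, ids, k, rng)
        if min(len(ga.members(g)) for g in ga.group_order) >= min_group_size:
            return k
    return 1


def singleton_histogram(
    profile: SingletonProfile, groups: GroupAssignment
) -> np.ndarray:
    """Summary statistic: per group, the mean singleton count of a group
    member divided by the total singleton count; entries ordered by group
    label order."""
    if not profile.defined:
        raise ValueError("no singletons: summary statistic undefined")
    idx = groups.indices(profile.chromosome_ids)
    counts = profile.per_chromosome_counts
    return np.array(
        [counts[idx[g]].mean() / profile.total for g in groups.groups]
    )


def mask_missing(
    matrix: HaplotypeMatrix,
    rate,
    rng: np.random.Generator,
) -> HaplotypeMatrix:
    """Set entries to missing independently at the target rate(s).

    ``rate`` is a global scalar or a per-chromosome vector, matching the
    missingness of an observed data set so that simulated and observed
    summary statistics are comparable.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any((rate < 0) | (rate >= 1)):
        raise ValueError("missingness rates must lie in [0, 1)")
    if rate.ndim == 0:
        rate = np.full(matrix.n_chromosomes, float(rate))
    elif rate.shape != (matrix.n_chromosomes,):
        raise ValueError("per-chromosome rate vector has wrong length")
    mask = rng.random(matrix.alleles.shape) < rate[:, None]
    alleles = matrix.alleles.copy()
    alleles[mask] = MISSING
    return HaplotypeMatrix(alleles, list(matrix.chromosome_ids), matrix.folded)


@dataclass
class ReferenceTable:
    """Archive of (parameter draw, summary statistic) pairs."""

    params: pd.DataFrame
    stats: np.ndarray
    group_order: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if self.stats.shape[0] != len(self.params):
            raise ValueError("params/stats row mismatch")
        if self.stats.shape[1] != len(self.group_order):
            raise ValueError("statistic dimension != number of groups")

    def __len__(self) -> int:
        return len(self.params)

    def subset(self, n: int) -> "ReferenceTable":
        return ReferenceTable(
            self.params.iloc[:n].reset_index(drop=True),
            self.stats[:n],
            list(self.group_order),
            dict(self.metadata),
        )

    def to_csv(self, path) -> None:
        path = Path(path)
        df = self.params.copy()
        for j, g in enumerate(self.group_order):
            df[f"stat_{g}"] = self.stats[:, j]
        df.to_csv(path, index=False)
        sidecar = dict(self.metadata)
        sidecar["group_order"] = [str(g) for g in self.group_order]
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, default=str) + "\n"
        )

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        path = Path(path)
        df = pd.read_csv(path)
        meta = {}
        side = path.with_suffix(".json")
        if side.exists():
            meta = json.loads(side.read_text())
        stat_cols = [c for c in df.columns if c.startswith("stat_")]
        groups = meta.get("group_order", [c[5:] for c in stat_cols])
        stats = df[[f"stat_{g}" for g in groups]].to_numpy()
        params = df.drop(columns=stat_cols)
        return cls(params, stats, list(groups), meta)


def _scenario_hash(scenario: ExpansionScenario, grid: DemeGrid) -> str:
    blob = json.dumps(
        {
            "scenario": scenario.__dict__,
            "grid": [grid.shape, grid.xllcorner, grid.yllcorner, grid.cellsize,
                     float(grid.capacity.sum())],
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_statistic(
    draw: dict,
    scenario_template: ExpansionScenario,
    grid: DemeGrid,
    sample: SpatialSample,
    groups: GroupAssignment,
    rng: np.random.Generator,
    n_loci: int | None = None,
    missing_rate=0.0,
) -> np.ndarray | None:
    """Run one range-expansion simulation at a parameter draw and return its
    singleton histogram (None when the run yields no singletons)."""
    from .expansion import run_forward_demography, sample_backward_coalescent

    kw = {k: v for k, v in draw.items() if k not in ("lon", "lat")}
    if "duration" in kw:
        kw["duration"] = int(round(kw["duration"]))
    if "lag" in kw:
        kw["lag"] = int(round(kw["lag"]))
    scenario = scenario_template.with_params(
        origin=(draw["lon"], draw["lat"]), **kw
    )
    history = run_forward_demography(grid, scenario)
    # fixed observation sites: snap each to the nearest occupied deme
    rows_o, cols_o = history.occupied_cells()
    if rows_o.size == 0:
        return None
    olon, olat = grid.cell_center(rows_o, cols_o)
    demes = np.empty_like(sample.demes)
    for i, (lon, lat) in enumerate(zip(sample.lons, sample.lats)):
        j = int(np.argmin((olon - lon) ** 2 + (olat - lat) ** 2))
        demes[i] = (rows_o[j], cols_o[j])
    snapped = SpatialSample(
        demes, sample.lons, sample.lats,
        list(sample.chromosome_ids), list(sample.site_labels), sample.mode,
    )
    matrix = sample_backward_coalescent(
        history, snapped, scenario, rng, n_loci=n_loci
    )
    if np.any(np.asarray(missing_rate) > 0):
        matrix = mask_missing(matrix, missing_rate, rng)
    profile = count_singletons(matrix)
    if not profile.defined:
        return None
    return singleton_histogram(profile, groups)


def build_reference_table(
    n_sims: int,
    spec: PriorSpec,
    scenario_template: ExpansionScenario,
    grid: DemeGrid,
    sample: SpatialSample,
    groups: GroupAssignment,
    rng: np.random.Generator,
    n_loci: int | None = None,
    missing_rate=0.0,
) -> ReferenceTable:
    """Prior-predictive reference table for ABC.

    For each draw from the prior, a range expansion is simulated, genotypes
    are sampled at the fixed observation sites (snapped to occupied demes),
    missingness is imposed, and the singleton histogram is recorded.  Draws
    whose simulation yields no singletons are skipped with a log entry.
    """
    rows, stats, seeds = [], [], []
    n_skipped = 0
    while len(rows) < n_sims:
        seed = int(rng.integers(2**31 - 1))
        sub = np.random.default_rng(seed)
        draw = sample_prior(spec, sub)
        stat = simulate_statistic(
            draw, scenario_template, grid, sample, groups, sub,
            n_loci=n_loci, missing_rate=missing_rate,
        )
        if stat is None:
            n_skipped += 1
            logger.info("build_reference_table: skipped draw %s", draw)
            continue
        rows.append(draw)
        stats.append(stat)
        seeds.append(seed)
    meta = {
        "seeds": seeds,
        "n_skipped": n_skipped,
        "scenario_hash": _scenario_hash(scenario_template, grid),
    }
    return ReferenceTable(
        pd.DataFrame(rows), np.asarray(stats), groups.groups, meta
    )


@dataclass
class PosteriorEstimate:
    """Accepted/adjusted ABC sample with weights and a 2D origin density."""

    samples: pd.DataFrame  # adjusted parameter draws
    weights: np.ndarray
    grid_lons: np.ndarray
    grid_lats: np.ndarray
    density: np.ndarray  # (n_lat, n_lon), normalized
    mode: tuple[float, float]
    credible_intervals: dict
    method: str

    def mean(self, coord: str) -> float:
        return float(np.average(self.samples[coord], weights=self.weights))


def _mad(x: np.ndarray) -> np.ndarray:
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    fallback = np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    return np.where(mad > 0, mad, fallback)


def _weighted_quantile(x, q, w):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw = cw / cw[-1]
    return float(np.interp(q, cw, np.asarray(x)[order]))


def abc_estimate(
    observed: np.ndarray,
    table: ReferenceTable,
    tolerance: float = 0.05,
    method: str = "local-linear",
    prior_spec: PriorSpec | None = None,
    grid_points: int = 100,
    ci_level: float = 0.95,
    hpd: bool = False,
    n_networks: int = 250,
    rng: np.random.Generator | None = None,
) -> PosteriorEstimate:
    """ABC posterior for the origin from an observed singleton histogram.

    Summary statistics are standardized by their table-wide median absolute
    deviation; the ``tolerance`` fraction of draws nearest (Euclidean) to the
    observed statistic is accepted with Epanechnikov weights.  ``method``:

    * ``rejection`` — accepted draws, weighted;
    * ``local-linear`` — Beaumont-style weighted linear regression
      adjustment of the parameters on the statistics (default);
    * ``nonlinear-regression`` — mean of an ensemble of ``n_networks``
      single-hidden-layer feed-forward regressions (requires ``rng``).

    The joint origin posterior is a weighted 2D Gaussian KDE on a
    ``grid_points`` x ``grid_points`` lon/lat grid, with density clipped to
    the prior support (zero outside the box and on water) and renormalized.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must lie in (0, 1]")
    if method not in ("rejection", "local-linear", "nonlinear-regression"):
        raise ValueError(f"unknown ABC method {method!r}")
    observed = np.asarray(observed, float)
    if observed.shape != (table.stats.shape[1],):
        raise ValueError("observed statistic has wrong dimension")
    S = table.stats
    scale = _mad(S)
    Z = (S - observed) / scale
    dist = np.sqrt((Z**2).sum(axis=1))
    n_acc = int(math.ceil(tolerance * len(table)))
    if n_acc < 20:
        raise ValueError(
            f"tolerance {tolerance} accepts only {n_acc} rows; increase it"
        )
    acc = np.argsort(dist)[:n_acc]
    delta = max(dist[acc].max(), 1e-300)
    w = 1.0 - (dist[acc] / delta) ** 2
    if w.sum() <= 0:
        w = np.ones(n_acc)
    w = w / w.sum()

    params = table.params.select_dtypes("number")
    theta = params.to_numpy()[acc]
    Sa = (S[acc] - observed) / scale  # centred at the observation

    if method == "local-linear":
        X = np.column_stack([np.ones(n_acc), Sa])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ theta, rcond=None)
        theta_adj = theta - Sa @ beta[1:]
    elif method == "nonlinear-regression":
        if rng is None:
            raise ValueError("nonlinear-regression requires an rng")
        from sklearn.neural_network import MLPRegressor

        preds_obs = np.zeros((n_networks, theta.shape[1]))
        preds_acc = np.zeros((n_networks, n_acc, theta.shape[1]))
        zero = np.zeros((1, Sa.shape[1]))
        for b in range(n_networks):
            net = MLPRegressor(
                hidden_layer_sizes=(max(4, Sa.shape[1]),),
                max_iter=500,
                random_state=int(rng.integers(2**31 - 1)),
            )
            net.fit(Sa, theta)
            preds_obs[b] = net.predict(zero)[0]
            preds_acc[b] = net.predict(Sa)
        m_obs = preds_obs.mean(axis=0)
        m_acc = preds_acc.mean(axis=0)
        theta_adj = theta - m_acc + m_obs[None, :]
    else:
        theta_adj = theta

    samples = pd.DataFrame(theta_adj, columns=list(params.columns))
    if prior_spec is not None:
        samples["lon"] = samples["lon"].clip(*prior_spec.lon_range)
        samples["lat"] = samples["lat"].clip(*prior_spec.lat_range)
        lon_range, lat_range = prior_spec.lon_range, prior_spec.lat_range
    else:
        lon_range = (samples["lon"].min(), samples["lon"].max())
        lat_range = (samples["lat"].min(), samples["lat"].max())

    glon = np.linspace(*lon_range, grid_points)
    glat = np.linspace(lat_range[1], lat_range[0], grid_points)
    xy = np.vstack([samples["lon"], samples["lat"]])
    try:
        kde = gaussian_kde(xy, weights=w)
        GX, GY = np.meshgrid(glon, glat)
        dens = kde(np.vstack([GX.ravel(), GY.ravel()])).reshape(GX.shape)
    except np.linalg.LinAlgError:  # degenerate sample (e.g. single point)
        dens = np.zeros((grid_points, grid_points))
        i = int(np.argmin(np.abs(glat - samples["lat"].iloc[0])))
        j = int(np.argmin(np.abs(glon - samples["lon"].iloc[0])))
        dens[i, j] = 1.0
    if prior_spec is not None and prior_spec.grid is not None:
        GX, GY = np.meshgrid(glon, glat)
        habitable = np.array(
            [prior_spec.habitable(x, y) for x, y in zip(GX.ravel(), GY.ravel())]
        ).reshape(GX.shape)
        dens = np.where(habitable, dens, 0.0)
    total = dens.sum()
    if total > 0:
        dens = dens / total
    i, j = np.unravel_index(int(np.argmax(dens)), dens.shape)
    mode = (float(glon[j]), float(glat[i]))

    alpha = 1.0 - ci_level
    cis = {}
    for coord in ("lon", "lat"):
        x = samples[coord].to_numpy()
        if hpd:
            order = np.argsort(x)
            xs, ws = x[order], w[order]
            cum = np.cumsum(ws)
            best = (xs[0], xs[-1])
            width = math.inf
            for lo_ix in range(len(xs)):
                target = (cum[lo_ix] - ws[lo_ix]) + ci_level
                hi_ix = int(np.searchsorted(cum, target))
                if hi_ix >= len(xs):
                    break
                if xs[hi_ix] - xs[lo_ix] < width:
                    width = xs[hi_ix] - xs[lo_ix]
                    best = (xs[lo_ix], xs[hi_ix])
            cis[coord] = best
        else:
            cis[coord] = (
                _weighted_quantile(x, alpha / 2, w),
                _weighted_quantile(x, 1 - alpha / 2, w),
            )
    return PosteriorEstimate(
        samples, w, glon, glat, dens, mode, cis, method
    )


def validate_origin_recovery(
    n_test: int,
    table: ReferenceTable,
    spec: PriorSpec,
    scenario_template: ExpansionScenario,
    grid: DemeGrid,
    sample: SpatialSample,
    groups: GroupAssignment,
    rng: np.random.Generator,
    tolerance: float = 0.05,
    method: str = "local-linear",
    n_loci: int | None = None,
    missing_rate=0.0,
) -> dict:
    """Origin-recovery validation: simulate pseudo-observed data sets at
    known origins, estimate each with ABC, and report the squared Pearson
    correlation of estimated vs. true coordinates."""
    if n_test < 10:
        raise ValueError("need at least 10 test data sets")
    truths, estimates = [], []
    made = 0
    while made < n_test:
        draw = sample_prior(spec, rng)
        stat = simulate_statistic(
            draw, scenario_template, grid, sample, groups, rng,
            n_loci=n_loci, missing_rate=missing_rate,
        )
        if stat is None:
            continue
        post = abc_estimate(
            stat, table, tolerance=tolerance, method=method,
            prior_spec=spec, grid_points=20, rng=rng,
        )
        truths.append((draw["lon"], draw["lat"]))
        estimates.append((post.mean("lon"), post.mean("lat")))
        made += 1
    truths = np.asarray(truths)
    estimates = np.asarray(estimates)
    out = {"truths": truths, "estimates": estimates}
    for k, coord in enumerate(("lon", "lat")):
        r = np.corrcoef(truths[:, k], estimates[:, k])[0, 1]
        out[f"r2_{coord}"] = float(r**2)
    return out
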