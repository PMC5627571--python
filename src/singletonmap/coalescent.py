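"""Coalescent simulation of genealogies and infinite-sites haplotypes.

Two demographic models are provided:

* a neutral, panmictic, constant-size Kingman coalescent, and
* a two-population split model: population 1 (present size ``N1``) grew
  exponentially from an ancestral population of size ``NA`` starting
  ``expansion_start_gens`` generations ago; population 2 split from
  population 1 ``split_time_gens`` generations ago at the constant relative
  size ``s * N1`` (``s`` is the shrink rate); there is no migration between
  the two populations after the split.

Time is measured in coalescent units of ``2 N1`` generations: while ``k``
lineages remain in a population of relative size ``x``, the waiting time to
the next coalescence is exponential with rate ``k (k - 1) / (2 x)``.
Mutations fall on a branch of length ``tau`` as Poisson with mean
``theta * tau / 2`` where ``theta = 2 mu N`` is the per-locus effective
mutation rate, so in the neutral model ``E[xi1] = theta`` and
``E[tau1] = 2``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genealogy import Genealogy
from .haplotypes import GroupAssignment, HaplotypeMatrix, concatenate
from .singletons import count_singletons, group_summaries

logger = logging.getLogger(__name__)

__all__ = [
    "SplitModelParams",
    "simulate_neutral_genealogy",
    "simulate_structured_genealogy",
    "drop_mutations",
    "replicate_split_study",
    "split_group_assignment",
]


@dataclass
class SplitModelParams:
    """Parameters of the two-population split model.

    ``theta`` and ``split_time_gens`` may each be a single number or a
    ``(low, high)`` range; ranges are redrawn uniformly per replicate by
    :func:`replicate_split_study`.
    """

    N1: float = 50_000.0
    shrink_rate: float = 0.33
    split_time_gens: float | tuple[float, float] = (1_000.0, 10_000.0)
    NA: float = 5_000.0
    expansion_start_gens: float = 10_000.0
    theta: float | tuple[float, float] = (5.0, 10.0)
    sample_sizes: tuple[int, int] = (50, 50)
    n_loci: int = 1_000
    #: The split study's per-locus theta is the ms-style Watterson parameter
    #: (4 N mu).  The package's mutation clock (Poisson rate theta/2 per unit
    #: of branch length, with E[xi1] = theta = 2 N mu in the neutral model)
    #: is half of that, so haplotype simulation doubles theta when this flag
    #: is set.  Setting it False treats theta directly as 2 N mu.
    watterson_theta: bool = True

    def __post_init__(self) -> None:
        if not (self.N1 > 0 and self.NA > 0):
            raise ValueError("population sizes must be positive")
        if not 0 < self.shrink_rate < 1:
            raise ValueError("shrink rate must lie in (0, 1)")
        hi = (
            self.split_time_gens[1]
            if isinstance(self.split_time_gens, tuple)
            else self.split_time_gens
        )
        if hi > self.expansion_start_gens:
            raise ValueError("split time must precede the expansion start")
        if min(self.sample_sizes) < 1 or self.n_loci < 0:
            raise ValueError("invalid sample sizes or locus count")

    @property
    def growth_rate(self) -> float:
        """Backward exponential decline rate of population 1, per 2*N1 gens."""
        t_exp = self.expansion_start_gens / (2.0 * self.N1)
        return math.log(self.N1 / self.NA) / t_exp

    def draw_scalars(self, rng: np.random.Generator) -> "SplitModelParams":
        """Resolve ranged parameters into scalars with one uniform draw each."""
        theta = self.theta
        if isinstance(theta, tuple):
            theta = float(rng.uniform(*theta))
        t = self.split_time_gens
        if isinstance(t, tuple):
            t = float(rng.uniform(*t))
        return replace(self, theta=theta, split_time_gens=t)


def _labels(n: int, prefix: str = "c") -> list[str]:
    w = len(str(n - 1))
    return [f"{prefix}{i:0{w}d}" for i in range(n)]


class _TreeBuilder:
    """Accumulates coalescence events into flat parent/length arrays."""

    def __init__(self, tip_labels: list[str]):
        n = len(tip_labels)
        self.labels = tip_labels
        self.parent = np.full(2 * n - 1, -1, dtype=np.int64)
        self.time = np.zeros(2 * n - 1, dtype=float)
        self.next_node = n

    def merge(self, a: int, b: int, tau: float) -> int:
        v = self.next_node
        self.next_node += 1
        self.parent[a] = v
        self.parent[b] = v
        self.time[v] = tau
        return v

    def build(self, units: str = "coalescent") -> Genealogy:
        length = np.zeros_like(self.time)
        has_parent = self.parent >= 0
        length[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        g = Genealogy(self.parent, length, self.labels, units=units)
        g.node_time = self.time.copy()
        return g


def _pop_pair(lineages: list[int], rng: np.random.Generator) -> tuple[int, int]:
    k = len(lineages)
    i = int(rng.integers(k))
    j = int(rng.integers(k - 1))
    if j >= i:
        j += 1
    if i > j:
        i, j = j, i
    a = lineages.pop(j)
    b = lineages.pop(i)
    return a, b


def simulate_neutral_genealogy(
    n: int, rng: np.random.Generator, tip_labels: list[str] | None = None
) -> Genealogy:
    """Neutral constant-size Kingman genealogy for ``n`` chromosomes.

    While ``k`` lineages remain, the waiting time to the next coalescence is
    exponential with rate ``k (k - 1) / 2`` (time in units of 2N generations)
    and a uniformly random pair merges.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    tb = _TreeBuilder(tip_labels or _labels(n))
    lineages = list(range(n))
    tau = 0.0
    for k in range(n, 1, -1):
        tau += rng.exponential(2.0 / (k * (k - 1)))
        a, b = _pop_pair(lineages, rng)
        lineages.append(tb.merge(a, b, tau))
    return tb.build()


def _next_growth_event(
    tau: float, rate0: float, beta: float, e: float
) -> float:
    """Waiting time to the next event under rate ``rate0 * exp(beta * u)``.

    ``rate0`` is the instantaneous rate at ``u = tau``; ``e`` an Exp(1) draw.
    """
    if rate0 <= 0:
        return math.inf
    if beta == 0.0:
        return e / rate0
    return math.log1p(beta * e / rate0) / beta


def simulate_structured_genealogy(
    params: SplitModelParams, rng: np.random.Generator
) -> Genealogy:
    """Genealogy of a two-population sample under the split model.

    Tips ``0 .. n1-1`` (labels ``p1_*``) are from population 1 and the rest
    (labels ``p2_*``) from population 2.  ``params.theta`` and
    ``params.split_time_gens`` must be scalars here (see ``draw_scalars``).
    """
    if isinstance(params.split_time_gens, tuple):
        params = params.draw_scalars(rng)
    n1, n2 = params.sample_sizes
    two_n1 = 2.0 * params.N1
    t_split = params.split_time_gens / two_n1
    t_exp = params.expansion_start_gens / two_n1
    beta = params.growth_rate
    s = params.shrink_rate
    anc = params.NA / params.N1

    labels = [f"p1_{i:02d}" for i in range(n1)] + [f"p2_{i:02d}" for i in range(n2)]
    tb = _TreeBuilder(labels)
    pop1 = list(range(n1))
    pop2 = list(range(n1, n1 + n2))
    tau = 0.0

    # phase A: two populations, 0 <= tau < t_split
    while tau < t_split and (len(pop1) + len(pop2)) > 1:
        k1, k2 = len(pop1), len(pop2)
        r1 = 0.5 * k1 * (k1 - 1) * math.exp(beta * tau)  # pop 1 shrinks backward
        r2 = 0.5 * k2 * (k2 - 1) / s
        dt1 = _next_growth_event(tau, r1, beta, rng.exponential())
        dt2 = rng.exponential() / r2 if r2 > 0 else math.inf
        if min(dt1, dt2) >= t_split - tau:
            tau = t_split
            break
        if dt1 <= dt2:
            tau += dt1
            pop1.append(tb.merge(*_pop_pair(pop1, rng), tau))
        else:
            tau += dt2
            pop2.append(tb.merge(*_pop_pair(pop2, rng), tau))

    # join: population 2 lineages move into population 1
    pool = pop1 + pop2

    # phase B: single growing population, t_split <= tau < t_exp
    while tau < t_exp and len(pool) > 1:
        k = len(pool)
        r = 0.5 * k * (k - 1) * math.exp(beta * tau)
        dt = _next_growth_event(tau, r, beta, rng.exponential())
        if dt >= t_exp - tau:
            tau = t_exp
            break
        tau += dt
        pool.append(tb.merge(*_pop_pair(pool, rng), tau))

    # phase C: constant-size ancestral population
    while len(pool) > 1:
        k = len(pool)
        tau += rng.exponential(2.0 * anc / (k * (k - 1)))
        pool.append(tb.merge(*_pop_pair(pool, rng), tau))
    return tb.build()


def split_group_assignment(params: SplitModelParams) -> GroupAssignment:
    """Population labels (1, 2) matching ``simulate_structured_genealogy``."""
    n1, n2 = params.sample_sizes
    labels = [f"p1_{i:02d}" for i in range(n1)] + [f"p2_{i:02d}" for i in range(n2)]
    return GroupAssignment.from_sequence(labels, [1] * n1 + [2] * n2)


def drop_mutations(
    tree: Genealogy, theta: float, rng: np.random.Generator
) -> HaplotypeMatrix:
    """Drop infinite-sites mutations on a genealogy.

    Each branch of length ``tau`` receives ``Poisson(theta * tau / 2)``
    mutations; every mutation creates one new biallelic column whose derived
    allele is carried by all tips below the branch.  Returns the
    ``n x S`` haplotype block (S = number of mutations; possibly 0).
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    counts = rng.poisson(0.5 * theta * tree.length)
    total = int(counts.sum())
    n = tree.n_tips
    if total == 0:
        return HaplotypeMatrix(
            np.zeros((n, 0), dtype=np.int8), list(tree.tip_labels)
        )
    masks = tree.descendant_masks()
    branch_ix = np.repeat(np.arange(tree.n_nodes), counts)
    alleles = masks[branch_ix].T.astype(np.int8)
    return HaplotypeMatrix(alleles, list(tree.tip_labels))


def simulate_split_matrix(
    params: SplitModelParams, rng: np.random.Generator
) -> tuple[HaplotypeMatrix, list[Genealogy]]:
    """Simulate ``params.n_loci`` unlinked infinite-sites loci and stack the
    resulting SNP columns into one haplotype matrix."""
    p = params.draw_scalars(rng)
    theta = 2.0 * p.theta if p.watterson_theta else p.theta
    blocks, trees = [], []
    for _ in range(p.n_loci):
        t = simulate_structured_genealogy(p, rng)
        trees.append(t)
        blocks.append(drop_mutations(t, theta, rng))
    return concatenate(blocks), trees


def replicate_split_study(
    params: SplitModelParams,
    n_replicates: int,
    rng: np.random.Generator,
    redraw: bool = True,
    keep_trees: bool = False,
) -> pd.DataFrame:
    """Replicate the split-model study and summarise each replicate.

    Each replicate simulates ``params.n_loci`` unlinked loci, stacks the SNP
    columns into a haplotype matrix, and computes per-population mean and SD
    of the singleton proportions against the known population assignment.
    With ``redraw`` (default), ranged parameters (theta, split time) are
    redrawn each replicate, mirroring the replication design of the split
    study; otherwise they are drawn once and held fixed.

    Returns a data frame with one row per replicate: ``pi_1, pi_2, ratio,
    sd_1, sd_2, n_polymorphic, n_singletons, theta, split_time_gens``.
    Replicates without a single singleton are recorded with NaN summaries.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    groups = split_group_assignment(params)
    fixed = params if redraw else params.draw_scalars(rng)
    rows = []
    all_trees: list[list[Genealogy]] = []
    for rep in range(n_replicates):
        p = fixed.draw_scalars(rng) if redraw else fixed
        matrix, trees = simulate_split_matrix(p, rng)
        if keep_trees:
            all_trees.append(trees)
        profile = count_singletons(matrix)
        row = {
            "replicate": rep,
            "theta": p.theta,
            "split_time_gens": p.split_time_gens,
            "n_polymorphic": matrix.n_loci,
            "n_singletons": profile.total,
        }
        if profile.defined:
            summ = group_summaries(profile, groups)
            row.update(
                pi_1=summ.mean_proportion[1],
                pi_2=summ.mean_proportion[2],
                ratio=summ.ratio,
                sd_1=summ.sd_proportion[1],
                sd_2=summ.sd_proportion[2],
            )
        else:
            logger.warning("replicate %d produced no singletons; excluded", rep)
            row.update(
                pi_1=np.nan, pi_2=np.nan, ratio=np.nan, sd_1=np.nan, sd_2=np.nan
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if keep_trees:
        df.attrs["trees"] = all_trees
    return df
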