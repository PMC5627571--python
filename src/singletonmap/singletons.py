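"""The empirical distribution of singletons and related diversity statistics.

A *singleton* is a derived allele observed on exactly one chromosome in the
sample.  Writing ``xi1_i`` for the number of singletons carried by chromosome
``i`` and ``xi1`` for their total, the empirical distribution of singletons is

    p_hat_i = xi1_i / xi1,        i = 1..n,

an unbiased, individual-level estimate of each chromosome's share of the
sample's genetic diversity.  Its theoretical counterpart is the expected
ratio of the external branch length of tip ``i`` to the total external branch
length of the locus genealogy, ``p_i = E[tau_i / tau1]``; in a panmictic
constant-size population ``p_i = 1/n`` and ``E[xi1] = theta``.

Related individuals inflate shared rare variation and bias these estimates;
they should be removed from the sample before analysis (no kinship filtering
is performed here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genealogy import Genealogy
from .haplotypes import MISSING, GroupAssignment, HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SingletonProfile",
    "DiversitySummary",
    "count_singletons",
    "external_branch_lengths",
    "theoretical_distribution",
    "group_summaries",
    "expected_heterozygosity",
    "site_frequency_spectrum",
    "filter_monomorphic",
]


@dataclass
class SingletonProfile:
    """Per-chromosome singleton counts and their normalized proportions."""

    per_chromosome_counts: np.ndarray
    chromosome_ids: list[str]
    n_loci_skipped: int = 0

    def __post_init__(self) -> None:
        self.per_chromosome_counts = np.asarray(
            self.per_chromosome_counts, dtype=np.int64
        )
        if np.any(self.per_chromosome_counts < 0):
            raise ValueError("negative singleton count")

    @property
    def total(self) -> int:
        return int(self.per_chromosome_counts.sum())

    @property
    def defined(self) -> bool:
        """Proportions are defined only when the sample has singletons."""
        return self.total > 0

    @property
    def proportions(self) -> np.ndarray:
        if not self.defined:
            return np.full(len(self.per_chromosome_counts), np.nan)
        return self.per_chromosome_counts / self.total


@dataclass
class DiversitySummary:
    """Per-group summaries of the empirical distribution of singletons."""

    group_order: list
    mean_proportion: dict
    sd_proportion: dict
    group_sizes: dict
    ratio: float | None = None
    heterozygosity: dict | None = None
    defined: bool = True

    def as_dict(self) -> dict:
        out: dict = {}
        for g in self.group_order:
            out[f"pi_{g}"] = self.mean_proportion[g]
            out[f"sd_{g}"] = self.sd_proportion[g]
        if self.ratio is not None:
            out["ratio"] = self.ratio
        return out


def count_singletons(matrix: HaplotypeMatrix) -> SingletonProfile:
    """Count singletons carried by each chromosome.

    In the default (ancestral-known) mode a singleton is a locus where exactly
    one non-missing chromosome carries the derived allele.  In folded mode the
    minor allele plays the role of the derived allele, so a locus where the
    *ancestral* allele appears exactly once also contributes a singleton to
    its carrier.  Loci with fewer than two non-missing calls are skipped
    (singleton status is undefined there) and the skip count is logged.
    """
    a = matrix.alleles
    called = a != MISSING
    n_called = called.sum(axis=0)
    usable = n_called >= 2
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("count_singletons: skipped %d loci with <2 calls", n_skipped)

    derived = (a == 1) & called
    d_count = derived.sum(axis=0)

    counts = np.zeros(matrix.n_chromosomes, dtype=np.int64)
    sing = usable & (d_count == 1)
    if sing.any():
        rows = np.argmax(derived[:, sing], axis=0)
        np.add.at(counts, rows, 1)
    if matrix.folded:
        anc = (a == 0) & called
        sing0 = usable & (d_count == n_called - 1) & (n_called >= 2)
        if sing0.any():
            rows = np.argmax(anc[:, sing0], axis=0)
            np.add.at(counts, rows, 1)
    return SingletonProfile(counts, list(matrix.chromosome_ids), n_skipped)


def external_branch_lengths(
    tree: Genealogy, order: list[str] | None = None
) -> tuple[np.ndarray, float]:
    """External branch length per tip and their sum ``tau1``.

    Tips are ordered by ``order`` when given, otherwise by sorted tip label.
    """
    if order is None:
        order = sorted(tree.tip_labels)
    pos = {lab: i for i, lab in enumerate(tree.tip_labels)}
    try:
        ix = np.asarray([pos[lab] for lab in order])
    except KeyError as e:
        raise ValueError(f"tip label {e} not in tree") from None
    tau = tree.external_branch_lengths()[ix]
    return tau, float(tau.sum())


def theoretical_distribution(
    trees: list[Genealogy], order: list[str] | None = None
) -> np.ndarray:
    """Theoretical singleton distribution ``p_i`` from a set of genealogies.

    ``p_i`` is the mean over trees of ``tau_i / tau1``, with tips matched by
    label across trees.  Trees with zero total external length are excluded
    with a warning.
    """
    if not trees:
        raise ValueError("no trees given")
    labels = sorted(trees[0].tip_labels)
    if order is None:
        order = labels
    elif sorted(order) != labels:
        raise ValueError("order does not match the trees' tip label set")
    ratios = []
    for t in trees:
        if sorted(t.tip_labels) != labels:
            raise ValueError("trees do not share a tip label set")
        tau, tau1 = external_branch_lengths(t, order)
        if tau1 <= 0:
            warnings.warn("tree with zero total external length excluded")
            continue
        ratios.append(tau / tau1)
    if not ratios:
        raise ValueError("all trees had zero external length")
    return np.mean(ratios, axis=0)


def group_summaries(
    profile: SingletonProfile,
    groups: GroupAssignment,
    matrix: HaplotypeMatrix | None = None,
) -> DiversitySummary:
    """Per-group mean and SD of the singleton proportions ``p_hat_i``.

    For two groups the ratio of group means is reported in the user's group
    order (first label over second).  When ``matrix`` is given, per-group
    expected heterozygosity is attached as well.
    """
    idx = groups.indices(profile.chromosome_ids)
    order = groups.groups
    if not profile.defined:
        logger.warning("group_summaries: no singletons; summary undefined")
        nanmap = {g: float("nan") for g in order}
        return DiversitySummary(
            order, dict(nanmap), dict(nanmap),
            {g: len(ix) for g, ix in idx.items()},
            ratio=None, defined=False,
        )
    p = profile.proportions
    means = {g: float(p[ix].mean()) for g, ix in idx.items()}
    sds = {g: float(p[ix].std(ddof=1)) if len(ix) > 1 else 0.0 for g, ix in idx.items()}
    ratio = None
    if len(order) == 2:
        g1, g2 = order
        ratio = means[g1] / means[g2] if means[g2] > 0 else float("inf")
    het = expected_heterozygosity(matrix, groups) if matrix is not None else None
    return DiversitySummary(
        order, means, sds, {g: len(ix) for g, ix in idx.items()},
        ratio=ratio, heterozygosity=het,
    )


def expected_heterozygosity(
    matrix: HaplotypeMatrix, groups: GroupAssignment
) -> dict:
    """Unbiased expected heterozygosity per group.

    Per locus with ``k >= 2`` non-missing calls in the group and within-group
    derived-allele frequency ``p``, the unbiased estimator is
    ``2 p (1 - p) k / (k - 1)``; the group value is the mean over usable loci.
    """
    idx = groups.indices(matrix.chromosome_ids)
    out = {}
    for g, ix in idx.items():
        if len(ix) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 chromosomes")
        sub = matrix.alleles[ix]
        called = sub != MISSING
        k = called.sum(axis=0)
        ok = k >= 2
        if not ok.any():
            out[g] = float("nan")
            continue
        d = ((sub == 1) & called).sum(axis=0)[ok]
        kk = k[ok].astype(float)
        p = d / kk
        out[g] = float(np.mean(2.0 * p * (1.0 - p) * kk / (kk - 1.0)))
    return out


def site_frequency_spectrum(matrix: HaplotypeMatrix) -> np.ndarray:
    """Site frequency spectrum: entry ``j-1`` counts loci with ``j`` derived
    copies among non-missing calls, for ``j = 1 .. n-1``.

    Monomorphic loci (0 or all derived) are not represented.  In folded mode
    the spectrum is folded on the minor allele: entry ``j-1`` counts loci
    whose minor allele has ``j`` copies, ``j = 1 .. floor(n/2)``.
    """
    a = matrix.alleles
    n = matrix.n_chromosomes
    called = a != MISSING
    n_called = called.sum(axis=0)
    d = ((a == 1) & called).sum(axis=0)
    usable = n_called >= 2
    poly = usable & (d >= 1) & (d <= n_called - 1)
    if matrix.folded:
        counts = np.minimum(d[poly], (n_called - d)[poly])
        size = n // 2
    else:
        counts = d[poly]
        size = n - 1
    sfs = np.bincount(counts, minlength=size + 1)[1 : size + 1]
    return sfs


def filter_monomorphic(matrix: HaplotypeMatrix) -> HaplotypeMatrix:
    """Drop loci that are monomorphic among non-missing calls."""
    a = matrix.alleles
    called = a != MISSING
    n_called = called.sum(axis=0)
    d = ((a == 1) & called).sum(axis=0)
    keep = (n_called >= 1) & (d >= 1) & (d <= n_called - 1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_monomorphic: removed %d monomorphic loci", n_drop)
    return matrix.select_loci(keep)
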