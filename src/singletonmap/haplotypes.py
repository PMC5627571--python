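"""Haploid genotype matrices and sample group assignments.

The central container is :class:`HaplotypeMatrix`: ``n`` chromosomes typed at
``L`` biallelic loci, coded 0 for the ancestral (or reference) allele, 1 for
the derived allele, and :data:`MISSING` for a missing call.  All downstream
statistics (singleton counts, site frequency spectra, heterozygosity) operate
on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Sentinel for a missing call in the internal allele matrix.
MISSING: int = -1

#: Character used for missing calls in the .geno text format.
GENO_MISSING_CHAR = "9"


class InvalidMatrixError(ValueError):
    """Raised when a genotype matrix violates the container invariants."""


def _as_allele_array(alleles) -> np.ndarray:
    arr = np.asarray(alleles)
    if arr.ndim != 2:
        raise InvalidMatrixError(f"allele matrix must be 2-D, got shape {arr.shape}")
    arr = arr.astype(np.int8, copy=False)
    bad = ~np.isin(arr, (0, 1, MISSING))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise InvalidMatrixError(
            f"allele matrix entries must be 0, 1 or missing ({MISSING}); "
            f"found {arr[i, j]} at chromosome {i}, locus {j}"
        )
    return arr


@dataclass
class HaplotypeMatrix:
    """``n_chromosomes x n_loci`` matrix of haploid 0/1 calls.

    Parameters
    ----------
    alleles:
        Integer matrix with rows = chromosomes, columns = loci; entries in
        {0, 1, -1} where -1 (:data:`MISSING`) marks a missing call.
    chromosome_ids:
        Unique identifier per chromosome (row).  Defaults to ``c0..c{n-1}``.
    folded:
        If True the ancestral state is considered unknown and singleton /
        frequency-spectrum statistics fold on the minor allele.
    """

    alleles: np.ndarray
    chromosome_ids: list[str] = field(default=None)  # type: ignore[assignment]
    folded: bool = False

    def __post_init__(self) -> None:
        self.alleles = _as_allele_array(self.alleles)
        n = self.alleles.shape[0]
        if n < 2:
            raise InvalidMatrixError(f"need at least 2 chromosomes, got {n}")
        if self.chromosome_ids is None:
            self.chromosome_ids = [f"c{i}" for i in range(n)]
        else:
            self.chromosome_ids = [str(c) for c in self.chromosome_ids]
        if len(self.chromosome_ids) != n:
            raise InvalidMatrixError(
                f"{len(self.chromosome_ids)} chromosome ids for {n} rows"
            )
        if len(set(self.chromosome_ids)) != n:
            raise InvalidMatrixError("chromosome ids must be unique")

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.alleles == MISSING

    def missing_rate(self, per_chromosome: bool = False):
        """Fraction of missing calls, overall or per chromosome."""
        m = self.missing_mask
        return m.mean(axis=1) if per_chromosome else float(m.mean())

    def derived_counts(self) -> np.ndarray:
        """Per-locus count of derived (1) alleles among non-missing calls."""
        return (self.alleles == 1).sum(axis=0)

    def called_counts(self) -> np.ndarray:
        """Per-locus count of non-missing calls."""
        return (self.alleles != MISSING).sum(axis=0)

    def select_loci(self, keep: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.alleles[:, keep], list(self.chromosome_ids), self.folded
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"HaplotypeMatrix(n={self.n_chromosomes}, L={self.n_loci}, "
            f"folded={self.folded})"
        )


def concatenate(blocks: Sequence[HaplotypeMatrix]) -> HaplotypeMatrix:
    """Concatenate locus blocks that share the same chromosomes."""
    if not blocks:
        raise ValueError("no blocks to concatenate")
    ids = blocks[0].chromosome_ids
    for b in blocks[1:]:
        if b.chromosome_ids != ids:
            raise InvalidMatrixError("blocks have different chromosome ids")
    return HaplotypeMatrix(
        np.concatenate([b.alleles for b in blocks], axis=1),
        list(ids),
        blocks[0].folded,
    )


@dataclass
class GroupAssignment:
    """Assignment of every chromosome to exactly one group.

    ``labels`` maps chromosome id -> group label.  Group order is the order of
    first appearance unless explicitly given via ``group_order``.
    """

    labels: Mapping[str, object]
    group_order: list | None = None

    def __post_init__(self) -> None:
        self.labels = dict(self.labels)
        if not self.labels:
            raise ValueError("empty group assignment")
        seen: list = []
        for g in self.labels.values():
            if g not in seen:
                seen.append(g)
        if self.group_order is None:
            self.group_order = seen
        else:
            if set(self.group_order) != set(seen):
                raise ValueError("group_order does not match labels")

    @property
    def groups(self) -> list:
        return list(self.group_order)

    def members(self, group) -> list[str]:
        return [c for c, g in self.labels.items() if g == group]

    def indices(self, chromosome_ids: Sequence[str]) -> dict:
        """Map group -> integer row indices into ``chromosome_ids``."""
        pos = {c: i for i, c in enumerate(chromosome_ids)}
        missing = [c for c in self.labels if c not in pos]
        if missing:
            raise KeyError(f"chromosomes not present in matrix: {missing[:5]}")
        out: dict = {g: [] for g in self.group_order}
        for c, g in self.labels.items():
            out[g].append(pos[c])
        return {g: np.asarray(sorted(ix), dtype=int) for g, ix in out.items()}

    @classmethod
    def from_sequence(
        cls, chromosome_ids: Sequence[str], group_labels: Iterable
    ) -> "GroupAssignment":
        labels = dict(zip(chromosome_ids, group_labels, strict=True))
        return cls(labels)
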