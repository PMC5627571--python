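"""Readers and writers for the package's text formats.

Formats covered:

* ``.geno`` — one text line per locus, one character per chromosome, with
  ``0``/``1`` calls and ``9`` for missing (haploid dialect).  A transpose
  flag accommodates the chromosome-per-line dialect.
* VCF — biallelic SNPs with haploid genotypes, or diploid genotypes
  collapsed under a haploidization policy (inbred-line data are effectively
  haploid).
* Newick genealogies (via dendropy, through :class:`Genealogy`).
* ESRI ASCII grids for habitat rasters and interpolated surfaces.
* CSV coordinate tables and JSON run manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genealogy import Genealogy
from .haplotypes import MISSING, HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_geno",
    "write_geno",
    "read_vcf",
    "read_newick",
    "write_newick",
    "read_esri_ascii",
    "write_esri_ascii",
    "read_coordinates",
    "write_coordinates",
    "write_manifest",
]


class FormatError(ValueError):
    pass


# --------------------------------------------------------------------- #
# .geno                                                                 #
# --------------------------------------------------------------------- #
_GENO_MAP = {"0": 0, "1": 1, "9": MISSING}
_GENO_INV = {0: "0", 1: "1", MISSING: "9"}


def read_geno(
    path,
    chromosome_ids: list[str] | None = None,
    loci_as_rows: bool = True,
    folded: bool = False,
) -> HaplotypeMatrix:
    """Read a haploid ``.geno`` file.

    By default each line is a locus and each character a chromosome; set
    ``loci_as_rows=False`` for the transposed dialect.
    """
    rows: list[list[int]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if width is None:
                width = len(line)
            elif len(line) != width:
                raise FormatError(
                    f"{path}: ragged line {lineno} (expected {width} "
                    f"characters, got {len(line)})"
                )
            try:
                rows.append([_GENO_MAP[c] for c in line])
            except KeyError as e:
                raise FormatError(
                    f"{path}: illegal character {e} on line {lineno}"
                ) from None
    if not rows:
        raise FormatError(f"{path}: empty .geno file")
    arr = np.asarray(rows, dtype=np.int8)
    if loci_as_rows:
        arr = arr.T
    return HaplotypeMatrix(arr, chromosome_ids, folded=folded)


def write_geno(matrix: HaplotypeMatrix, path, loci_as_rows: bool = True) -> None:
    arr = matrix.alleles if not loci_as_rows else matrix.alleles.T
    with open(path, "w") as fh:
        for row in arr:
            fh.write("".join(_GENO_INV[int(v)] for v in row))
            fh.write("\n")


# --------------------------------------------------------------------- #
# VCF                                                                   #
# --------------------------------------------------------------------- #
def read_vcf(
    path,
    policy: str = "homozygous-collapse",
    rng: np.random.Generator | None = None,
    folded: bool = False,
) -> HaplotypeMatrix:
    """Read biallelic SNPs from a VCF into a haploid matrix.

    Policies for diploid genotypes:

    * ``"haploid"`` — genotypes must be haploid already; diploid records
      are an error.
    * ``"homozygous-collapse"`` (default) — 0/0 -> 0, 1/1 -> 1,
      heterozygotes -> missing; appropriate for inbred lines.
    * ``"random-allele"`` — one allele of each diploid genotype is chosen
      uniformly (requires ``rng``).

    Multiallelic and non-SNP records are skipped with a logged count.
    """
    import pysam

    if policy not in ("haploid", "homozygous-collapse", "random-allele"):
        raise ValueError(f"unknown haploidization policy: {policy!r}")
    if policy == "random-allele" and rng is None:
        raise ValueError("random-allele policy requires an rng")

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples")
    columns: list[list[int]] = []
    n_skipped = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped += 1
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            n_skipped += 1
            continue
        col = []
        for s in samples:
            gt = rec.samples[s].get("GT", (None,))
            alleles = [a for a in gt if a is not None]
            if not alleles:
                col.append(MISSING)
            elif len(alleles) == 1:
                col.append(int(alleles[0]))
            else:
                if policy == "haploid":
                    raise FormatError(
                        f"{path}: diploid genotype at {rec.chrom}:{rec.pos} "
                        "under the 'haploid' policy"
                    )
                if policy == "homozygous-collapse":
                    col.append(int(alleles[0]) if alleles[0] == alleles[1] else MISSING)
                else:
                    col.append(int(alleles[int(rng.integers(2))]))
        columns.append(col)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not columns:
        raise FormatError(f"{path}: no usable biallelic SNP records")
    return HaplotypeMatrix(
        np.asarray(columns, dtype=np.int8).T, samples, folded=folded
    )


# --------------------------------------------------------------------- #
# Newick                                                                #
# --------------------------------------------------------------------- #
def read_newick(path, units: str = "coalescent") -> list[Genealogy]:
    """Read one genealogy per non-empty line."""
    trees = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            trees.append(Genealogy.from_newick(line, units=units))
    if not trees:
        raise FormatError(f"{path}: no trees found")
    return trees


def write_newick(trees, path) -> None:
    if isinstance(trees, Genealogy):
        trees = [trees]
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


# --------------------------------------------------------------------- #
# ESRI ASCII grid                                                       #
# --------------------------------------------------------------------- #
def read_esri_ascii(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array, header) with NODATA as NaN.

    The array is row 0 = northernmost row, as stored in the file.
    """
    header: dict = {}
    values: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                values.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise FormatError(f"{path}: missing header field {req}")
    arr = np.asarray(values, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if arr.shape != (nrows, ncols):
        arr = arr.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return arr, header


def write_esri_ascii(
    arr: np.ndarray,
    path,
    xllcorner: float,
    yllcorner: float,
    cellsize: float,
    nodata: float = -9999.0,
) -> None:
    arr = np.asarray(arr, dtype=float)
    out = np.where(np.isnan(arr), nodata, arr)
    with open(path, "w") as fh:
        fh.write(f"ncols {arr.shape[1]}\n")
        fh.write(f"nrows {arr.shape[0]}\n")
        fh.write(f"xllcorner {xllcorner:.10g}\n")
        fh.write(f"yllcorner {yllcorner:.10g}\n")
        fh.write(f"cellsize {cellsize:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.10g}" for v in row))
            fh.write("\n")


# --------------------------------------------------------------------- #
# coordinates + manifests                                               #
# --------------------------------------------------------------------- #
def read_coordinates(path) -> pd.DataFrame:
    """Read a CSV of point coordinates with columns id, lon, lat[, value]."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for req in ("lon", "lat"):
        if req not in cols:
            raise FormatError(f"{path}: missing column {req!r}")
    df = df.rename(columns={v: k for k, v in cols.items()})
    if "id" not in df.columns:
        df.insert(0, "id", [f"s{i}" for i in range(len(df))])
    return df


def write_coordinates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_manifest(out_dir, config: dict, seed: int | None) -> Path:
    """Write a reproducibility manifest (config hash, seed, version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
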