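"""Contact-matrix data model, valid-pair binning, and text-format I/O.

All interval logic is 0-based half-open; conversion to 1-based coordinates
happens only when VCF is emitted (variants module).  Matrices are stored per
chromosome as dense symmetric arrays — every analysis in this package is
intra-chromosomal and the working scale is hundreds of bins per chromosome.

Inputs are assumed MAPQ- and duplicate-filtered upstream (the usual
MAPQ >= 10 / PCR-duplicate contract of Hi-C pair filtering); this module does
not re-check alignment quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PAIR_COLUMNS = ["read_id", "chrA", "posA", "strandA", "chrB", "posB", "strandB"]


@dataclass
class ContactMatrix:
    """Symmetric binned contact map for one chromosome.

    ``mask`` flags excluded bins (True = masked); masked rows/columns are
    zeroed.  ``bias`` is defined only for normalized matrices (provenance
    ``iced`` or ``caicb``) and is NaN on masked bins.
    """

    chrom: str
    resolution: int
    matrix: np.ndarray
    mask: np.ndarray = None
    bias: np.ndarray | None = None
    provenance: str = "raw"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, rtol=1e-8, atol=1e-8):
            raise ValueError("contact matrix must be symmetric")
        if self.mask is None:
            self.mask = np.zeros(len(self.matrix), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.matrix):
            raise ValueError("mask length must equal bin count")
        if self.provenance == "raw" and self.bias is not None:
            raise ValueError("raw matrices carry no bias vector")
        if self.mask.any():
            self.matrix[self.mask, :] = 0.0
            self.matrix[:, self.mask] = 0.0

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def scaled(self, factor: float) -> "ContactMatrix":
        return ContactMatrix(self.chrom, self.resolution, self.matrix * factor,
                             self.mask.copy(), None if self.bias is None
                             else self.bias.copy(), self.provenance)


@dataclass
class CoverageProfile:
    """Per-bin 1D coverage (contact-matrix row sums) — the CNV substrate."""

    chrom: str
    resolution: int
    values: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("coverage must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(len(self.values), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.values):
            raise ValueError("mask length must equal bin count")


def bin_valid_pairs(pairs, layout, resolution: int) -> tuple[dict[str, ContactMatrix], int]:
    """Bin a valid-pairs table into per-chromosome contact matrices.

    ``pairs`` is a DataFrame with columns ``read_id, chrA, posA, strandA,
    chrB, posB, strandB`` or a path to such a TSV (no header).  Each
    intra-chromosomal pair increments exactly one cell (stored symmetric);
    inter-chromosomal pairs are counted and otherwise ignored.  A pair naming
    an unknown chromosome raises with its (0-based) row number.
    """
    if isinstance(pairs, (str, Path)):
        pairs = read_valid_pairs(pairs)
    known = set(layout.chromosomes)
    for row, (ca, cb) in enumerate(zip(pairs["chrA"], pairs["chrB"])):
        if ca not in known or cb not in known:
            raise ValueError(f"unknown chromosome in pair at line {row}")

    mats = {c: np.zeros((-(-layout.lengths[c] // resolution),) * 2) for c in known}
    intra = pairs[pairs["chrA"] == pairs["chrB"]]
    n_inter = len(pairs) - len(intra)
    for chrom, grp in intra.groupby("chrA", sort=False):
        n = mats[chrom].shape[0]
        bi = grp["posA"].to_numpy() // resolution
        bj = grp["posB"].to_numpy() // resolution
        if (bi >= n).any() or (bj >= n).any() or (bi < 0).any() or (bj < 0).any():
            raise ValueError(f"pair position outside {chrom}")
        lo, hi = np.minimum(bi, bj), np.maximum(bi, bj)
        np.add.at(mats[chrom], (lo, hi), 1.0)
    out = {}
    for chrom, m in mats.items():
        full = m + np.triu(m, k=1).T
        out[chrom] = ContactMatrix(chrom=chrom, resolution=resolution, matrix=full)
    return out, n_inter


def coverage_from_matrix(matrix: ContactMatrix) -> CoverageProfile:
    """Row sums of a raw matrix (diagonal counted once); masked bins are 0.

    Normalized input is rejected: copy-number inference needs the raw signal.
    """
    if matrix.provenance != "raw":
        raise ValueError("coverage requires a raw matrix (CNV needs raw signal)")
    cov = matrix.matrix.sum(axis=1)
    cov[matrix.mask] = 0.0
    return CoverageProfile(chrom=matrix.chrom, resolution=matrix.resolution,
                           values=cov, mask=matrix.mask.copy())


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------

def write_valid_pairs(pairs: pd.DataFrame, path) -> None:
    pairs[PAIR_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_valid_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=PAIR_COLUMNS)


def write_triplets(matrix: ContactMatrix, matrix_path, bed_path, chrom_length: int | None = None) -> None:
    """Sparse upper-triangle triplets (binA, binB, count) plus a bin BED."""
    iu = np.triu_indices(matrix.n_bins)
    counts = matrix.matrix[iu]
    keep = counts != 0
    pd.DataFrame({"binA": iu[0][keep], "binB": iu[1][keep],
                  "count": counts[keep]}).to_csv(
        matrix_path, sep="\t", header=False, index=False)
    res = matrix.resolution
    length = chrom_length if chrom_length is not None else matrix.n_bins * res
    starts = np.arange(matrix.n_bins) * res
    pd.DataFrame({"chrom": matrix.chrom, "start": starts,
                  "end": np.minimum(starts + res, length),
                  "index": np.arange(matrix.n_bins)}).to_csv(
        bed_path, sep="\t", header=False, index=False)


def read_triplets(matrix_path, bed_path) -> ContactMatrix:
    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["chrom", "start", "end", "index"])
    n = len(bed)
    resolution = int(bed["end"].iloc[0] - bed["start"].iloc[0]) if n > 1 else int(bed["end"].iloc[0])
    if n > 1:
        resolution = int(bed["start"].iloc[1] - bed["start"].iloc[0])
    m = np.zeros((n, n))
    trip = pd.read_csv(matrix_path, sep="\t", header=None,
                       names=["binA", "binB", "count"])
    m[trip["binA"], trip["binB"]] = trip["count"]
    m = np.triu(m) + np.triu(m, k=1).T
    return ContactMatrix(chrom=bed["chrom"].iloc[0], resolution=resolution, matrix=m)


def write_dense_tsv(matrix: ContactMatrix, path) -> None:
    np.savetxt(path, matrix.matrix, delimiter="\t", fmt="%.6g")


def write_bedgraph(chrom: str, resolution: int, values: np.ndarray, path,
                   chrom_length: int | None = None) -> None:
    """Per-bin track as bedGraph; NaN bins are skipped."""
    starts = np.arange(len(values)) * resolution
    length = chrom_length if chrom_length is not None else len(values) * resolution
    df = pd.DataFrame({"chrom": chrom, "start": starts,
                       "end": np.minimum(starts + resolution, length),
                       "value": values})
    df[np.isfinite(df["value"])].to_csv(path, sep="\t", header=False, index=False)
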