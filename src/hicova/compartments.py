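"""A/B compartment calling and paired-sample switch classification.

Compartments are called at coarse resolution (500 kb by default) from the
first principal component of the Pearson correlation matrix of the
observed/expected map.  The PC1 sign is arbitrary; orientation follows the
convention that the A compartment is gene-dense: the sign is flipped if
needed so the positive-sign group has the higher mean gene density, then
positive bins are labeled A and negative bins B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .normalization import oe_transform

COMPARTMENT_RESOLUTION = 500_000
MIN_UNMASKED_BINS = 20


@dataclass
class CompartmentProfile:
    """Per-bin PC1 values with A/B labels for one chromosome.

    ``labels`` hold 'A', 'B', or '' (NA, where PC1 is undefined).
    ``gene_density_a``/``gene_density_b`` record the orientation evidence.
    """

    chrom: str
    resolution: int
    pc1: np.ndarray
    labels: np.ndarray
    gene_density_a: float
    gene_density_b: float

    @property
    def defined(self) -> np.ndarray:
        return self.labels != ""


@dataclass
class SwitchTable:
    """Per-bin switch classes between two samples plus genome fractions."""

    chrom: str
    classes: np.ndarray                 # 'A->A', 'A->B', 'B->A', 'B->B', ''
    fractions: dict[str, float]         # over bins defined in both samples

    @property
    def switched_fraction(self) -> float:
        return self.fractions["A->B"] + self.fractions["B->A"]


def gene_density_per_bin(layout, chrom: str, resolution: int) -> np.ndarray:
    """Aggregate the layout's per-bin gene density onto ``resolution`` bins."""
    g = layout.chrom_bins(chrom)
    n = -(-layout.lengths[chrom] // resolution)
    idx = (g["start"].to_numpy() // resolution).astype(int)
    return np.bincount(idx, weights=g["gene_density"].to_numpy(), minlength=n)


def compartment_profile(matrix: ContactMatrix, layout) -> CompartmentProfile:
    """Call A/B compartments from a normalized coarse-resolution matrix.

    O/E transform -> Pearson correlation over unmasked bins -> leading
    eigenvector -> sign oriented by gene density (A = gene dense).
    Degenerate (constant) correlation input yields all-NA with a warning.
    """
    if matrix.provenance == "raw":
        raise ValueError("compartment calling expects a normalized matrix")
    mask = matrix.mask | (matrix.matrix.sum(axis=1) == 0)
    n = matrix.n_bins
    keep = np.flatnonzero(~mask)
    labels = np.full(n, "", dtype=object)
    pc1 = np.full(n, np.nan)
    if len(keep) < MIN_UNMASKED_BINS:
        raise ValueError(f"need >= {MIN_UNMASKED_BINS} unmasked bins, got {len(keep)}")

    oe = oe_transform(matrix)
    sub = oe[np.ix_(keep, keep)]
    np.fill_diagonal(sub, np.nan)
    col_mean = np.nanmean(sub, axis=0)
    inds = np.where(np.isnan(sub))
    sub[inds] = col_mean[inds[1]]

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    if not np.isfinite(corr).all() or np.allclose(corr, corr[0, 0]):
        warnings.warn(f"{matrix.chrom}: degenerate correlation matrix; all bins NA")
        return CompartmentProfile(matrix.chrom, matrix.resolution, pc1,
                                  labels.astype(str), np.nan, np.nan)

    eigvals, eigvecs = np.linalg.eigh(corr)
    vec = eigvecs[:, -1]

    dens = gene_density_per_bin(layout, matrix.chrom, matrix.resolution)[keep]
    vec = orient_by_gene_density(vec, dens)

    pc1[keep] = vec
    labels[keep] = np.where(vec >= 0, "A", "B")
    pos, neg = vec >= 0, vec < 0
    return CompartmentProfile(
        chrom=matrix.chrom, resolution=matrix.resolution, pc1=pc1,
        labels=labels.astype(str),
        gene_density_a=float(dens[pos].mean()) if pos.any() else np.nan,
        gene_density_b=float(dens[neg].mean()) if neg.any() else np.nan,
    )


def orient_by_gene_density(pc1: np.ndarray, gene_density: np.ndarray) -> np.ndarray:
    """Flip PC1 sign if the negative group is more gene-dense than the positive."""
    pos, neg = pc1 >= 0, pc1 < 0
    if pos.any() and neg.any() and gene_density[pos].mean() < gene_density[neg].mean():
        return -pc1
    return pc1


def switch_table(profile_n: CompartmentProfile, profile_t: CompartmentProfile) -> SwitchTable:
    """Cross-classify bins between paired samples (e.g. normal vs tumor)."""
    if profile_n.resolution != profile_t.resolution:
        raise ValueError("resolution mismatch")
    if len(profile_n.labels) != len(profile_t.labels):
        raise ValueError("bin-count mismatch")
    both = profile_n.defined & profile_t.defined
    classes = np.full(len(both), "", dtype=object)
    classes[both] = [f"{a}->{b}" for a, b in
                     zip(profile_n.labels[both], profile_t.labels[both])]
    denom = max(int(both.sum()), 1)
    fractions = {key: float(np.sum(classes == key)) / denom
                 for key in ("A->A", "A->B", "B->A", "B->B")}
    return SwitchTable(chrom=profile_n.chrom, classes=classes.astype(str),
                       fractions=fractions)


def constitutive_states(profiles: list[CompartmentProfile]) -> np.ndarray:
    """Per-bin state: 'A'/'B' where all profiles agree, 'variable' otherwise,
    '' where any profile is NA."""
    if not profiles:
        raise ValueError("need at least one profile")
    if len(profiles) < 2:
        raise ValueError("constitutive states need >= 2 profiles")
    labels = np.vstack([p.labels for p in profiles])
    out = np.full(labels.shape[1], "", dtype=object)
    defined = (labels != "").all(axis=0)
    agree = (labels == labels[0]).all(axis=0)
    out[defined & agree] = labels[0][defined & agree]
    out[defined & ~agree] = "variable"
    return out.astype(str)


def switch_table_to_bed(table: SwitchTable, resolution: int, chrom_length: int) -> pd.DataFrame:
    starts = np.arange(len(table.classes)) * resolution
    df = pd.DataFrame({"chrom": table.chrom, "start": starts,
                       "end": np.minimum(starts + resolution, chrom_length),
                       "name": table.classes})
    return df[df["name"] != ""].reset_index(drop=True)
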