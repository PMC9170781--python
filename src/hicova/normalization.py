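"""Matrix balancing and reproducibility.

Implements iterative correction (ICE) of per-bin multiplicative biases, a
copy-number-aware chromosome/segment-level adjustment in the spirit of caICB
(per-segment distance-stratified intercept correction on the log-log decay
fit), the distance-decay expected model with an optional isotonic fit, the
observed/expected transform, and a HiCRep-style stratum-adjusted correlation
coefficient (SCC) for reproducibility scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from .contacts import ContactMatrix

ICE_TOLERANCE = 1e-5
ICE_MAX_ITER = 200
SCC_SMOOTHING_WINDOW = 1     # half-width in bins (3x3 mean filter)
SCC_MAX_DISTANCE = 5_000_000


def marginal_spread(matrix: np.ndarray, mask: np.ndarray) -> float:
    """Max relative deviation of unmasked marginals from their mean."""
    marg = matrix.sum(axis=1)[~mask]
    if len(marg) == 0 or marg.mean() == 0:
        return np.inf
    return float(np.max(np.abs(marg - marg.mean())) / marg.mean())


def ice_normalize(
    matrix: ContactMatrix,
    tolerance: float = ICE_TOLERANCE,
    max_iterations: int = ICE_MAX_ITER,
) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative proportional fitting until unmasked marginals equalize.

    Returns the balanced matrix (``M'_ij = M_ij / (b_i b_j)``) and the bias
    vector, rescaled to mean 1 over unmasked bins and NaN on masked bins
    (zero-coverage bins are masked before balancing).  Non-convergence at
    ``max_iterations`` is reported with the final marginal spread.
    """
    if matrix.provenance != "raw":
        raise ValueError("ICE expects a raw matrix")
    m = matrix.matrix.copy()
    mask = matrix.mask | (m.sum(axis=1) == 0)
    m[mask, :] = 0.0
    m[:, mask] = 0.0

    bias = np.ones(len(m))
    converged = False
    for _ in range(max_iterations):
        marg = m.sum(axis=1)
        mean = marg[~mask].mean()
        db = np.where(mask, 1.0, marg / mean)
        db[db == 0] = 1.0
        m /= np.outer(db, db)
        bias *= db
        if marginal_spread(m, mask) <= tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iterations} iterations "
            f"(final marginal spread {marginal_spread(m, mask):.3g})")

    scale = bias[~mask].mean()
    bias /= scale
    m *= scale ** 2
    bias_out = np.where(mask, np.nan, bias)
    iced = ContactMatrix(matrix.chrom, matrix.resolution, m, mask,
                         bias=bias_out, provenance="iced")
    return iced, bias_out


def caicb_adjust(
    iced: ContactMatrix,
    segments: list[tuple[int, int]] | None = None,
    min_segment_bins: int = 10,
) -> ContactMatrix:
    """Segment-level decay-intercept correction of residual copy-number scale.

    Fits a chromosome-wide linear regression of log contact on log genomic
    distance, then for each segment computes the mean log-residual of
    within-segment contacts and divides the segment's rows and columns by
    ``exp(residual / 2)``, so distance-stratified means agree across segments.
    With no segments the whole chromosome is one segment (factors ~ 1).
    """
    if iced.provenance != "iced":
        raise ValueError("caICB adjustment expects an ICE-normalized matrix")
    n = iced.n_bins
    if segments is None:
        segments = [(0, n)]
    m = iced.matrix.copy()
    mask = iced.mask

    iu, ju = np.triu_indices(n, k=1)
    ok = (~mask[iu]) & (~mask[ju]) & (m[iu, ju] > 0)
    iu, ju = iu[ok], ju[ok]
    logc = np.log(m[iu, ju])
    logd = np.log((ju - iu).astype(float))
    slope, intercept = np.polyfit(logd, logc, 1)
    resid = logc - (slope * logd + intercept)

    factors = np.ones(n)
    for s, e in segments:
        nbins = int(np.sum(~mask[s:e]))
        if nbins < min_segment_bins:
            warnings.warn(f"segment [{s}, {e}) has {nbins} bins; left unadjusted")
            continue
        inside = (iu >= s) & (iu < e) & (ju >= s) & (ju < e)
        if inside.sum() < 3:
            continue
        factors[s:e] = np.exp(resid[inside].mean() / 2.0)

    adj = m / np.outer(factors, factors)
    bias = None if iced.bias is None else iced.bias * factors
    return ContactMatrix(iced.chrom, iced.resolution, adj, mask.copy(),
                         bias=bias, provenance="caicb")


# ---------------------------------------------------------------------------
# Expected-by-distance model
# ---------------------------------------------------------------------------

@dataclass
class DecayCurve:
    """Mean contact per genomic-distance stratum (stratum width = resolution)."""

    resolution: int
    distances: np.ndarray          # bp, center-to-center bin separation
    values: np.ndarray
    isotonic: np.ndarray           # non-increasing fit of values
    interpolated: np.ndarray       # flags strata filled from neighbors

    def __call__(self, distance_bins: np.ndarray) -> np.ndarray:
        """Expected value at a separation of ``distance_bins`` bins."""
        idx = np.clip(np.asarray(distance_bins, dtype=int) - 1, 0,
                      len(self.values) - 1)
        return self.values[idx]


def expected_by_distance(matrix: ContactMatrix) -> DecayCurve:
    """Distance-stratified expected contact with an isotonic (non-increasing) fit.

    Empty strata are linearly interpolated from neighbors and flagged.
    """
    n = matrix.n_bins
    mask = matrix.mask
    means = np.full(n - 1, np.nan)
    for d in range(1, n):
        i = np.arange(n - d)
        ok = (~mask[i]) & (~mask[i + d])
        if ok.any():
            means[d - 1] = matrix.matrix[i[ok], i[ok] + d].mean()
    interpolated = ~np.isfinite(means)
    if interpolated.all():
        raise ValueError("no defined distance strata")
    idx = np.arange(n - 1)
    means[interpolated] = np.interp(idx[interpolated], idx[~interpolated],
                                    means[~interpolated])
    means = np.maximum(means, np.finfo(float).tiny)
    iso = IsotonicRegression(increasing=False).fit_transform(idx, means)
    return DecayCurve(resolution=matrix.resolution,
                      distances=(idx + 1) * matrix.resolution,
                      values=means, isotonic=np.maximum(iso, np.finfo(float).tiny),
                      interpolated=interpolated)


def oe_transform(matrix: ContactMatrix, curve: DecayCurve | None = None) -> np.ndarray:
    """Observed/expected matrix; masked bins and the diagonal are NaN."""
    if curve is None:
        curve = expected_by_distance(matrix)
    n = matrix.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    exp = np.full((n, n), np.nan)
    off = d > 0
    exp[off] = curve(d[off])
    oe = matrix.matrix / exp
    oe[matrix.mask, :] = np.nan
    oe[:, matrix.mask] = np.nan
    return oe


# ---------------------------------------------------------------------------
# Reproducibility (stratum-adjusted correlation)
# ---------------------------------------------------------------------------

def scc(
    matrix_a: ContactMatrix,
    matrix_b: ContactMatrix,
    smoothing_window: int = SCC_SMOOTHING_WINDOW,
    max_distance: int = SCC_MAX_DISTANCE,
) -> float:
    """Stratum-adjusted correlation coefficient between two maps.

    Both matrices are mean-filter smoothed (window half-width in bins), then
    per-distance-stratum Pearson correlations are combined as a weighted
    average with weights ``N_k * sqrt(var(rank x) * var(rank y))`` — the
    variance-stabilized weighting of the HiCRep statistic.  Bounded in
    [-1, 1]; invariant to positive scaling of either matrix.
    """
    if matrix_a.resolution != matrix_b.resolution:
        raise ValueError("resolution mismatch")
    if matrix_a.n_bins != matrix_b.n_bins:
        raise ValueError("bin-count mismatch")
    size = 2 * smoothing_window + 1
    a = uniform_filter(matrix_a.matrix, size=size, mode="nearest")
    b = uniform_filter(matrix_b.matrix, size=size, mode="nearest")
    mask = matrix_a.mask | matrix_b.mask
    n = matrix_a.n_bins
    max_d = min(n - 1, max_distance // matrix_a.resolution)

    num = den = 0.0
    for d in range(1, max_d + 1):
        i = np.arange(n - d)
        ok = (~mask[i]) & (~mask[i + d])
        x, y = a[i[ok], i[ok] + d], b[i[ok], i[ok] + d]
        if len(x) < 3 or x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        w = len(x) * np.sqrt(rankdata(x).var() * rankdata(y).var())
        num += w * r
        den += w
    if den == 0:
        raise ValueError("no informative strata for SCC")
    return float(np.clip(num / den, -1.0, 1.0))
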