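"""Copy-number inference from Hi-C 1D coverage.

Pipeline: covariate filtering (drop bins with GC < 0.2 or mappability
< 0.5, strict thresholds), local-regression normalization of coverage
against GC and restriction-fragment count, moving-median smoothing, then a
hidden-Markov segmentation with Gaussian emissions centered at c/2 for copy
states c = 0..4 decoded by Viterbi.  Profile comparison against reference
copy-ratio tracks is plain Pearson correlation, ranked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .contacts import CoverageProfile

GC_MIN = 0.2
MAPPABILITY_MIN = 0.5
MAX_COPY_STATE = 4
SMOOTHING_SPAN_BINS = 25
STATE_SWITCH_PROB = 1e-3
EMISSION_SD_FLOOR = 0.05
LOWESS_FRAC = 0.5
MIN_BINS_FOR_FIT = 50


@dataclass
class CnvSegments:
    """Integer-copy-state segments tiling the unmasked bins of one chromosome."""

    chrom: str
    resolution: int
    segments: pd.DataFrame    # start, end (bp), state, mean_coverage
    copy_ratio: np.ndarray    # per-bin normalized coverage (NaN on masked)

    @property
    def fraction_altered(self) -> float:
        seg = self.segments
        total = (seg["end"] - seg["start"]).sum()
        if total == 0:
            return 0.0
        altered = seg.loc[seg["state"] != 2, "end"].sub(
            seg.loc[seg["state"] != 2, "start"]).sum()
        return float(altered / total)

    def state_per_bin(self, n_bins: int) -> np.ndarray:
        states = np.full(n_bins, -1)
        res = self.resolution
        for r in self.segments.itertuples():
            states[r.start // res: -(-r.end // res)] = r.state
        return states


def filter_bins(
    coverage: CoverageProfile,
    layout,
    gc_min: float = GC_MIN,
    map_min: float = MAPPABILITY_MIN,
) -> CoverageProfile:
    """Mask bins with GC < gc_min or mappability < map_min (strict <).

    Bin-level analog of the fragment-level covariate filter used for Hi-C
    CNV calling; a bin exactly at a threshold is kept.
    """
    bins = layout.chrom_bins(coverage.chrom)
    if len(bins) != len(coverage.values):
        raise ValueError("layout does not match coverage bin count")
    if bins["gc"].isna().any() or bins["mappability"].isna().any():
        raise ValueError("missing GC/mappability covariates")
    bad = (bins["gc"].to_numpy() < gc_min) | (bins["mappability"].to_numpy() < map_min)
    values = coverage.values.copy()
    values[bad] = 0.0
    return CoverageProfile(chrom=coverage.chrom, resolution=coverage.resolution,
                           values=values, mask=coverage.mask | bad)


def normalize_coverage(coverage: CoverageProfile, layout) -> CoverageProfile:
    """Remove GC and fragment-count trends by lowess; rescale to median 1.

    Falls back to plain median scaling (with a warning) when too few bins
    are available for a stable local-regression fit.
    """
    bins = layout.chrom_bins(coverage.chrom)
    ok = ~coverage.mask
    pos = ok & (coverage.values > 0)   # fit the trend on informative bins only
    values = coverage.values.astype(float).copy()
    if pos.sum() < MIN_BINS_FOR_FIT:
        warnings.warn("too few bins for covariate fit; median scaling only")
    else:
        for covariate in ("gc", "frag_count"):
            x = bins[covariate].to_numpy(dtype=float)[pos]
            fit = lowess(values[pos], x, frac=LOWESS_FRAC, return_sorted=False)
            fit = np.maximum(fit, np.finfo(float).tiny)
            values[pos] = values[pos] / fit * fit.mean()
    med = np.median(values[ok]) if ok.any() else 1.0
    if med > 0:
        values = values / med
    values[~ok] = 0.0
    return CoverageProfile(chrom=coverage.chrom, resolution=coverage.resolution,
                           values=values, mask=~ok)


def neighborhood_adjust(
    coverage: CoverageProfile,
    decay_exponent: float = 1.0,
    n_iterations: int = 20,
) -> CoverageProfile:
    """Deconvolve the neighbor copy-number effect from Hi-C marginal coverage.

    The marginal coverage of bin i in a contact map scales as
    ``(c_i/2) * sum_j w_ij (c_j/2)`` with distance-decay weights w — a gained
    region inflates its own bins' coverage twice (both contact endpoints).
    Fixed-point iteration of ``r_i <- cov_i / sum_j w_ij r_j`` (median-1
    rescaled) recovers a per-bin copy ratio proportional to c/2.
    """
    ok = ~coverage.mask
    n = len(coverage.values)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    with np.errstate(divide="ignore"):
        w = np.where(d > 0, d ** -decay_exponent, 0.0)
    w[~ok, :] = 0.0
    w[:, ~ok] = 0.0
    cov = coverage.values.copy()
    r = np.where(ok, 1.0, 0.0)
    for _ in range(n_iterations):
        denom = w @ r
        denom[denom <= 0] = np.nan
        with np.errstate(invalid="ignore"):
            r_new = np.where(ok, cov / denom, 0.0)
        r_new = np.nan_to_num(r_new, nan=0.0)
        med = np.median(r_new[ok & (r_new > 0)]) if (ok & (r_new > 0)).any() else 1.0
        r = r_new / med if med > 0 else r_new
    return CoverageProfile(chrom=coverage.chrom, resolution=coverage.resolution,
                           values=r, mask=coverage.mask.copy())


# ---------------------------------------------------------------------------
# HMM segmentation
# ---------------------------------------------------------------------------

def viterbi_gaussian(
    observations: np.ndarray,
    means: np.ndarray,
    sd: float,
    switch_prob: float,
) -> np.ndarray:
    """Viterbi path for a uniform-prior HMM with Gaussian emissions.

    Transition matrix: stay with probability 1 - switch_prob, move to any
    other state with switch_prob / (k - 1).
    """
    k = len(means)
    log_stay = np.log(1 - switch_prob)
    log_move = np.log(switch_prob / (k - 1))
    trans = np.full((k, k), log_move)
    np.fill_diagonal(trans, log_stay)
    emit = -0.5 * ((observations[:, None] - means[None, :]) / sd) ** 2
    score = np.full(k, -np.log(k)) + emit[0]
    back = np.zeros((len(observations), k), dtype=int)
    for t in range(1, len(observations)):
        cand = score[:, None] + trans
        back[t] = cand.argmax(axis=0)
        score = cand.max(axis=0) + emit[t]
    path = np.empty(len(observations), dtype=int)
    path[-1] = int(score.argmax())
    for t in range(len(observations) - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def moving_median(values: np.ndarray, span: int) -> np.ndarray:
    if span <= 1:
        return values.copy()
    half = span // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        out[i] = np.median(values[max(i - half, 0): i + half + 1])
    return out


def segment_copy_number(
    coverage: CoverageProfile,
    max_state: int = MAX_COPY_STATE,
    smoothing_span: int = SMOOTHING_SPAN_BINS,
    switch_prob: float = STATE_SWITCH_PROB,
    sd_floor: float = EMISSION_SD_FLOOR,
    adjust_neighbor_effect: bool = True,
    decay_exponent: float = 1.0,
) -> CnvSegments:
    """Moving-median smoothing + Gaussian-emission HMM over copy ratios.

    By default the Hi-C neighbor copy-number effect is first deconvolved
    (see :func:`neighborhood_adjust`).  Emissions are centered at c/2 for
    c = 0..max_state; the emission SD is estimated from the median absolute
    deviation of the smoothed unmasked coverage (floored).  Adjacent
    equal-state runs merge into segments.
    """
    if adjust_neighbor_effect:
        coverage = neighborhood_adjust(coverage, decay_exponent=decay_exponent)
    ok = ~coverage.mask
    n = len(coverage.values)
    if not ok.any():
        return CnvSegments(chrom=coverage.chrom, resolution=coverage.resolution,
                           segments=pd.DataFrame(columns=["start", "end", "state",
                                                          "mean_coverage"]),
                           copy_ratio=np.full(n, np.nan))
    idx = np.flatnonzero(ok)
    smooth = moving_median(coverage.values[idx], smoothing_span)
    mad = np.median(np.abs(smooth - np.median(smooth)))
    sd = max(1.4826 * mad, sd_floor)
    means = np.arange(max_state + 1) / 2.0
    path = viterbi_gaussian(smooth, means, sd, switch_prob)

    ratio = np.full(n, np.nan)
    ratio[idx] = coverage.values[idx]
    res = coverage.resolution
    rows = []
    run_start = 0
    for t in range(1, len(path) + 1):
        if t == len(path) or path[t] != path[run_start]:
            b0, b1 = idx[run_start], idx[t - 1]
            rows.append((int(b0) * res, int(b1 + 1) * res, int(path[run_start]),
                         float(smooth[run_start:t].mean())))
            run_start = t
    segments = pd.DataFrame(rows, columns=["start", "end", "state", "mean_coverage"])
    return CnvSegments(chrom=coverage.chrom, resolution=coverage.resolution,
                       segments=segments, copy_ratio=ratio)


def compare_profiles(
    copy_ratio: np.ndarray,
    references: dict[str, np.ndarray],
    min_shared_bins: int = 20,
) -> pd.DataFrame:
    """Pearson correlation against named reference copy-ratio tracks, ranked.

    Only bins finite in both tracks enter each correlation; references with
    fewer than ``min_shared_bins`` shared bins are skipped with a warning.
    """
    rows = []
    for name, ref in references.items():
        ref = np.asarray(ref, dtype=float)
        if len(ref) != len(copy_ratio):
            raise ValueError(f"reference '{name}' is on a different bin grid")
        ok = np.isfinite(copy_ratio) & np.isfinite(ref)
        if ok.sum() < min_shared_bins:
            warnings.warn(f"reference '{name}': only {int(ok.sum())} shared bins; skipped")
            continue
        x, y = copy_ratio[ok], ref[ok]
        if x.std() == 0 or y.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append((name, r, int(ok.sum())))
    out = pd.DataFrame(rows, columns=["reference", "pearson_r", "n_bins"])
    return out.sort_values("pearson_r", ascending=False).reset_index(drop=True)


def segments_to_bed(cnv: CnvSegments) -> pd.DataFrame:
    seg = cnv.segments
    return pd.DataFrame({"chrom": cnv.chrom, "start": seg["start"],
                         "end": seg["end"], "name": "cnv",
                         "score": seg["state"]})
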