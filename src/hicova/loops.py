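"""Chromatin-loop calling, donut-style local refinement, and APA.

The primary caller tests each candidate bin pair against a distance-decay +
bias expected model with an upper-tail binomial test (n = total
intra-chromosomal contacts, p = expected/total), followed by
Benjamini-Hochberg correction; significant interactions are kept at
q < 0.01.  An optional refinement step retains only loops enriched over
four local neighborhoods (donut, lower-left, horizontal, vertical), in the
spirit of the HiCCUPS filters.  Aggregate peak analysis (APA) averages O/E
windows centered on the called loops; the enrichment score is the center
pixel over the mean of the lower-left corner block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .contacts import ContactMatrix
from .normalization import DecayCurve, oe_transform

Q_THRESHOLD = 0.01
MIN_SEPARATION_BINS = 2
MAX_LOOP_DISTANCE_BP = 2_000_000
DONUT_RATIOS = {"donut": 1.5, "lower_left": 1.75, "horizontal": 2.0, "vertical": 2.0}
PEAK_WIDTH = 1
DONUT_WIDTH = 3
APA_HALF_WINDOW = 5


@dataclass
class LoopSet:
    """Called loops plus the parameter snapshot that produced them."""

    chrom: str
    resolution: int
    loops: pd.DataFrame   # bin_i, bin_j (i<j), observed, expected, p, q
    params: dict

    def __len__(self) -> int:
        return len(self.loops)


@dataclass
class ApaResult:
    """Aggregate O/E submatrix around loops and its center enrichment score."""

    matrix: np.ndarray
    score: float
    n_loops: int


def call_loops_decay(
    matrix: ContactMatrix,
    bias: np.ndarray,
    curve: DecayCurve,
    q_threshold: float = Q_THRESHOLD,
    min_separation: int = MIN_SEPARATION_BINS,
    max_distance: int = MAX_LOOP_DISTANCE_BP,
    p_mode: str = "exact",
    seed: int = 0,
) -> LoopSet:
    """Binomial significance of observed counts against decay x bias expectation.

    ``curve`` must come from the bias-corrected matrix so that
    ``curve(d) * b_i * b_j`` is the raw-scale expectation.  ``p_mode='exact'``
    is the conservative upper tail P(X >= x); ``p_mode='randomized'`` draws
    p = P(X > x) + U * P(X = x), which is exactly Uniform(0,1) under the null
    and is intended for calibration checks, not for calling.
    """
    if matrix.provenance != "raw":
        raise ValueError("loop calling expects raw counts")
    if bias is None:
        raise ValueError("bias vector required")
    if p_mode not in ("exact", "randomized"):
        raise ValueError("p_mode must be 'exact' or 'randomized'")

    n = matrix.n_bins
    mask = matrix.mask | ~np.isfinite(bias)
    max_d = min(n - 1, max_distance // matrix.resolution)
    iu, ju = np.triu_indices(n, k=min_separation)
    keep = (ju - iu <= max_d) & ~mask[iu] & ~mask[ju]
    iu, ju = iu[keep], ju[keep]

    obs = matrix.matrix[iu, ju]
    expected = curve(ju - iu) * bias[iu] * bias[ju]
    total = matrix.matrix[np.triu_indices(n, k=1)].sum()
    pe = np.clip(expected / total, 0, 1)

    obs_int = obs.astype(int)
    if p_mode == "exact":
        p = binom.sf(obs_int - 1, int(total), pe)          # P(X >= obs)
    else:
        rng = np.random.default_rng(seed)
        tail = binom.sf(obs_int, int(total), pe)           # P(X > obs)
        point = binom.pmf(obs_int, int(total), pe)
        p = tail + rng.random(len(obs_int)) * point
    p = np.clip(p, 0, 1)
    q = multipletests(p, method="fdr_bh")[1]

    df = pd.DataFrame({"bin_i": iu, "bin_j": ju, "observed": obs,
                       "expected": expected, "p": p, "q": q})
    called = df[df["q"] < q_threshold].reset_index(drop=True)
    called = _deduplicate_local_maxima(called)
    params = dict(q_threshold=q_threshold, min_separation=min_separation,
                  max_distance=max_distance, p_mode=p_mode, n_tested=len(df))
    ls = LoopSet(chrom=matrix.chrom, resolution=matrix.resolution,
                 loops=called, params=params)
    ls.tested = df  # full table kept for calibration diagnostics
    return ls


def _deduplicate_local_maxima(called: pd.DataFrame) -> pd.DataFrame:
    """Keep only pixels that are local maxima of observed count within 1 bin."""
    if called.empty:
        return called
    by_pos = {(r.bin_i, r.bin_j): r.observed for r in called.itertuples()}
    keep = []
    for r in called.itertuples():
        neighborhood = [by_pos.get((r.bin_i + di, r.bin_j + dj), -1)
                        for di in (-1, 0, 1) for dj in (-1, 0, 1)
                        if (di, dj) != (0, 0)]
        if r.observed >= max(neighborhood):
            keep.append(r.Index)
    return called.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Donut refinement
# ---------------------------------------------------------------------------

def _neighborhood_masks(peak_width: int, donut_width: int):
    """Boolean masks for the four HiCCUPS-style neighborhoods on a
    (2*donut_width+1)^2 patch, all excluding the central peak square."""
    size = 2 * donut_width + 1
    c = donut_width
    yy, xx = np.mgrid[0:size, 0:size]
    peak = (np.abs(yy - c) <= peak_width) & (np.abs(xx - c) <= peak_width)
    donut = ~peak
    lower_left = (yy > c) & (xx < c) & ~peak
    horizontal = (np.abs(yy - c) <= peak_width) & ~peak
    vertical = (np.abs(xx - c) <= peak_width) & ~peak
    return {"donut": donut, "lower_left": lower_left,
            "horizontal": horizontal, "vertical": vertical}


def donut_refine(
    loops: LoopSet,
    matrix: ContactMatrix,
    ratios: dict[str, float] | None = None,
    peak_width: int = PEAK_WIDTH,
    donut_width: int = DONUT_WIDTH,
) -> LoopSet:
    """Keep loops enriched over all four local neighborhoods on the O/E map.

    A loop too close to the matrix edge for the donut is flagged ``edge`` and
    excluded (not silently kept).  The returned loop table gains per-
    neighborhood ratio columns and a ``status`` column in
    {pass, fail, edge}.
    """
    ratios = dict(DONUT_RATIOS if ratios is None else ratios)
    oe = oe_transform(matrix) if matrix.provenance != "raw" else \
        matrix.matrix / np.maximum(_expected_dense(matrix), np.finfo(float).tiny)
    n = matrix.n_bins
    masks = _neighborhood_masks(peak_width, donut_width)
    rows = []
    for r in loops.loops.itertuples():
        i, j = int(r.bin_i), int(r.bin_j)
        if (i - donut_width < 0 or j + donut_width >= n
                or j - donut_width < 0 or i + donut_width >= n):
            rows.append({**r._asdict(), "status": "edge"})
            continue
        patch = oe[i - donut_width: i + donut_width + 1,
                   j - donut_width: j + donut_width + 1]
        center = oe[i, j]
        rec = r._asdict()
        ok = np.isfinite(center)
        for name, msk in masks.items():
            vals = patch[msk]
            vals = vals[np.isfinite(vals)]
            ratio = center / vals.mean() if len(vals) and vals.mean() > 0 else np.nan
            rec[f"ratio_{name}"] = ratio
            ok = ok and np.isfinite(ratio) and ratio >= ratios[name]
        rec["status"] = "pass" if ok else "fail"
        rows.append(rec)
    out = pd.DataFrame(rows).drop(columns=["Index"], errors="ignore")
    kept = out[out.get("status", pd.Series(dtype=str)) == "pass"].reset_index(drop=True) \
        if len(out) else out
    params = dict(loops.params, ratios=ratios, peak_width=peak_width,
                  donut_width=donut_width)
    refined = LoopSet(chrom=loops.chrom, resolution=loops.resolution,
                      loops=kept, params=params)
    refined.evaluated = out
    return refined


def _expected_dense(matrix: ContactMatrix) -> np.ndarray:
    from .normalization import expected_by_distance
    curve = expected_by_distance(matrix)
    n = matrix.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = np.ones((n, n))
    off = d > 0
    e[off] = curve(d[off])
    return e


# ---------------------------------------------------------------------------
# Aggregate peak analysis
# ---------------------------------------------------------------------------

def apa(
    matrix: ContactMatrix,
    loops: LoopSet | pd.DataFrame,
    half_window: int = APA_HALF_WINDOW,
) -> ApaResult:
    """Element-wise mean of O/E windows centered on loop pixels.

    Score = center pixel / mean of the lower-left ``w x w`` corner block
    (the short-distance corner, the conventional APA normalizer).  Loops
    whose window does not fit inside the matrix are skipped; at least one
    usable loop is required.
    """
    table = loops.loops if isinstance(loops, LoopSet) else loops
    if len(table) == 0:
        raise ValueError("no loops supplied for APA")
    oe = oe_transform(matrix)
    n = matrix.n_bins
    w = half_window
    acc = np.zeros((2 * w + 1, 2 * w + 1))
    used = 0
    for r in table.itertuples():
        i, j = int(r.bin_i), int(r.bin_j)
        if i - w < 0 or j + w >= n or j - w < 0 or i + w >= n or (j - i) <= 2 * w:
            continue
        patch = oe[i - w: i + w + 1, j - w: j + w + 1]
        if not np.isfinite(patch).all():
            continue
        acc += patch
        used += 1
    if used == 0:
        raise ValueError("no usable loops: windows out of range or undefined")
    mean = acc / used
    corner = mean[w + 1:, :w]
    score = float(mean[w, w] / corner.mean())
    return ApaResult(matrix=mean, score=score, n_loops=used)


def write_bedpe(loops: LoopSet, path, chrom_length: int | None = None) -> None:
    res = loops.resolution
    t = loops.loops
    length = chrom_length if chrom_length is not None else 10 ** 12
    df = pd.DataFrame({
        "chrom1": loops.chrom, "start1": t["bin_i"] * res,
        "end1": np.minimum((t["bin_i"] + 1) * res, length),
        "chrom2": loops.chrom, "start2": t["bin_j"] * res,
        "end2": np.minimum((t["bin_j"] + 1) * res, length),
        "p": t["p"], "q": t["q"]})
    df.to_csv(path, sep="\t", header=False, index=False)
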