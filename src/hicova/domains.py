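"""Insulation-score TAD calling and paired-sample conservation.

The insulation score of bin i is the mean contact within a window x window
square placed immediately down-diagonal of i (contacts crossing the bin),
log2-normalized by the chromosome mean.  Local minima of the score, found as
negative-to-positive zero crossings of a flanking delta vector with
sufficient amplitude, are domain boundaries; consecutive boundaries become
TADs.  TADs shorter than 200 kb and TADs touching masked (telomere or
centromere) bins are discarded.  Conservation between samples uses the
reciprocal-overlap rule: a TAD is conserved iff a partner covers at least a
fraction (default 0.80) of BOTH intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactMatrix

INSULATION_WINDOW_BP = 500_000     # floored to whole bins
DELTA_SPAN_BP = 100_000
BOUNDARY_STRENGTH_THRESHOLD = 0.1
MIN_TAD_LENGTH_BP = 200_000        # keep only TADs strictly larger
RECIPROCAL_FRACTION = 0.80


@dataclass
class InsulationProfile:
    """Per-bin insulation and delta scores plus called boundaries."""

    chrom: str
    resolution: int
    insulation: np.ndarray           # log2 ratio to chromosome mean; NaN undefined
    delta: np.ndarray
    boundaries: pd.DataFrame         # columns: bin, strength


@dataclass
class TadSet:
    """Non-overlapping TAD intervals (bp, 0-based half-open) for one chromosome."""

    chrom: str
    resolution: int
    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["start", "end"]))

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def lengths(self) -> np.ndarray:
        return (self.intervals["end"] - self.intervals["start"]).to_numpy()


@dataclass
class TadComparison:
    """Reciprocal-overlap conservation, reported in both directions."""

    status_a: pd.DataFrame   # per TAD of A: start, end, status in {conserved, changed}
    status_b: pd.DataFrame
    counts: dict[str, int]   # conserved_a, changed_a, conserved_b, changed_b


def insulation_profile(
    matrix: ContactMatrix,
    window: int = INSULATION_WINDOW_BP,
    delta_span: int = DELTA_SPAN_BP,
    strength_threshold: float = BOUNDARY_STRENGTH_THRESHOLD,
) -> InsulationProfile:
    """Crane-style insulation score, delta vector, and boundary calls.

    ``window`` and ``delta_span`` are in bp and floored to whole bins.  The
    score is defined only where the square fits inside the chromosome and
    touches no masked bin.
    """
    res = matrix.resolution
    n = matrix.n_bins
    w = max(window // res, 2)
    ds = max(delta_span // res, 1)
    if w >= n // 2:
        raise ValueError("insulation window too large for chromosome")

    m = matrix.matrix
    mask = matrix.mask
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        if mask[i - w: i + w + 1].any():
            continue
        raw[i] = m[i - w: i, i + 1: i + w + 1].mean()
    defined = np.isfinite(raw) & (raw > 0)
    ins = np.full(n, np.nan)
    if defined.any():
        ins[defined] = np.log2(raw[defined] / raw[defined].mean())

    delta = np.full(n, np.nan)
    for i in range(n):
        right = ins[i + 1: i + 1 + ds]
        left = ins[max(i - ds, 0): i]
        if len(right) and len(left) and np.isfinite(right).all() and np.isfinite(left).all():
            delta[i] = right.mean() - left.mean()

    bounds = []
    for i in range(n - 1):
        if not (np.isfinite(delta[i]) and np.isfinite(delta[i + 1])):
            continue
        if delta[i] <= 0 < delta[i + 1]:
            cand = i if (np.isfinite(ins[i]) and ins[i] <= ins[i + 1]) else i + 1
            lo, hi = max(i - ds, 0), min(i + 2 + ds, n)
            seg = delta[lo:hi]
            seg = seg[np.isfinite(seg)]
            strength = float(seg.max() - seg.min()) if len(seg) else 0.0
            if strength >= strength_threshold:
                bounds.append((cand, strength))
    boundaries = pd.DataFrame(bounds, columns=["bin", "strength"]).drop_duplicates("bin")
    return InsulationProfile(chrom=matrix.chrom, resolution=res,
                             insulation=ins, delta=delta, boundaries=boundaries)


def assemble_tads(
    profile: InsulationProfile,
    layout,
    min_length: int = MIN_TAD_LENGTH_BP,
) -> TadSet:
    """Turn adjacent boundary pairs into TADs and apply the length/mask filters."""
    bins = np.sort(profile.boundaries["bin"].to_numpy())
    if len(bins) < 2:
        warnings.warn(f"{profile.chrom}: fewer than 2 boundaries; empty TAD set")
        return TadSet(chrom=profile.chrom, resolution=profile.resolution)
    res = profile.resolution
    mask = layout.mask[profile.chrom]
    rows = []
    for b0, b1 in zip(bins[:-1], bins[1:]):
        start, end = int(b0) * res, int(b1) * res
        if end - start <= min_length:
            continue
        if mask[b0:b1].any():
            continue
        rows.append((start, end))
    return TadSet(chrom=profile.chrom, resolution=res,
                  intervals=pd.DataFrame(rows, columns=["start", "end"]))


def classify_conservation(
    set_a: TadSet,
    set_b: TadSet,
    min_fraction: float = RECIPROCAL_FRACTION,
) -> TadComparison:
    """Reciprocal-overlap classification (the `intersectBed -f 0.80 -r` rule).

    A TAD is conserved iff some partner TAD overlaps it by at least
    ``min_fraction`` of BOTH lengths; otherwise changed.  Reported for A
    against B and B against A.
    """
    if len(set_b) == 0 and len(set_a) > 0:
        warnings.warn("empty comparison set; all TADs classified as changed")

    def classify(query: TadSet, target: TadSet) -> pd.DataFrame:
        rows = []
        tgt = target.intervals
        for _, t in query.intervals.iterrows():
            qlen = t["end"] - t["start"]
            conserved = False
            for _, u in tgt.iterrows():
                ov = min(t["end"], u["end"]) - max(t["start"], u["start"])
                if ov <= 0:
                    continue
                if ov >= min_fraction * qlen and ov >= min_fraction * (u["end"] - u["start"]):
                    conserved = True
                    break
            rows.append((t["start"], t["end"], "conserved" if conserved else "changed"))
        return pd.DataFrame(rows, columns=["start", "end", "status"])

    sa, sb = classify(set_a, set_b), classify(set_b, set_a)
    counts = {
        "conserved_a": int((sa["status"] == "conserved").sum()),
        "changed_a": int((sa["status"] == "changed").sum()),
        "conserved_b": int((sb["status"] == "conserved").sum()),
        "changed_b": int((sb["status"] == "changed").sum()),
    }
    return TadComparison(status_a=sa, status_b=sb, counts=counts)


def tad_length_summary(sets: dict[str, TadSet]) -> pd.DataFrame:
    """Median and quartiles of (filtered) TAD lengths per named set."""
    if not sets:
        raise ValueError("no TAD sets given")
    rows = []
    for name, ts in sets.items():
        if len(ts) == 0:
            rows.append((name, 0, np.nan, np.nan, np.nan))
            continue
        lengths = ts.lengths
        rows.append((name, len(ts), float(np.percentile(lengths, 25)),
                     float(np.median(lengths)), float(np.percentile(lengths, 75))))
    return pd.DataFrame(rows, columns=["set", "n_tads", "q1", "median", "q3"])


def boundary_recovery(
    called: np.ndarray, planted: np.ndarray, slack_bins: int = 1,
) -> tuple[float, float]:
    """(recall, false rate) of called vs planted boundary bin indices."""
    called = np.asarray(sorted(called))
    planted = np.asarray(sorted(planted))
    if len(planted) == 0:
        return np.nan, float(len(called) > 0)
    hit = np.array([np.min(np.abs(called - p)) <= slack_bins if len(called) else False
                    for p in planted])
    false = np.array([np.min(np.abs(planted - c)) > slack_bins for c in called]) \
        if len(called) else np.array([])
    recall = float(hit.mean())
    false_rate = float(false.mean()) if len(false) else 0.0
    return recall, false_rate
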