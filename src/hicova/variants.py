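"""SNV calling from per-site pileups and downstream variant analyses.

Calls are made directly from DP (total high-quality depth) and DV
(high-quality non-reference depth) columns with strict thresholds
(DP > 8 and DV > 4 in the default paired-sample preset; a DV >= 3 preset
supports WGS-comparison-style calling).  Downstream: known-polymorphism
removal, paired tumor-minus-normal somatic subtraction, mutation-rate
binning with hotspot flagging, exon/UTR/intron functional labeling, and
distance-to-restriction-site analysis of call sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .synthetic import distance_to_nearest_site

#: strict thresholds of the paired normal/tumor calling mode: DP > 8, DV > 4
PRESET_PAIRED = dict(dp_min=8, dv_min=4, strict=True)
#: WGS-comparison mode: at least three non-reference reads (DV >= 3)
PRESET_WGS_COMPARISON = dict(dp_min=0, dv_min=3, strict=False)
HOTSPOT_PERCENTILE = 99.0

CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "DP", "DV", "sample",
                "known_site", "somatic"]


def call_snvs(
    pileups: pd.DataFrame,
    dp_min: int = 8,
    dv_min: int = 4,
    strict: bool = True,
    sample: str = "",
) -> pd.DataFrame:
    """Emit a call for every pileup row passing the depth filters.

    ``strict=True`` (default) applies the exclusive thresholds DP > dp_min
    and DV > dv_min; ``strict=False`` applies DP >= dp_min and DV >= dv_min.
    Rows with DV > DP are rejected.
    """
    if (pileups["DV"] > pileups["DP"]).any():
        bad = int((pileups["DV"] > pileups["DP"]).idxmax())
        raise ValueError(f"DV exceeds DP at pileup row {bad}")
    if strict:
        keep = (pileups["DP"] > dp_min) & (pileups["DV"] > dv_min)
    else:
        keep = (pileups["DP"] >= dp_min) & (pileups["DV"] >= dv_min)
    calls = pileups.loc[keep, ["chrom", "pos", "ref", "alt", "DP", "DV"]].copy()
    calls["sample"] = sample
    calls["known_site"] = False
    calls["somatic"] = False
    return calls.reset_index(drop=True)


def filter_known_sites(calls: pd.DataFrame, known: set | pd.DataFrame) -> pd.DataFrame:
    """Drop calls at known polymorphic sites (dbSNP-style list).

    ``known`` is a set of (chrom, pos) tuples or a DataFrame with chrom/pos
    columns, on the same 1-based convention as the calls.
    """
    if isinstance(known, pd.DataFrame):
        known = set(zip(known["chrom"], known["pos"]))
    if not known:
        return calls.copy().reset_index(drop=True)
    flagged = [(c, p) in known for c, p in zip(calls["chrom"], calls["pos"])]
    out = calls.copy()
    out["known_site"] = flagged
    return out[~out["known_site"]].reset_index(drop=True)


def somatic_subtract(normal_calls: pd.DataFrame, tumor_calls: pd.DataFrame) -> pd.DataFrame:
    """Tumor calls absent from the normal set (keyed on chrom, pos, alt)."""
    normal_keys = set(zip(normal_calls["chrom"], normal_calls["pos"],
                          normal_calls["alt"]))
    keep = [(c, p, a) not in normal_keys
            for c, p, a in zip(tumor_calls["chrom"], tumor_calls["pos"],
                               tumor_calls["alt"])]
    out = tumor_calls[keep].copy()
    out["somatic"] = True
    return out.reset_index(drop=True)


@dataclass
class MutationRateTrack:
    """Per-bin mutation counts/rates at a stated bin size (1 Mb or 500 kb)."""

    bin_size: int
    counts: dict[str, np.ndarray]      # per chromosome
    rates: dict[str, np.ndarray]       # counts / bin length (per bp)
    hotspot: dict[str, np.ndarray]     # bins above the 99th percentile

    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def flat(self, field: str = "rates") -> np.ndarray:
        return np.concatenate([getattr(self, field)[c] for c in sorted(self.counts)])


def mutation_rate_track(
    calls: pd.DataFrame,
    layout,
    bin_size: int = 1_000_000,
    hotspot_percentile: float = HOTSPOT_PERCENTILE,
) -> MutationRateTrack:
    """Bin calls into fixed windows; flag bins above the rate percentile.

    Calls outside the layout's chromosomes or lengths are rejected.
    """
    counts, rates = {}, {}
    for chrom in layout.chromosomes:
        n = -(-layout.lengths[chrom] // bin_size)
        counts[chrom] = np.zeros(n)
    for r in calls.itertuples():
        if r.chrom not in counts or not 1 <= r.pos <= layout.lengths[r.chrom]:
            raise ValueError(f"call at {r.chrom}:{r.pos} outside layout")
        counts[r.chrom][(r.pos - 1) // bin_size] += 1
    for chrom in counts:
        n = len(counts[chrom])
        starts = np.arange(n) * bin_size
        widths = np.minimum(starts + bin_size, layout.lengths[chrom]) - starts
        rates[chrom] = counts[chrom] / widths
    all_rates = np.concatenate(list(rates.values()))
    cutoff = np.percentile(all_rates, hotspot_percentile)
    hotspot = {c: (rates[c] > cutoff) if all_rates.sum() > 0
               else np.zeros(len(rates[c]), dtype=bool) for c in rates}
    return MutationRateTrack(bin_size=bin_size, counts=counts, rates=rates,
                             hotspot=hotspot)


def annotate_functional(calls: pd.DataFrame, gene_model: pd.DataFrame) -> pd.DataFrame:
    """Label calls exonic / UTR / intronic / intergenic by highest priority.

    ``gene_model`` rows: chrom, start, end (0-based half-open), feature in
    {exon, UTR, intron}.  A call overlapping several features takes the
    highest-priority label (exonic > UTR > intronic).
    """
    if (gene_model["end"] <= gene_model["start"]).any():
        raise ValueError("malformed gene-model interval (end <= start)")
    priority = {"exon": 0, "UTR": 1, "intron": 2}
    label_of = {"exon": "exonic", "UTR": "UTR", "intron": "intronic"}
    unknown = set(gene_model["feature"]) - set(priority)
    if unknown:
        raise ValueError(f"unknown gene-model features: {unknown}")

    out = calls.copy()
    labels = []
    by_chrom = {c: g.sort_values("start") for c, g in gene_model.groupby("chrom")}
    for r in calls.itertuples():
        pos0 = r.pos - 1  # calls are 1-based
        best = None
        g = by_chrom.get(r.chrom)
        if g is not None:
            hits = g[(g["start"] <= pos0) & (pos0 < g["end"])]
            if len(hits):
                best = hits.loc[hits["feature"].map(priority).idxmin(), "feature"]
        labels.append(label_of[best] if best else "intergenic")
    out["region"] = labels
    return out


def cut_site_distances(calls: pd.DataFrame, sites: dict[str, np.ndarray]) -> np.ndarray:
    """Distance (bp) from each call to the nearest restriction (GATC) site."""
    if not sites or all(len(s) == 0 for s in sites.values()):
        raise ValueError("empty restriction-site list")
    out = np.empty(len(calls), dtype=float)
    for chrom, g in calls.groupby("chrom", sort=False):
        if chrom not in sites or len(sites[chrom]) == 0:
            raise ValueError(f"no restriction sites for {chrom}")
        out[calls["chrom"] == chrom] = distance_to_nearest_site(
            g["pos"].to_numpy() - 1, sites[chrom])
    return out


def compare_cut_site_distances(
    distances_a: np.ndarray, distances_b: np.ndarray,
) -> tuple[float, float]:
    """One-sided rank-sum test that set A sits closer to cut sites than set B.

    Returns (statistic, p).  Mirrors the comparison of Hi-C-called vs
    WGS-called SNV distance distributions.
    """
    stat, p = mannwhitneyu(distances_a, distances_b, alternative="less")
    return float(stat), float(p)


def write_vcf(calls: pd.DataFrame, path, reference_name: str = "synthetic") -> None:
    """Minimal VCF: CHROM POS REF ALT with DP/DV (and SOMATIC) in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=DV,Number=1,Type=Integer,Description="Non-reference depth">\n')
        fh.write('##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic call">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in calls.itertuples():
            info = f"DP={r.DP};DV={r.DV}"
            if getattr(r, "somatic", False):
                info += ";SOMATIC"
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")


def read_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=") for kv in info.split(";") if "=" in kv)
            rows.append((chrom, int(pos), ref, alt, int(fields.get("DP", 0)),
                         int(fields.get("DV", 0)), "SOMATIC" in info))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "DP", "DV", "somatic"])
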