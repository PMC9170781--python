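"""Multi-omics integration: differential expression, compartment-switch
grouping, chromosome-level CNV/TAD/DEG correlation, and mutation-rate by
compartment association.

The differential-expression test is a deliberately simple negative-binomial
Wald test (median-of-ratios size factors, pooled method-of-moments
dispersion with a per-gene floor, normal Wald p-values, BH correction) — a
transparent, conservative stand-in for a full shrinkage-based NB framework,
calibrated on null simulations in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm as norm_dist, pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

DEG_FDR = 0.05
DISPERSION_FLOOR = 0.01
N_PERMUTATIONS = 1999


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = per-gene geometric mean)."""
    log = np.log(counts.where(counts > 0))
    ref = log.mean(axis=1)
    usable = np.isfinite(ref)
    if usable.sum() == 0:
        raise ValueError("no gene has positive counts in all samples")
    ratios = log.loc[usable].sub(ref[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def deg_test(
    normal: pd.DataFrame,
    tumor: pd.DataFrame,
    fdr: float = DEG_FDR,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Simplified NB Wald test per gene between two replicate groups.

    Returns a table with log2 fold change (tumor over normal), p, BH q, and
    a DEG flag at the stated FDR.  Genes with all-zero counts are excluded
    (kept in the table with NaN statistics and ``tested=False``).  The
    per-gene dispersion is the larger of the gene's method-of-moments
    estimate, a pooled regression estimate across genes, and a floor — a
    conservative choice that keeps the null calibrated at tiny replicate
    numbers.
    """
    if normal.shape[1] < 2 or tumor.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    genes = normal.index
    if not genes.equals(tumor.index):
        raise ValueError("gene sets differ between groups")
    counts = pd.concat([normal, tumor], axis=1)
    sf = size_factors(counts)
    norm = counts / sf
    n_n, n_t = normal.shape[1], tumor.shape[1]
    xn, xt = norm.iloc[:, :n_n].to_numpy(), norm.iloc[:, n_n:].to_numpy()

    tested = counts.sum(axis=1).to_numpy() > 0
    mu_n, mu_t = xn.mean(axis=1), xt.mean(axis=1)
    overall = (mu_n + mu_t) / 2

    var_within = (xn.var(axis=1, ddof=1) + xt.var(axis=1, ddof=1)) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_gene = (var_within - overall) / overall ** 2
    # pooled dispersion by least squares of (var - mu) on mu^2 across genes:
    # unbiased for a shared dispersion, unlike the median of noisy per-gene
    # moment estimates which is biased low at tiny replicate numbers
    y, x2 = (var_within - overall)[tested], (overall ** 2)[tested]
    phi_trend = max(float((y * x2).sum() / (x2 * x2).sum()), 0.0) \
        if x2.sum() > 0 else dispersion_floor
    phi = np.maximum.reduce([np.nan_to_num(phi_gene, nan=0.0),
                             np.full(len(genes), phi_trend),
                             np.full(len(genes), dispersion_floor)])

    pseudo = 0.5
    lfc = np.log2((mu_t + pseudo) / (mu_n + pseudo))
    var_log = ((mu_n + phi * mu_n ** 2) / (n_n * np.maximum(mu_n, pseudo) ** 2)
               + (mu_t + phi * mu_t ** 2) / (n_t * np.maximum(mu_t, pseudo) ** 2))
    se = np.sqrt(var_log) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    # normal Wald reference: the variance is trend-stabilized, not a 2-sample
    # estimate, so a t reference at n-2 df would double-count uncertainty
    p = 2 * norm_dist.sf(np.abs(z))
    p[~tested] = np.nan

    q = np.full(len(genes), np.nan)
    q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    out = pd.DataFrame({
        "gene": genes, "base_mean": overall, "log2fc": lfc, "dispersion": phi,
        "p": p, "q": q, "deg": (q < fdr) & tested, "tested": tested,
    }).set_index("gene")
    if (~tested).any():
        warnings.warn(f"{int((~tested).sum())} all-zero genes excluded from testing")
    return out


# ---------------------------------------------------------------------------
# Compartment-switch grouping
# ---------------------------------------------------------------------------

@dataclass
class SwitchGrouping:
    """Per-switch-class expression-change distributions and trend statistic."""

    medians: dict[str, float]          # 'B->A', 'stable', 'A->B'
    class_sizes: dict[str, int]
    trend_rho: float
    trend_p: float
    concordant_fraction_all: float     # DEGs in concordant-switch regions / all DEGs
    no_switch_fraction_all: float
    concordant_fraction_mapped: float  # same, over mappable DEGs
    no_switch_fraction_mapped: float
    n_unmapped: int
    table: pd.DataFrame                # gene, log2fc, switch_class, deg


def group_by_switch(
    degs: pd.DataFrame,
    switches: dict[str, "SwitchTable"],
    gene_bins: pd.DataFrame,
    compartment_bin_size: int = 500_000,
) -> SwitchGrouping:
    """Group gene expression changes by the compartment switch of their bin.

    ``gene_bins`` maps genes to genomic position (columns gene, chrom, tss);
    a gene's compartment bin is its transcription start.  Classes are
    'B->A', 'stable' (A->A or B->B), 'A->B'; the trend statistic is the
    Spearman correlation of log2FC with the ordered classes (-1, 0, +1).
    """
    rows, unmapped = [], 0
    for r in gene_bins.itertuples():
        if r.gene not in degs.index:
            continue
        st = switches.get(r.chrom)
        cb = int(r.tss // compartment_bin_size)
        cls = st.classes[cb] if st is not None and cb < len(st.classes) else ""
        if cls == "":
            unmapped += 1
            continue
        simple = {"B->A": "B->A", "A->B": "A->B"}.get(cls, "stable")
        rows.append((r.gene, degs.loc[r.gene, "log2fc"], simple,
                     bool(degs.loc[r.gene, "deg"])))
    table = pd.DataFrame(rows, columns=["gene", "log2fc", "switch_class", "deg"])

    order = {"A->B": -1, "stable": 0, "B->A": 1}
    medians, sizes = {}, {}
    for cls in order:
        sub = table[table["switch_class"] == cls]
        sizes[cls] = len(sub)
        medians[cls] = float(sub["log2fc"].median()) if len(sub) else np.nan
    present = table["switch_class"].nunique()
    if present >= 2 and len(table) >= 3:
        rho, p = spearmanr(table["switch_class"].map(order), table["log2fc"])
        rho, p = float(rho), float(p)
    else:
        rho, p = np.nan, np.nan

    degs_all = degs[degs["deg"]]
    deg_tab = table[table["deg"]]
    concord = (((deg_tab["switch_class"] == "B->A") & (deg_tab["log2fc"] > 0))
               | ((deg_tab["switch_class"] == "A->B") & (deg_tab["log2fc"] < 0)))
    no_switch = deg_tab["switch_class"] == "stable"
    n_all, n_mapped = max(len(degs_all), 1), max(len(deg_tab), 1)
    return SwitchGrouping(
        medians=medians, class_sizes=sizes, trend_rho=rho, trend_p=p,
        concordant_fraction_all=float(concord.sum() / n_all),
        no_switch_fraction_all=float(no_switch.sum() / n_all),
        concordant_fraction_mapped=float(concord.sum() / n_mapped),
        no_switch_fraction_mapped=float(no_switch.sum() / n_mapped),
        n_unmapped=unmapped, table=table,
    )


# ---------------------------------------------------------------------------
# Chromosome-level summary
# ---------------------------------------------------------------------------

@dataclass
class IntegrationSummary:
    """Per-chromosome alteration fractions and their cross-chromosome correlations."""

    fractions: pd.DataFrame   # chrom, cnv_fraction, tad_changed_fraction, deg_fraction
    correlations: pd.DataFrame  # pair, pearson_r, pearson_p, spearman_rho, spearman_p


def chromosome_summary(
    cnv: dict[str, "CnvSegments"],
    tads: dict[str, "TadComparison"],
    degs: pd.DataFrame,
    gene_bins: pd.DataFrame,
    layout,
) -> IntegrationSummary:
    """Fractions of each chromosome altered by CNVs, changed TADs, and DEGs,
    with pairwise Pearson/Spearman correlations across chromosomes."""
    rows = []
    for chrom in layout.chromosomes:
        if chrom not in cnv or chrom not in tads:
            warnings.warn(f"{chrom} missing from CNV or TAD input; excluded")
            continue
        seg = cnv[chrom]
        cnv_frac = seg.fraction_altered
        cmp_ = tads[chrom]
        n_tads = cmp_.counts["conserved_a"] + cmp_.counts["changed_a"]
        tad_frac = cmp_.counts["changed_a"] / n_tads if n_tads else np.nan
        genes_here = gene_bins[gene_bins["chrom"] == chrom]["gene"]
        genes_here = [g for g in genes_here if g in degs.index and degs.loc[g, "tested"]]
        deg_frac = float(degs.loc[genes_here, "deg"].mean()) if genes_here else np.nan
        rows.append((chrom, cnv_frac, tad_frac, deg_frac))
    frac = pd.DataFrame(rows, columns=["chrom", "cnv_fraction",
                                       "tad_changed_fraction", "deg_fraction"])

    pairs = [("cnv_fraction", "tad_changed_fraction"),
             ("cnv_fraction", "deg_fraction"),
             ("tad_changed_fraction", "deg_fraction")]
    crows = []
    for a, b in pairs:
        ok = frac[[a, b]].notna().all(axis=1)
        x, y = frac.loc[ok, a], frac.loc[ok, b]
        if ok.sum() < 3 or x.std() == 0 or y.std() == 0:
            warnings.warn(f"correlation {a} vs {b} undefined (degenerate input)")
            crows.append((f"{a}~{b}", np.nan, np.nan, np.nan, np.nan))
            continue
        pr, pp = pearsonr(x, y)
        sr, sp = spearmanr(x, y)
        crows.append((f"{a}~{b}", float(pr), float(pp), float(sr), float(sp)))
    corr = pd.DataFrame(crows, columns=["pair", "pearson_r", "pearson_p",
                                        "spearman_rho", "spearman_p"])
    return IntegrationSummary(fractions=frac, correlations=corr)


# ---------------------------------------------------------------------------
# Mutation rate vs constitutive compartment
# ---------------------------------------------------------------------------

def mutation_compartment_association(
    rates: "MutationRateTrack",
    states: dict[str, np.ndarray],
    n_permutations: int = N_PERMUTATIONS,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean mutation rate in constitutive-B bins over constitutive-A bins.

    Significance by permuting the state labels over bins; the two-sided
    permutation p-value lies in [1/(n_permutations+1), 1].
    """
    rate, lab = [], []
    for chrom in rates.counts:
        if chrom not in states:
            raise ValueError(f"no compartment states for {chrom}")
        s = np.asarray(states[chrom])
        if len(s) != len(rates.rates[chrom]):
            raise ValueError(f"{chrom}: state track not on the rate bins")
        rate.append(rates.rates[chrom])
        lab.append(s)
    rate, lab = np.concatenate(rate), np.concatenate(lab)
    if rate.sum() == 0:
        raise ValueError("no mutations in the rate track")
    is_a, is_b = lab == "A", lab == "B"
    if not is_a.any() or not is_b.any():
        raise ValueError("both constitutive compartment classes must be non-empty")

    def ratio(a_mask, b_mask):
        ma, mb = rate[a_mask].mean(), rate[b_mask].mean()
        return np.inf if ma == 0 else mb / ma

    observed = ratio(is_a, is_b)
    obs_stat = np.abs(np.log(observed)) if np.isfinite(observed) and observed > 0 else np.inf
    rng = np.random.default_rng(seed)
    n_a = int(is_a.sum())
    eligible = np.flatnonzero(is_a | is_b)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(eligible)
        pa = np.zeros(len(rate), dtype=bool)
        pb = np.zeros(len(rate), dtype=bool)
        pa[perm[:n_a]] = True
        pb[perm[n_a:]] = True
        r = ratio(pa, pb)
        stat = np.abs(np.log(r)) if np.isfinite(r) and r > 0 else np.inf
        if stat >= obs_stat:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return float(observed), float(p)
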