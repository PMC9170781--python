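"""Synthetic Hi-C, pileup, and expression data with planted ground truth.

Every downstream stage of the package (normalization, compartments, TADs,
loops, CNV, SNV, integration) is validated by recovering structure planted
here.  The contact-map model is multiplicative: the expected count between
bins i and j combines a power-law distance decay, a checkerboard A/B
compartment term, a within-TAD boost, focal loop boosts, and per-bin copy
number, with Poisson counting noise on top.  Pileups model depth capture
biased toward restriction (GATC) cut sites; expression is negative-binomial
with log2 fold-change effects optionally coupled to compartment switches.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .contacts import ContactMatrix

DEFAULT_BIN_SIZE = 40_000
DEFAULT_COMPARTMENT_BIN_SIZE = 500_000
#: intra-chromosomal read pairs per 20-Mb toy chromosome; scaled from typical
#: clinical in-situ Hi-C yields of ~1e8-4e8 valid pairs per 3-Gb genome
DEFAULT_DEPTH_PER_CHROM = 2_000_000
#: GATC occurs once per 256 bp in uniform random sequence
DEFAULT_SITE_DENSITY = 1.0 / 256.0
#: exponential length scale (bp) of the capture-efficiency kernel around cut sites
CAPTURE_SCALE_BP = 200.0

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass
class GenomeLayout:
    """Binned toy genome with per-bin covariates and restriction sites.

    Bins tile each chromosome with 0-based half-open intervals; the last bin
    may be short.  ``mask`` marks telomere/centromere bins excluded from
    domain analysis.  ``sites`` holds strictly increasing GATC positions per
    chromosome.
    """

    chromosomes: list[str]
    lengths: dict[str, int]
    bin_size: int
    bins: pd.DataFrame  # chrom, start, end, gc, mappability, gene_density, frag_count
    mask: dict[str, np.ndarray]  # True = telomere/centromere bin
    sites: dict[str, np.ndarray]

    def n_bins(self, chrom: str) -> int:
        return int(-(-self.lengths[chrom] // self.bin_size))

    def chrom_bins(self, chrom: str) -> pd.DataFrame:
        return self.bins[self.bins["chrom"] == chrom].reset_index(drop=True)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Bin index of a 0-based position."""
        if not 0 <= pos < self.lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_size


def make_genome_layout(
    n_chromosomes: int = 2,
    lengths: list[int] | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    seed: int = 0,
    site_density: float = DEFAULT_SITE_DENSITY,
    low_gc_fraction: float = 0.03,
    low_mappability_fraction: float = 0.03,
    telomere_bins: int = 2,
    centromere_bins: int = 2,
) -> GenomeLayout:
    """Build a toy genome layout: 0-based half-open bins, covariates, GATC sites.

    GC is Uniform(0.3, 0.6) with a small planted fraction of low-GC bins;
    restriction sites follow a homogeneous Poisson process of the given
    density.  Deterministic given ``seed``.
    """
    if lengths is None:
        lengths = [20_000_000] * n_chromosomes
    if len(lengths) != n_chromosomes:
        raise ValueError("lengths must have one entry per chromosome")
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    for length in lengths:
        if length <= 0:
            raise ValueError("chromosome lengths must be positive")
        if length // bin_size < 20:
            raise ValueError("bin_size must divide each chromosome into >= 20 bins")

    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    length_of = dict(zip(chroms, (int(x) for x in lengths)))

    rows, mask, sites = [], {}, {}
    for chrom in chroms:
        length = length_of[chrom]
        n = -(-length // bin_size)
        starts = np.arange(n) * bin_size
        ends = np.minimum(starts + bin_size, length)

        gc = rng.uniform(0.3, 0.6, size=n)
        low = rng.random(n) < low_gc_fraction
        gc[low] = rng.uniform(0.05, 0.19, size=low.sum())
        mapp = rng.uniform(0.55, 1.0, size=n)
        low_m = rng.random(n) < low_mappability_fraction
        mapp[low_m] = rng.uniform(0.1, 0.49, size=low_m.sum())
        gene_density = rng.poisson(2.0, size=n)

        n_sites = rng.poisson(length * site_density)
        pos = np.unique(rng.integers(0, length, size=n_sites))
        sites[chrom] = pos
        frag_count = np.bincount(pos // bin_size, minlength=n)

        m = np.zeros(n, dtype=bool)
        m[:telomere_bins] = True
        m[n - telomere_bins:] = True
        mid = n // 2
        m[mid: mid + centromere_bins] = True
        mask[chrom] = m

        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends, "gc": gc,
            "mappability": mapp, "gene_density": gene_density,
            "frag_count": frag_count,
        }))

    return GenomeLayout(
        chromosomes=chroms, lengths=length_of, bin_size=bin_size,
        bins=pd.concat(rows, ignore_index=True), mask=mask, sites=sites,
    )


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Planted structure scored against every stage's output.

    ``compartments``/``tumor_compartments`` are +/-1 vectors on compartment
    bins (A = +1); CNV segments are half-open bin intervals with integer copy
    state; loop anchors are matrix bin pairs (i < j); variants carry genotype,
    somatic flag, and allele fraction; ``deg_effects`` maps gene -> log2 fold
    change in tumor.
    """

    seed: int
    alpha: float
    gamma: float
    tau: float
    lam: float
    purity: float
    compartment_bin_size: int
    compartments: dict[str, np.ndarray]
    tumor_compartments: dict[str, np.ndarray]
    tads: dict[str, list[tuple[int, int]]]
    tumor_tads: dict[str, list[tuple[int, int]]]
    loops: dict[str, list[tuple[int, int]]]
    cnv: dict[str, list[tuple[int, int, int]]]  # (start_bin, end_bin, state)
    variants: pd.DataFrame
    deg_effects: dict[str, float] = field(default_factory=dict)

    def copy_state(self, chrom: str, n_bins: int) -> np.ndarray:
        c = np.full(n_bins, 2, dtype=int)
        for s, e, state in self.cnv.get(chrom, []):
            c[s:e] = state
        return c

    def tad_boundaries(self, chrom: str) -> np.ndarray:
        bounds = sorted({b for s, e in self.tads.get(chrom, []) for b in (s, e)})
        return np.asarray(bounds, dtype=int)

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        for key in ("compartments", "tumor_compartments"):
            d[key] = {c: np.asarray(v).tolist() for c, v in d[key].items()}
        for key in ("tads", "tumor_tads", "loops", "cnv"):
            d[key] = {c: [list(map(int, t)) for t in v] for c, v in d[key].items()}
        d["variants"] = self.variants.to_dict(orient="list")
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        for key in ("compartments", "tumor_compartments"):
            d[key] = {c: np.asarray(v, dtype=int) for c, v in d[key].items()}
        for key in ("tads", "tumor_tads", "loops", "cnv"):
            d[key] = {c: [tuple(t) for t in v] for c, v in d[key].items()}
        d["variants"] = pd.DataFrame(d["variants"])
        return cls(**d)


def make_truth(
    layout: GenomeLayout,
    seed: int = 0,
    alpha: float = 1.0,
    gamma: float = 0.4,
    tau: float = 3.0,
    lam: float = 10.0,
    purity: float = 0.35,
    compartment_bin_size: int = DEFAULT_COMPARTMENT_BIN_SIZE,
    compartment_block_bins: int = 4,
    switch_b_to_a: float = 0.05,
    switch_a_to_b: float = 0.03,
    mean_tad_bins: int = 18,
    min_tad_bins: int = 8,
    tad_change_fraction: float = 0.25,
    n_loops_per_chrom: int = 12,
    cnv_segments: dict[str, list[tuple[int, int, int]]] | None = None,
    n_germline_variants: int = 300,
    n_somatic_variants: int = 150,
    couple_gene_density: bool = True,
) -> SyntheticTruth:
    """Draw a full planted truth for ``layout``.

    Compartments alternate in blocks of ``compartment_block_bins`` compartment
    bins with random phase; tumor compartments flip a fraction of B bins to A
    (and vice versa).  TADs tile each chromosome with jittered lengths; the
    tumor re-draws boundaries inside a ``tad_change_fraction`` of the genome.
    When ``couple_gene_density`` is set, the layout's per-bin gene density is
    re-drawn so A bins are gene-dense (Poisson mean 4 vs 1) — the orientation
    evidence the compartment caller relies on.
    """
    rng = np.random.default_rng(seed)

    compartments, tumor_compartments = {}, {}
    tads, tumor_tads, loops, cnv = {}, {}, {}, {}
    for chrom in layout.chromosomes:
        n = layout.n_bins(chrom)
        n_comp = -(-layout.lengths[chrom] // compartment_bin_size)

        # block-alternating +/-1 compartment vector with random phase
        phase = int(rng.integers(0, compartment_block_bins))
        v = np.where(((np.arange(n_comp) + phase) // compartment_block_bins) % 2 == 0, 1, -1)
        compartments[chrom] = v
        # switch rates are fractions of ALL bins; rescale to per-class flip probs
        vt = v.copy()
        p_ba = min(switch_b_to_a / max(float(np.mean(v == -1)), 1e-9), 1.0)
        p_ab = min(switch_a_to_b / max(float(np.mean(v == 1)), 1e-9), 1.0)
        vt[(v == -1) & (rng.random(n_comp) < p_ba)] = 1
        vt[(v == 1) & (rng.random(n_comp) < p_ab)] = -1
        tumor_compartments[chrom] = vt

        tads[chrom] = _tile_tads(n, rng, mean_tad_bins, min_tad_bins)
        tumor_tads[chrom] = _perturb_tads(tads[chrom], n, rng, tad_change_fraction,
                                          mean_tad_bins, min_tad_bins)

        pairs = set()
        while len(pairs) < n_loops_per_chrom:
            i = int(rng.integers(5, n - 60))
            j = i + int(rng.integers(10, 50))
            if j < n - 5 and not layout.mask[chrom][i] and not layout.mask[chrom][j]:
                pairs.add((i, j))
        loops[chrom] = sorted(pairs)
        cnv[chrom] = []

    if cnv_segments is not None:
        cnv.update(copy.deepcopy(cnv_segments))

    if couple_gene_density:
        dens = layout.bins["gene_density"].to_numpy().copy()
        offset = 0
        for chrom in layout.chromosomes:
            n = layout.n_bins(chrom)
            v_bin = compartments[chrom][(np.arange(n) * layout.bin_size) // compartment_bin_size]
            mean = np.where(v_bin > 0, 4.0, 1.0)
            dens[offset: offset + n] = rng.poisson(mean)
            offset += n
        layout.bins["gene_density"] = dens

    variants = _draw_variants(layout, rng, n_germline_variants, n_somatic_variants)

    return SyntheticTruth(
        seed=seed, alpha=alpha, gamma=gamma, tau=tau, lam=lam, purity=purity,
        compartment_bin_size=compartment_bin_size,
        compartments=compartments, tumor_compartments=tumor_compartments,
        tads=tads, tumor_tads=tumor_tads, loops=loops, cnv=cnv,
        variants=variants,
    )


def _tile_tads(n_bins: int, rng, mean_bins: int, min_bins: int) -> list[tuple[int, int]]:
    tads, pos = [], 0
    while pos < n_bins - min_bins:
        size = int(rng.integers(min_bins, 2 * mean_bins - min_bins + 1))
        end = min(pos + size, n_bins)
        tads.append((pos, end))
        pos = end
    return tads


def _perturb_tads(tads, n_bins, rng, change_fraction, mean_bins, min_bins):
    """Re-draw TAD boundaries inside a random fraction of the chromosome."""
    if change_fraction <= 0:
        return list(tads)
    out = []
    for s, e in tads:
        if rng.random() < change_fraction:
            # split or merge region by re-tiling with a different offset
            mid = (s + e) // 2
            if e - s >= 2 * min_bins:
                out.extend([(s, mid), (mid, e)])
            else:
                out.append((max(0, s - min_bins // 2), e))
        else:
            out.append((s, e))
    # repair overlaps introduced by shifts
    fixed, prev_end = [], 0
    for s, e in out:
        s = max(s, prev_end)
        if e - s >= 2:
            fixed.append((s, e))
            prev_end = e
    return fixed


def _draw_variants(layout, rng, n_germline: int, n_somatic: int) -> pd.DataFrame:
    rows = []
    for somatic, count in ((False, n_germline), (True, n_somatic)):
        for _ in range(count):
            chrom = layout.chromosomes[int(rng.integers(len(layout.chromosomes)))]
            pos = int(rng.integers(1, layout.lengths[chrom]))  # 1-based
            ref, alt = rng.choice(4, size=2, replace=False)
            genotype = "1/1" if (not somatic and rng.random() < 0.2) else "0/1"
            f = 1.0 if genotype == "1/1" else 0.5
            rows.append((chrom, pos, BASES[ref], BASES[alt], genotype, somatic, f))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "genotype", "somatic", "allele_fraction"])
    return (df.drop_duplicates(subset=["chrom", "pos"])
              .sort_values(["chrom", "pos"]).reset_index(drop=True))


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

def expected_contact_matrix(
    layout: GenomeLayout, truth: SyntheticTruth, chrom: str, tumor: bool = False,
) -> np.ndarray:
    """Noise-free expected contact intensity (unnormalized) for one chromosome."""
    n = layout.n_bins(chrom)
    bs = layout.bin_size
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * bs
    with np.errstate(divide="ignore"):
        e = np.where(d > 0, d.astype(float) ** -truth.alpha, 0.0)

    comp = truth.tumor_compartments if tumor else truth.compartments
    v = comp[chrom][(np.arange(n) * bs) // truth.compartment_bin_size].astype(float)
    e *= np.exp(truth.gamma * np.outer(v, v))

    tad_id = np.full(n, -1)
    for k, (s, t) in enumerate((truth.tumor_tads if tumor else truth.tads)[chrom]):
        tad_id[s:t] = k
    same = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
    e = np.where(same, e * truth.tau, e)

    for i, j in truth.loops[chrom]:
        e[i, j] *= truth.lam
        e[j, i] *= truth.lam

    if tumor and truth.cnv.get(chrom):
        c = truth.copy_state(chrom, n) / 2.0
        e *= np.outer(c, c)
    return e


def simulate_contact_map(
    layout: GenomeLayout,
    truth: SyntheticTruth,
    depth: int = DEFAULT_DEPTH_PER_CHROM * 2,
    tumor: bool = False,
    seed: int | None = None,
) -> dict[str, ContactMatrix]:
    """Poisson contact maps for all chromosomes, total off-diagonal ~ ``depth``.

    Depth is allocated across chromosomes proportionally to length; the
    diagonal is excluded from scaling and left at zero (self-ligation bins
    carry no distance signal in this model).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(truth.seed + 7_919 if seed is None else seed)
    total_len = sum(layout.lengths.values())
    out = {}
    for chrom in layout.chromosomes:
        e = expected_contact_matrix(layout, truth, chrom, tumor=tumor)
        np.fill_diagonal(e, 0.0)
        chrom_depth = depth * layout.lengths[chrom] / total_len
        e *= chrom_depth / e.sum()
        upper = np.triu(e, k=1)
        counts = rng.poisson(upper).astype(float)
        m = counts + counts.T
        out[chrom] = ContactMatrix(chrom=chrom, resolution=layout.bin_size,
                                   matrix=m, mask=np.zeros(len(m), dtype=bool))
    return out


def downsample_pairs(matrix: ContactMatrix, fraction: float, seed: int = 0) -> ContactMatrix:
    """Binomially thin every contact — emulates lower cell-number inputs."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return ContactMatrix(matrix.chrom, matrix.resolution,
                             matrix.matrix.copy(), matrix.mask.copy())
    rng = np.random.default_rng(seed)
    upper = np.triu(matrix.matrix, k=0)
    thinned = rng.binomial(upper.astype(int), fraction).astype(float)
    m = thinned + np.triu(thinned, k=1).T
    return ContactMatrix(matrix.chrom, matrix.resolution, m, matrix.mask.copy())


def simulate_coupled_alterations(
    n_chromosomes: int = 12,
    chrom_length: int = 6_000_000,
    bin_size: int = DEFAULT_BIN_SIZE,
    n_genes_per_chrom: int = 40,
    n_replicates: int = 3,
    dispersion: float = 0.05,
    deg_lfc: float = 2.0,
    seed: int = 0,
):
    """Many small chromosomes with a coupled alteration gradient.

    Chromosome k carries alteration intensity ``u_k = (k + 0.5) / n``: a
    copy-gain segment covering ``0.5 u_k`` of its bins, TAD boundaries
    re-drawn over ``0.6 u_k`` of its domains, and each of its genes a DEG
    (log2FC +/- ``deg_lfc``) with probability ``0.5 u_k``.  Returns
    ``(layout, cnv_segments, tad_pairs, genes, expr_normal, expr_tumor,
    truth)`` where ``cnv_segments`` maps chromosome to a planted
    :class:`~hicova.cnv.CnvSegments` and ``tad_pairs`` maps chromosome to its
    (normal TadSet, tumor TadSet) pair — the substrate of the
    chromosome-level CNV/TAD/DEG correlation analysis.
    """
    from .cnv import CnvSegments
    from .domains import TadSet

    rng = np.random.default_rng(seed)
    layout = make_genome_layout(n_chromosomes, [chrom_length] * n_chromosomes,
                                bin_size, seed=seed)
    intensity = (np.arange(n_chromosomes) + 0.5) / n_chromosomes
    rng.shuffle(intensity)

    cnv_segments, tad_pairs, cnv_truth = {}, {}, {}
    for k, chrom in enumerate(layout.chromosomes):
        n = layout.n_bins(chrom)
        u = intensity[k]
        gain = int(round(0.5 * u * n))
        start = int(rng.integers(0, n - gain)) if gain else 0
        segs = []
        if start > 0:
            segs.append((0, start * bin_size, 2, 1.0))
        if gain > 0:
            segs.append((start * bin_size, (start + gain) * bin_size, 3, 1.5))
        if start + gain < n:
            segs.append(((start + gain) * bin_size, layout.lengths[chrom], 2, 1.0))
        ratio = np.ones(n)
        ratio[start: start + gain] = 1.5
        cnv_segments[chrom] = CnvSegments(
            chrom=chrom, resolution=bin_size,
            segments=pd.DataFrame(segs, columns=["start", "end", "state",
                                                 "mean_coverage"]),
            copy_ratio=ratio)
        cnv_truth[chrom] = [(start, start + gain, 3)] if gain else []

        normal_tads = _tile_tads(n, rng, mean_bins=14, min_bins=6)
        tumor_tads = _perturb_tads(normal_tads, n, rng, 0.6 * u, 14, 6)
        tad_pairs[chrom] = (
            TadSet(chrom=chrom, resolution=bin_size, intervals=pd.DataFrame(
                [(s * bin_size, e * bin_size) for s, e in normal_tads],
                columns=["start", "end"])),
            TadSet(chrom=chrom, resolution=bin_size, intervals=pd.DataFrame(
                [(s * bin_size, e * bin_size) for s, e in tumor_tads],
                columns=["start", "end"])),
        )

    truth = make_truth(layout, seed=seed, cnv_segments=cnv_truth,
                       n_germline_variants=0, n_somatic_variants=0)
    genes = make_gene_table(layout, n_genes=n_genes_per_chrom * n_chromosomes,
                            seed=seed + 1)
    effects = {}
    for g in genes.itertuples():
        u = intensity[layout.chromosomes.index(g.chrom)]
        if rng.random() < 0.5 * u:
            effects[g.gene] = float(rng.choice([-1, 1])) * deg_lfc
        else:
            effects[g.gene] = 0.0
    truth.deg_effects = effects
    expr_n, expr_t = simulate_expression(genes, truth, n_replicates=n_replicates,
                                         dispersion=dispersion, seed=seed + 2)
    return layout, cnv_segments, tad_pairs, genes, expr_n, expr_t, truth


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

def simulate_pileups(
    layout: GenomeLayout,
    truth: SyntheticTruth,
    mean_depth: float = 30.0,
    error_rate: float = 0.001,
    capture_bias: float = 3.0,
    sample_kind: str = "normal",
    n_background_sites: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site pileup table (chrom, pos 1-based, ref, alt, DP, DV).

    Depth at each site is Poisson with mean modulated by
    ``1 + capture_bias * exp(-distance_to_nearest_GATC / 200 bp)`` (normalized
    to overall mean ``mean_depth``) — the capture preference of Hi-C libraries
    for restriction-site-proximal sequence.  DV is binomial: allele fraction
    (purity-scaled for somatic sites in tumor) at variant sites, ``error_rate``
    elsewhere.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    if sample_kind not in ("normal", "tumor"):
        raise ValueError("sample_kind must be 'normal' or 'tumor'")
    if sample_kind == "tumor" and not truth.variants["somatic"].any():
        import warnings
        warnings.warn("tumor pileups requested but truth has no somatic variants")

    rng = np.random.default_rng(seed)
    var = truth.variants
    rows = []
    if len(var):
        rows.append(var[["chrom", "pos", "ref", "alt"]].assign(
            f=var["allele_fraction"].to_numpy(),
            somatic=var["somatic"].to_numpy()))
    # background (non-variant) sites
    n_bg_per = {c: int(round(n_background_sites * layout.lengths[c]
                             / sum(layout.lengths.values())))
                for c in layout.chromosomes}
    for chrom, n_bg in n_bg_per.items():
        pos = rng.integers(1, layout.lengths[chrom], size=n_bg)
        ref_i = rng.integers(0, 4, size=n_bg)
        alt_i = (ref_i + rng.integers(1, 4, size=n_bg)) % 4
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref": BASES[ref_i], "alt": BASES[alt_i],
            "f": 0.0, "somatic": False}))
    df = (pd.concat(rows, ignore_index=True)
            .drop_duplicates(subset=["chrom", "pos"])
            .sort_values(["chrom", "pos"]).reset_index(drop=True))

    dist = np.concatenate([
        distance_to_nearest_site(g["pos"].to_numpy() - 1, layout.sites[chrom])
        for chrom, g in df.groupby("chrom", sort=False)])
    w = 1.0 + capture_bias * np.exp(-dist / CAPTURE_SCALE_BP)
    w /= w.mean()
    dp = rng.poisson(mean_depth * w)

    f = df["f"].to_numpy().copy()
    if sample_kind == "tumor":
        f[df["somatic"].to_numpy()] *= truth.purity
    else:
        f[df["somatic"].to_numpy()] = 0.0  # somatic signal absent in normal
    p = np.where(f > 0, f, error_rate)
    dv = rng.binomial(dp, p)

    return pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos"].astype(int),
        "ref": df["ref"], "alt": df["alt"],
        "DP": dp.astype(int), "DV": dv.astype(int)})


def distance_to_nearest_site(pos: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Distance (bp) from each 0-based position to its nearest site, either side."""
    if len(sites) == 0:
        raise ValueError("empty site list")
    idx = np.searchsorted(sites, pos)
    left = np.where(idx > 0, pos - sites[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
    right = np.where(idx < len(sites), sites[np.minimum(idx, len(sites) - 1)] - pos,
                     np.iinfo(np.int64).max)
    return np.abs(np.minimum(left, right))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def make_gene_table(layout: GenomeLayout, n_genes: int = 400, seed: int = 0) -> pd.DataFrame:
    """Random gene table: name, chrom, tss (0-based), base mean expression."""
    rng = np.random.default_rng(seed)
    chroms = rng.choice(layout.chromosomes, size=n_genes,
                        p=[layout.lengths[c] / sum(layout.lengths.values())
                           for c in layout.chromosomes])
    tss = np.array([rng.integers(0, layout.lengths[c]) for c in chroms])
    return pd.DataFrame({
        "gene": [f"G{i:05d}" for i in range(n_genes)],
        "chrom": chroms, "tss": tss,
        "base_mean": np.exp(rng.uniform(np.log(50), np.log(2000), size=n_genes)),
    })


def plant_deg_effects(
    truth: SyntheticTruth,
    genes: pd.DataFrame,
    layout: GenomeLayout,
    couple_to_switches: bool = True,
    switch_lfc: float = 1.0,
    background_deg_fraction: float = 0.1,
    background_lfc: float = 1.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Assign log2 fold changes: +lfc to B->A genes, -lfc to A->B, plus a
    random background fraction of DEGs elsewhere.  Mutates ``truth.deg_effects``."""
    rng = np.random.default_rng(seed)
    effects: dict[str, float] = {}
    for _, g in genes.iterrows():
        cb = int(g["tss"] // truth.compartment_bin_size)
        vn = truth.compartments[g["chrom"]][cb]
        vt = truth.tumor_compartments[g["chrom"]][cb]
        if couple_to_switches and vn == -1 and vt == 1:
            effects[g["gene"]] = switch_lfc
        elif couple_to_switches and vn == 1 and vt == -1:
            effects[g["gene"]] = -switch_lfc
        elif rng.random() < background_deg_fraction:
            effects[g["gene"]] = float(rng.choice([-1, 1])) * background_lfc
        else:
            effects[g["gene"]] = 0.0
    truth.deg_effects = effects
    return truth


def simulate_expression(
    genes: pd.DataFrame,
    truth: SyntheticTruth,
    n_replicates: int = 2,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate NB counts for normal and tumor: mean mu_g * 2^(lfc_g) in tumor."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    mu = genes["base_mean"].to_numpy()
    lfc = np.array([truth.deg_effects.get(g, 0.0) for g in genes["gene"]])

    def draw(means):
        cols = {}
        for r in range(n_replicates):
            if dispersion == 0:
                cols[f"rep{r + 1}"] = rng.poisson(means)
            else:
                nb_n = 1.0 / dispersion
                cols[f"rep{r + 1}"] = rng.negative_binomial(
                    nb_n, nb_n / (nb_n + means))
        return pd.DataFrame(cols, index=genes["gene"].to_numpy())

    return draw(mu), draw(mu * 2.0 ** lfc)
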