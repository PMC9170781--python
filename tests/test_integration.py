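"""Differential expression, switch grouping, chromosome summary, mutation-rate
association."""

import numpy as np
import pandas as pd
import pytest

import hicova as hv


def truth_switch_tables(truth, layout, resolution=500_000):
    """Switch tables built from planted labels (isolates downstream logic)."""
    tables = {}
    for c in layout.chromosomes:
        vn, vt = truth.compartments[c], truth.tumor_compartments[c]
        pn = hv.CompartmentProfile(c, resolution, vn.astype(float),
                                   np.where(vn > 0, "A", "B").astype(str), 1, 0)
        pt = hv.CompartmentProfile(c, resolution, vt.astype(float),
                                   np.where(vt > 0, "A", "B").astype(str), 1, 0)
        tables[c] = hv.switch_table(pn, pt)
    return tables


@pytest.fixture(scope="module")
def deg_layout():
    return hv.make_genome_layout(seed=91)


@pytest.fixture(scope="module")
def deg_genes(deg_layout):
    return hv.make_gene_table(deg_layout, n_genes=1000, seed=91)


class TestDegTest:
    def test_null_fdr_controlled(self, deg_layout, deg_genes):
        # identical-group simulations: mean V/max(R,1) at q<0.05 stays <= nominal
        false_rates = []
        for s in range(25):
            tr = hv.make_truth(deg_layout, seed=400 + s)
            tr.deg_effects = {g: 0.0 for g in deg_genes["gene"]}
            en, et = hv.simulate_expression(deg_genes, tr, seed=500 + s)
            res = hv.deg_test(en, et)
            rejections = int(res["deg"].sum())
            false_rates.append(1.0 if rejections > 0 else 0.0)
        assert np.mean(false_rates) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 25)

    def test_planted_effect_regression_values(self, deg_layout, deg_genes):
        # 2-fold effects in ~10% of genes, 2 replicates, dispersion 0.05
        rng = np.random.default_rng(91)
        tr = hv.make_truth(deg_layout, seed=91)
        eff = {g: (1.0 if rng.random() < 0.1 else 0.0)
               for g in deg_genes["gene"]}
        tr.deg_effects = eff
        en, et = hv.simulate_expression(deg_genes, tr, n_replicates=2,
                                        dispersion=0.05, seed=92)
        res = hv.deg_test(en, et)
        truth = np.array([eff[g] for g in res.index]) != 0
        called = res["deg"].to_numpy()
        recall = (called & truth).sum() / truth.sum()
        fdr = (called & ~truth).sum() / max(called.sum(), 1)
        assert recall == pytest.approx(0.3217, abs=1e-4)
        assert fdr == 0.0

    def test_size_factor_scaling_identity(self, deg_layout, deg_genes):
        tr = hv.make_truth(deg_layout, seed=93)
        tr.deg_effects = {g: 0.0 for g in deg_genes["gene"]}
        en, et = hv.simulate_expression(deg_genes, tr, seed=94)
        base = hv.deg_test(en, et)
        scaled = en.copy()
        scaled["rep1"] = scaled["rep1"] * 2
        sf_base = hv.size_factors(pd.concat([en, et], axis=1))
        sf_scaled = hv.size_factors(pd.concat([scaled, et], axis=1))
        # size factors are relative: the scaled sample doubles against the rest
        assert (sf_scaled.iloc[0] / sf_scaled.iloc[2]) == pytest.approx(
            2 * sf_base.iloc[0] / sf_base.iloc[2], rel=1e-9)
        rerun = hv.deg_test(scaled, et)
        # invariant up to the pseudo-count (normalized counts shift by 2^(1/4))
        np.testing.assert_allclose(rerun["log2fc"], base["log2fc"], atol=5e-3)

    def test_replicate_relabeling_invariance(self, deg_layout, deg_genes):
        tr = hv.make_truth(deg_layout, seed=95)
        tr.deg_effects = {g: 0.0 for g in deg_genes["gene"]}
        en, et = hv.simulate_expression(deg_genes, tr, n_replicates=3, seed=96)
        shuffled = en[["rep3", "rep1", "rep2"]]
        shuffled.columns = ["rep1", "rep2", "rep3"]
        a, b = hv.deg_test(en, et), hv.deg_test(shuffled, et)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_all_zero_gene_excluded(self, deg_layout):
        genes = hv.make_gene_table(deg_layout, n_genes=50, seed=97)
        tr = hv.make_truth(deg_layout, seed=97)
        tr.deg_effects = {g: 0.0 for g in genes["gene"]}
        en, et = hv.simulate_expression(genes, tr, seed=98)
        en.iloc[0] = 0
        et.iloc[0] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            res = hv.deg_test(en, et)
        assert not res["tested"].iloc[0]
        assert np.isnan(res["p"].iloc[0])

    def test_too_few_replicates_rejected(self, deg_layout, deg_genes):
        tr = hv.make_truth(deg_layout, seed=99)
        tr.deg_effects = {g: 0.0 for g in deg_genes["gene"]}
        en, et = hv.simulate_expression(deg_genes, tr, seed=99)
        with pytest.raises(ValueError):
            hv.deg_test(en[["rep1"]], et)


class TestGroupBySwitch:
    def test_coupled_simulation_ordering(self, deg_layout):
        genes = hv.make_gene_table(deg_layout, n_genes=600, seed=101)
        tr = hv.make_truth(deg_layout, seed=101)
        tr = hv.plant_deg_effects(tr, genes, deg_layout, seed=102)
        en, et = hv.simulate_expression(genes, tr, seed=103)
        degs = hv.deg_test(en, et)
        grouping = hv.group_by_switch(degs, truth_switch_tables(tr, deg_layout),
                                      genes)
        assert grouping.medians["B->A"] > grouping.medians["stable"]
        assert grouping.medians["stable"] > grouping.medians["A->B"]
        assert grouping.trend_rho > 0
        assert grouping.trend_p < 0.01

    def test_class_sizes_sum_to_mapped_genes(self, deg_layout):
        genes = hv.make_gene_table(deg_layout, n_genes=300, seed=104)
        tr = hv.make_truth(deg_layout, seed=104)
        tr = hv.plant_deg_effects(tr, genes, deg_layout, seed=105)
        en, et = hv.simulate_expression(genes, tr, seed=106)
        degs = hv.deg_test(en, et)
        grouping = hv.group_by_switch(degs, truth_switch_tables(tr, deg_layout),
                                      genes)
        assert sum(grouping.class_sizes.values()) == len(grouping.table)
        assert len(grouping.table) + grouping.n_unmapped == len(genes)

    def test_no_switches_trend_undefined(self, deg_layout):
        genes = hv.make_gene_table(deg_layout, n_genes=200, seed=107)
        tr = hv.make_truth(deg_layout, seed=107, switch_b_to_a=0.0,
                           switch_a_to_b=0.0)
        tr = hv.plant_deg_effects(tr, genes, deg_layout, seed=108)
        en, et = hv.simulate_expression(genes, tr, seed=109)
        degs = hv.deg_test(en, et)
        grouping = hv.group_by_switch(degs, truth_switch_tables(tr, deg_layout),
                                      genes)
        assert np.isnan(grouping.trend_p)
        assert grouping.class_sizes["B->A"] == 0

    def test_uncoupled_simulation_trend_null(self, deg_layout):
        hits, n_sims = 0, 40
        for s in range(n_sims):
            genes = hv.make_gene_table(deg_layout, n_genes=300,
                                       seed=40_000 + s)
            tr = hv.make_truth(deg_layout, seed=10_000 + s)
            tr = hv.plant_deg_effects(tr, genes, deg_layout,
                                      couple_to_switches=False,
                                      background_deg_fraction=0.1,
                                      seed=20_000 + s)
            en, et = hv.simulate_expression(genes, tr, seed=30_000 + s)
            degs = hv.deg_test(en, et)
            grouping = hv.group_by_switch(
                degs, truth_switch_tables(tr, deg_layout), genes)
            if np.isfinite(grouping.trend_p) and grouping.trend_p < 0.05:
                hits += 1
        # nominal 5% plus ~2.5 binomial SDs of Monte-Carlo error
        assert hits <= 7


class TestChromosomeSummary:
    def test_coupled_alterations_correlate(self):
        layout, cnv, tad_pairs, genes, en, et, _ = \
            hv.simulate_coupled_alterations(seed=3)
        comparisons = {c: hv.classify_conservation(a, b)
                       for c, (a, b) in tad_pairs.items()}
        degs = hv.deg_test(en, et)
        summary = hv.chromosome_summary(cnv, comparisons, degs, genes, layout)
        assert len(summary.fractions) == 12
        corr = summary.correlations.set_index("pair")
        assert corr.loc["cnv_fraction~tad_changed_fraction", "spearman_p"] < 0.05
        assert corr.loc["cnv_fraction~deg_fraction", "spearman_p"] < 0.05
        assert (corr["spearman_rho"] > 0).all()

    def test_degenerate_fractions_warn_na(self, deg_layout, deg_genes):
        from hicova.cnv import CnvSegments
        from hicova.domains import TadComparison
        cnv = {}
        tads = {}
        for c in deg_layout.chromosomes:
            cnv[c] = CnvSegments(
                chrom=c, resolution=40_000,
                segments=pd.DataFrame([(0, deg_layout.lengths[c], 2, 1.0)],
                                      columns=["start", "end", "state",
                                               "mean_coverage"]),
                copy_ratio=np.ones(deg_layout.n_bins(c)))
            status = pd.DataFrame([(0, 400_000, "conserved")],
                                  columns=["start", "end", "status"])
            tads[c] = TadComparison(status_a=status, status_b=status,
                                    counts={"conserved_a": 1, "changed_a": 0,
                                            "conserved_b": 1, "changed_b": 0})
        tr = hv.make_truth(deg_layout, seed=130)
        tr.deg_effects = {g: 0.0 for g in deg_genes["gene"]}
        en, et = hv.simulate_expression(deg_genes, tr, seed=131)
        degs = hv.deg_test(en, et)
        with pytest.warns(UserWarning, match="degenerate"):
            summary = hv.chromosome_summary(cnv, tads, degs, deg_genes,
                                            deg_layout)
        assert (summary.fractions["cnv_fraction"] == 0).all()
        assert summary.correlations["pearson_r"].isna().all()


class TestMutationCompartmentAssociation:
    def planted_rate_inputs(self, ratio_b_over_a, seed, n_chrom=2):
        layout = hv.make_genome_layout(n_chromosomes=n_chrom, seed=seed)
        tr = hv.make_truth(layout, seed=seed)
        rng = np.random.default_rng(seed)
        states, rows = {}, []
        for c in layout.chromosomes:
            v = tr.compartments[c]
            states[c] = np.where(v > 0, "A", "B").astype(str)
            lam = np.where(states[c] == "B", ratio_b_over_a, 1.0) * 2.0
            counts = rng.poisson(lam)
            for b, k in enumerate(counts):
                rows += [(c, b * 500_000 + 1 + int(rng.integers(0, 400_000)))
                         for _ in range(k)]
        calls = pd.DataFrame(rows, columns=["chrom", "pos"])
        track = hv.mutation_rate_track(calls, layout, bin_size=500_000)
        return track, states

    def test_planted_threefold_ratio_recovered(self):
        track, states = self.planted_rate_inputs(3.0, seed=141)
        ratio, p = hv.mutation_compartment_association(track, states,
                                                       n_permutations=999,
                                                       seed=1)
        assert 2.0 < ratio < 4.5
        assert p < 0.01

    def test_equal_rates_ratio_near_one(self):
        track, states = self.planted_rate_inputs(1.0, seed=142)
        ratio, p = hv.mutation_compartment_association(track, states,
                                                       n_permutations=499,
                                                       seed=2)
        assert 0.7 < ratio < 1.4
        assert p >= 1 / 500

    def test_p_value_bounds(self):
        track, states = self.planted_rate_inputs(3.0, seed=143)
        _, p = hv.mutation_compartment_association(track, states,
                                                   n_permutations=99, seed=3)
        assert 1 / 100 <= p <= 1.0

    def test_single_class_rejected(self):
        track, states = self.planted_rate_inputs(1.0, seed=144)
        all_a = {c: np.full(len(s), "A") for c, s in states.items()}
        with pytest.raises(ValueError, match="non-empty"):
            hv.mutation_compartment_association(track, all_a)

    def test_zero_mutations_rejected(self, deg_layout):
        track = hv.mutation_rate_track(
            pd.DataFrame(columns=["chrom", "pos"]), deg_layout,
            bin_size=500_000)
        states = {c: np.array(["A", "B"] * (len(track.rates[c]) // 2)
                              + ["A"] * (len(track.rates[c]) % 2))
                  for c in track.rates}
        with pytest.raises(ValueError, match="no mutations"):
            hv.mutation_compartment_association(track, states)
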