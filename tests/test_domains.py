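"""Insulation scoring, TAD assembly/filtering, reciprocal-overlap conservation."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import hicova as hv
from hicova.domains import TadSet


def make_tadset(intervals, chrom="chr1", resolution=40_000):
    return TadSet(chrom=chrom, resolution=resolution,
                  intervals=pd.DataFrame(intervals, columns=["start", "end"]))


def brute_force_insulation(matrix, w):
    """Independent window-mean oracle evaluated at every bin."""
    n = len(matrix)
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        vals = [matrix[r, c] for r in range(i - w, i)
                for c in range(i + 1, i + w + 1)]
        raw[i] = float(np.mean(vals))
    return raw


class TestInsulation:
    def test_uniform_matrix_no_boundaries(self):
        n = 120
        m = np.full((n, n), 4.0)
        np.fill_diagonal(m, 0.0)
        cm = hv.ContactMatrix("chr1", 40_000, m, provenance="iced",
                              bias=np.ones(n))
        prof = hv.insulation_profile(cm, window=480_000)
        defined = np.isfinite(prof.insulation)
        assert np.allclose(prof.insulation[defined], 0.0, atol=1e-9)
        assert len(prof.boundaries) == 0

    def test_two_block_matrix_single_boundary(self):
        # strong within-block contacts, exactly one junction at bin 60
        n, junction = 120, 60
        m = np.ones((n, n))
        m[:junction, :junction] = 20.0
        m[junction:, junction:] = 20.0
        np.fill_diagonal(m, 0.0)
        cm = hv.ContactMatrix("chr1", 40_000, m, provenance="iced",
                              bias=np.ones(n))
        w = 12
        prof = hv.insulation_profile(cm, window=w * 40_000)

        oracle = brute_force_insulation(m, w)
        assert np.nanargmin(oracle) in (junction - 1, junction)
        defined = np.isfinite(prof.insulation) & np.isfinite(oracle)
        np.testing.assert_allclose(
            prof.insulation[defined],
            np.log2(oracle[defined] / oracle[defined].mean()), atol=1e-9)

        assert len(prof.boundaries) == 1
        assert abs(int(prof.boundaries["bin"].iloc[0]) - junction) <= 1

    def test_planted_boundaries_recovered(self, layout_one, tad_truth, tad_map):
        iced, _ = hv.ice_normalize(tad_map)
        prof = hv.insulation_profile(iced)
        defined = np.isfinite(prof.insulation)
        planted = [b for b in tad_truth.tad_boundaries("chr1")
                   if 0 < b < tad_map.n_bins - 1
                   and defined[max(b - 1, 0): b + 2].any()]
        recall, false_rate = hv.boundary_recovery(
            prof.boundaries["bin"].to_numpy(), planted)
        assert recall >= 0.90
        assert false_rate <= 0.10

    def test_low_input_boundary_recovery(self, layout_one, tad_truth, tad_map):
        # 1% of the read pairs (the cell-number-gradient regime) still
        # recovers the planted domain boundaries
        thin = hv.downsample_pairs(tad_map, 0.01, seed=5)
        iced, _ = hv.ice_normalize(thin)
        prof = hv.insulation_profile(iced)
        defined = np.isfinite(prof.insulation)
        planted = [b for b in tad_truth.tad_boundaries("chr1")
                   if 0 < b < tad_map.n_bins - 1
                   and defined[max(b - 1, 0): b + 2].any()]
        recall, _ = hv.boundary_recovery(prof.boundaries["bin"].to_numpy(),
                                         planted)
        assert recall >= 0.80

    def test_thinned_map_more_conserved_than_different_truth(
            self, layout_one, tad_truth, tad_map):
        def call(m):
            iced, _ = hv.ice_normalize(m)
            return hv.assemble_tads(hv.insulation_profile(iced), layout_one)

        base = call(tad_map)
        thin = call(hv.downsample_pairs(tad_map, 0.01, seed=6))
        other_truth = hv.make_truth(layout_one, seed=955, gamma=0.0, tau=3.0,
                                    lam=1.0, n_loops_per_chrom=1)
        other = call(hv.simulate_contact_map(layout_one, other_truth,
                                             depth=2_000_000,
                                             seed=956)["chr1"])

        def conserved_fraction(cmp_):
            n = cmp_.counts["conserved_a"] + cmp_.counts["changed_a"]
            return cmp_.counts["conserved_a"] / n

        assert conserved_fraction(hv.classify_conservation(base, thin)) > \
            conserved_fraction(hv.classify_conservation(base, other))

    def test_boundaries_scale_invariant(self, iced_map):
        iced, _ = iced_map
        a = hv.insulation_profile(iced)
        b = hv.insulation_profile(iced.scaled(11.0))
        np.testing.assert_array_equal(a.boundaries["bin"], b.boundaries["bin"])

    def test_window_too_large_rejected(self, iced_map):
        with pytest.raises(ValueError):
            hv.insulation_profile(iced_map[0], window=12_000_000)


class TestAssembleTads:
    def test_boundary_pair_arithmetic(self, layout_one):
        prof = hv.InsulationProfile(
            chrom="chr1", resolution=40_000,
            insulation=np.zeros(500), delta=np.zeros(500),
            boundaries=pd.DataFrame({"bin": [10, 25], "strength": [1.0, 1.0]}))
        tads = hv.assemble_tads(prof, layout_one)
        assert len(tads) == 1
        assert tads.intervals.iloc[0].tolist() == [400_000, 1_000_000]
        assert tads.lengths[0] == 600_000

    def test_short_tad_dropped(self, layout_one):
        prof = hv.InsulationProfile(
            chrom="chr1", resolution=40_000,
            insulation=np.zeros(500), delta=np.zeros(500),
            boundaries=pd.DataFrame({"bin": [20, 24], "strength": [1.0, 1.0]}))
        tads = hv.assemble_tads(prof, layout_one)  # 160 kb < 200 kb
        assert len(tads) == 0

    def test_masked_overlap_dropped(self, layout_one):
        masked_bin = int(np.flatnonzero(layout_one.mask["chr1"])[2])
        prof = hv.InsulationProfile(
            chrom="chr1", resolution=40_000,
            insulation=np.zeros(500), delta=np.zeros(500),
            boundaries=pd.DataFrame({"bin": [masked_bin - 5, masked_bin + 5],
                                     "strength": [1.0, 1.0]}))
        tads = hv.assemble_tads(prof, layout_one)
        assert len(tads) == 0

    def test_too_few_boundaries_warns_empty(self, layout_one):
        prof = hv.InsulationProfile(
            chrom="chr1", resolution=40_000,
            insulation=np.zeros(500), delta=np.zeros(500),
            boundaries=pd.DataFrame({"bin": [10], "strength": [1.0]}))
        with pytest.warns(UserWarning):
            tads = hv.assemble_tads(prof, layout_one)
        assert len(tads) == 0


class TestConservation:
    def test_identical_tad_conserved(self):
        a = make_tadset([(0, 1_000_000)])
        cmp_ = hv.classify_conservation(a, make_tadset([(0, 1_000_000)]))
        assert cmp_.status_a["status"].tolist() == ["conserved"]
        assert cmp_.counts == {"conserved_a": 1, "changed_a": 0,
                               "conserved_b": 1, "changed_b": 0}

    def test_half_overlap_changed(self):
        # overlap 0.5 Mb is 50% of both 1-Mb TADs: below 0.8, changed
        a = make_tadset([(0, 1_000_000)])
        b = make_tadset([(500_000, 1_500_000)])
        cmp_ = hv.classify_conservation(a, b)
        assert cmp_.status_a["status"].tolist() == ["changed"]

    def test_reciprocal_rule_arithmetic(self):
        # overlap 0.9 Mb: 90% of 1.0 Mb and 94.7% of 0.95 Mb -> conserved
        a = make_tadset([(0, 1_000_000)])
        b = make_tadset([(100_000, 1_050_000)])
        cmp_ = hv.classify_conservation(a, b)
        assert cmp_.status_a["status"].tolist() == ["conserved"]
        assert cmp_.status_b["status"].tolist() == ["conserved"]

    def test_one_sided_overlap_not_conserved(self):
        # small TAD fully inside a big one: fraction of the big one too low
        a = make_tadset([(0, 400_000)])
        b = make_tadset([(0, 1_600_000)])
        cmp_ = hv.classify_conservation(a, b)
        assert cmp_.status_a["status"].tolist() == ["changed"]

    def test_empty_target_all_changed(self):
        a = make_tadset([(0, 1_000_000)])
        with pytest.warns(UserWarning):
            cmp_ = hv.classify_conservation(a, make_tadset([]))
        assert cmp_.status_a["status"].tolist() == ["changed"]

    @pytest.mark.skipif(shutil.which("intersectBed") is None,
                        reason="bedtools not on PATH")
    def test_matches_bedtools_oracle(self, tmp_path):
        rng = np.random.default_rng(17)
        def random_set(seed):
            r = np.random.default_rng(seed)
            starts = np.sort(r.choice(np.arange(0, 19_000_000, 40_000), 25,
                                      replace=False))
            ends = starts + r.integers(6, 30, 25) * 40_000
            ends = np.minimum(ends, np.r_[starts[1:], 20_000_000])
            keep = ends - starts >= 240_000
            return make_tadset(list(zip(starts[keep], ends[keep])))
        a, b = random_set(1), random_set(2)
        fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
        for ts, path in ((a, fa), (b, fb)):
            ts.intervals.assign(chrom="chr1")[["chrom", "start", "end"]].to_csv(
                path, sep="\t", header=False, index=False)
        out = subprocess.run(
            ["intersectBed", "-a", fa, "-b", fb, "-f", "0.80", "-r", "-u"],
            capture_output=True, text=True, check=True).stdout
        conserved_bedtools = {tuple(map(int, line.split("\t")[1:3]))
                              for line in out.strip().splitlines() if line}
        cmp_ = hv.classify_conservation(a, b)
        mine = {(int(r.start), int(r.end))
                for r in cmp_.status_a.itertuples() if r.status == "conserved"}
        assert mine == conserved_bedtools


class TestLengthSummary:
    def test_single_tad_median(self):
        summary = hv.tad_length_summary({"s": make_tadset([(0, 600_000)])})
        assert summary["median"].iloc[0] == 600_000

    def test_empty_set_na_row(self):
        summary = hv.tad_length_summary({"empty": make_tadset([])})
        assert np.isnan(summary["median"].iloc[0])
        assert summary["n_tads"].iloc[0] == 0

    def test_filter_floor_respected(self, layout_one, iced_map):
        iced, _ = iced_map
        tads = hv.assemble_tads(hv.insulation_profile(iced), layout_one)
        assert (tads.lengths > 200_000).all()
        summary = hv.tad_length_summary({"called": tads})
        assert summary["median"].iloc[0] > 200_000

    def test_no_sets_rejected(self):
        with pytest.raises(ValueError):
            hv.tad_length_summary({})
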