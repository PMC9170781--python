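"""Shared fixtures: small planted-truth genomes and contact maps.

Session-scoped so the heavier simulations are built once per run.
"""

import numpy as np
import pytest

import hicova as hv


@pytest.fixture(scope="session")
def layout_one():
    """One 20-Mb chromosome at 40 kb (500 bins)."""
    return hv.make_genome_layout(n_chromosomes=1, lengths=[20_000_000],
                                 bin_size=40_000, seed=101)


@pytest.fixture(scope="session")
def truth_one(layout_one):
    return hv.make_truth(layout_one, seed=101)


@pytest.fixture(scope="session")
def raw_map(layout_one, truth_one):
    """Full-structure raw map: compartments + TADs + loops."""
    return hv.simulate_contact_map(layout_one, truth_one, depth=2_000_000,
                                   seed=111)["chr1"]


@pytest.fixture(scope="session")
def iced_map(raw_map):
    iced, bias = hv.ice_normalize(raw_map)
    return iced, bias


@pytest.fixture(scope="session")
def tad_truth(layout_one):
    """TAD-only truth (gamma=0, tau=3): isolates domain structure so boundary
    recovery is scored against planted TADs alone, without the additional
    insulation minima that compartment-block edges create."""
    return hv.make_truth(layout_one, seed=151, gamma=0.0, tau=3.0, lam=1.0,
                         n_loops_per_chrom=1)


@pytest.fixture(scope="session")
def tad_map(layout_one, tad_truth):
    return hv.simulate_contact_map(layout_one, tad_truth, depth=2_000_000,
                                   seed=152)["chr1"]


@pytest.fixture(scope="session")
def flat_truth(layout_one):
    """Decay-only truth: no compartments, TADs, loops, or CNVs."""
    tr = hv.make_truth(layout_one, seed=202, gamma=0.0, tau=1.0, lam=1.0,
                       n_loops_per_chrom=1)
    tr.loops["chr1"] = []
    return tr


@pytest.fixture(scope="session")
def flat_map(layout_one, flat_truth):
    return hv.simulate_contact_map(layout_one, flat_truth, depth=2_000_000,
                                   seed=203)["chr1"]


@pytest.fixture(scope="session")
def comp_layout():
    """One 50-Mb chromosome binned directly at 500 kb (100 bins)."""
    return hv.make_genome_layout(n_chromosomes=1, lengths=[50_000_000],
                                 bin_size=500_000, seed=301)


@pytest.fixture(scope="session")
def comp_truth(comp_layout):
    return hv.make_truth(comp_layout, seed=301, tau=1.0, lam=1.0,
                         n_loops_per_chrom=1, compartment_bin_size=500_000,
                         switch_b_to_a=0.05, switch_a_to_b=0.0)


@pytest.fixture(scope="session")
def comp_maps(comp_layout, comp_truth):
    normal = hv.simulate_contact_map(comp_layout, comp_truth,
                                     depth=2_000_000, seed=302)["chr1"]
    tumor = hv.simulate_contact_map(comp_layout, comp_truth, depth=2_000_000,
                                    tumor=True, seed=303)["chr1"]
    return normal, tumor


def truth_labels(truth, chrom="chr1"):
    v = truth.compartments[chrom]
    return np.where(v > 0, "A", "B")
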