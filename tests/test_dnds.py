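"""Pairwise dN/dS: difference counting, site sums, method comparison."""

import math

import numpy as np
import pytest

from codonsites import (
    compare_methods,
    count_differences,
    dnds_pair,
    gene_composition,
    gene_sites,
    random_reference,
    simulate_pair,
)
from codonsites.dnds import FrameError, InternalStopError


class TestGeneSites:
    def test_sum_of_per_codon_values(self):
        gs = gene_sites("ATGTGG", "modified", 4)
        assert gs.S_total == pytest.approx(0.0)
        assert gs.N_total == pytest.approx(3.0 + 10 / 6)  # 4.667
        gs_old = gene_sites("ATGTGG", "old")
        assert (gs_old.S_total, gs_old.N_total) == (0.0, 6.0)

    def test_old_method_site_conservation(self):
        gs = gene_sites("ATGAAACCCGGG", "old")
        assert gs.S_total + gs.N_total == pytest.approx(3 * gs.n_codons_counted)

    def test_empty_sequence(self):
        gs = gene_sites("")
        assert (gs.S_total, gs.N_total, gs.n_codons_counted) == (0.0, 0.0, 0)

    def test_terminal_stop_stripped_but_internal_stop_raises(self):
        gs = gene_sites("ATGAAATAA", "old")
        assert gs.n_codons_counted == 2
        with pytest.raises(InternalStopError, match="codon 2"):
            gene_sites("ATGTAAAAA", "old")
        gs = gene_sites("ATGTAAAAA", "old", on_internal_stop="skip")
        assert gs.n_codons_counted == 2 and gs.n_codons_skipped == 1

    def test_ambiguous_codons_skipped_and_counted(self):
        gs = gene_sites("ATGNNNAAA", "old")
        assert gs.n_codons_counted == 2 and gs.n_codons_skipped == 1

    def test_frame_error_names_record(self):
        with pytest.raises(FrameError, match="geneX"):
            gene_sites("ATGA", seq_id="geneX")

    def test_skip_start_excludes_initiation_codon(self):
        with_start = gene_sites("ATGAAA", "old")
        without = gene_sites("ATGAAA", "old", skip_start=True)
        assert with_start.N_total - without.N_total == pytest.approx(3.0)


class TestCountDifferences:
    def test_identical_sequences(self):
        d = count_differences("ATGAAA", "ATGAAA")
        assert (d.sd, d.nd, d.n_single, d.n_multi, d.n_identical) == (0, 0, 0, 0, 2)

    @pytest.mark.parametrize(
        "a,b,sd,nd",
        [
            ("TTT", "TTC", 1, 0),  # Phe -> Phe
            ("ATG", "ACG", 0, 1),  # Met -> Thr
        ],
    )
    def test_single_difference_classification(self, a, b, sd, nd):
        d = count_differences(a, b)
        assert (d.sd, d.nd) == (sd, nd)
        assert d.sd + d.nd == d.n_single

    def test_multi_difference_codons_excluded(self):
        d = count_differences("TTT", "TAC")
        assert (d.sd, d.nd, d.n_multi) == (0, 0, 1)

    def test_stop_and_ambiguous_pairs_excluded(self):
        d = count_differences("TAAATG", "TACATG")
        assert d.n_excluded == 1 and d.n_identical == 1
        d = count_differences("TTNATG", "TTCATG")
        assert d.n_excluded == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(FrameError, match="length"):
            count_differences("ATGATG", "ATG")


class TestDnDsPair:
    def test_arithmetic_from_definition(self):
        # craft a pair: one synonymous, one non-synonymous single difference
        a = "TTTATGGGG"
        b = "TTCATGGGC"  # TTT->TTC syn; GGG->GGC syn... use ATG->ACG instead
        b = "TTCACGGGG"
        res = dnds_pair(a, b, "old", ids=("a", "b"))
        assert (res.sd, res.nd) == (1, 1)
        assert res.ps == pytest.approx(res.sd / res.s_sites)
        assert res.pn == pytest.approx(res.nd / res.n_sites)
        assert res.ratio == pytest.approx(res.pn / res.ps)

    def test_sites_are_averaged_between_sequences(self):
        a, b = "TTTATG", "TTTACG"
        res = dnds_pair(a, b, "old")
        ga, gb = gene_sites(a, "old"), gene_sites(b, "old")
        assert res.s_sites == pytest.approx((ga.S_total + gb.S_total) / 2)
        res_first = dnds_pair(a, b, "old", sites="first")
        assert res_first.s_sites == pytest.approx(ga.S_total)

    def test_undefined_ratio_flagged_not_zero(self):
        res = dnds_pair("ATGAAA", "ACGAAA", "old")  # only a non-syn diff
        assert res.ratio is None
        assert res.undefined_reason == "no_synonymous_differences"

    def test_symmetry_is_exact(self, rng):
        ref = random_reference(120, rng)
        a, b = simulate_pair(ref, 25, kappa=4.0, omega=0.6, rng=rng)
        r_ab = dnds_pair(a, b, "modified", 4.0)
        r_ba = dnds_pair(b, a, "modified", 4.0)
        assert (r_ab.sd, r_ab.nd, r_ab.s_sites, r_ab.n_sites, r_ab.ratio) == (
            r_ba.sd, r_ba.nd, r_ba.s_sites, r_ba.n_sites, r_ba.ratio,
        )

    def test_determinism(self, rng):
        ref = random_reference(60, rng)
        a, b = simulate_pair(ref, 10, rng=rng)
        assert dnds_pair(a, b) == dnds_pair(a, b)

    def test_jukes_cantor_correction_increases_distance(self, rng):
        ref = random_reference(200, rng)
        a, b = simulate_pair(ref, 60, rng=rng)
        raw = dnds_pair(a, b, "modified", 4.0)
        jc = dnds_pair(a, b, "modified", 4.0, jc_correction=True)
        assert jc.ps > raw.ps and jc.pn > raw.pn


class TestGeneComposition:
    def test_pretermination_fraction(self):
        comp = gene_composition("TGGTAT")
        assert comp.pretermination_fraction == 1.0

    def test_tfd_ffd_counts(self):
        comp = gene_composition("TTTGGG")
        assert (comp.n_tfd, comp.n_ffd) == (1, 1)
        assert comp.tfd_ffd_ratio == pytest.approx(1.0)

    def test_degenerate_input_flagged(self):
        comp = gene_composition("ATGATGATG")
        assert comp.n_tfd == 0 and comp.n_ffd == 0
        assert comp.tfd_ffd_ratio is None

    def test_family_box_codons_count_as_neither(self):
        comp = gene_composition("CTTTCA")  # Leu family box, Ser family box
        assert (comp.n_tfd, comp.n_ffd) == (0, 0)


class TestCompareMethods:
    def test_identical_ratios_give_zero_increase(self):
        # FFD-only genes: old and modified sites coincide -> increase 0
        # FFD-only genes avoiding GGA (its stop neighbor would differ):
        # old and modified site values coincide codon by codon
        genes = [
            ("g1", "GGGGGTCCC", "GGCGCTCCC"),  # Gly syn + Gly->Ala missense
            ("g2", "CCTCCCACA", "CCACCCGCA"),  # Pro syn + Thr->Ala missense
        ]
        comp = compare_methods(genes, kappa=4.0)
        inc = comp.per_gene["percent_increase"].dropna()
        assert np.allclose(inc, 0.0)

    def test_modified_exceeds_old_on_tfd_rich_pairs(self, rng):
        # neutral divergence on a TFD-rich sequence: weighting raises dN/dS
        from codonsites import genetic_code as gc

        weights = {c: (5.0 if gc.degeneracy_class(c) == gc.TWOFOLD else 1.0)
                   for c in gc.SENSE_CODONS}
        ref = random_reference(400, rng, weights)
        a, b = simulate_pair(ref, 80, kappa=4.0, omega=1.0, rng=rng)
        old = dnds_pair(a, b, "old", 4.0)
        new = dnds_pair(a, b, "modified", 4.0)
        assert new.ratio > old.ratio

    def test_too_few_genes_leaves_correlations_undefined(self):
        comp = compare_methods([("g1", "TTTAAA", "TTCAAA")], kappa=4.0)
        assert comp.r_tfd_ffd is None and comp.r_pretermination is None
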