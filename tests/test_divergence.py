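"""Codon alignment handling and NG86 dS/dN estimation."""

import math

import numpy as np
import pytest

from dupscape import divergence
from dupscape.divergence import CodonAlignment, DivergenceInputError
from dupscape.simulate import SENSE_CODON_INDICES, BASES, SimConfig, evolve_sequences, random_cds
from oracles import ng86_pair


def random_pair(rng, n_codons, n_subs):
    """A random stop-free CDS and a mutated copy (stop-free)."""
    a = random_cds(n_codons, rng)
    b = list(a)
    from dupscape.simulate import AA_BY_CODON_INDEX

    for _ in range(n_subs):
        while True:
            i = int(rng.integers(len(b)))
            old = b[i]
            b[i] = BASES[int(rng.integers(4))]
            codon_start = i - i % 3
            codon = "".join(b[codon_start : codon_start + 3])
            idx = BASES.index(codon[0]) * 16 + BASES.index(codon[1]) * 4 + BASES.index(codon[2])
            if AA_BY_CODON_INDEX[idx] != "*":
                break
            b[i] = old
    return a, "".join(b)


class TestBacktranslate:
    def test_ungapped_identity(self, rng):
        cds = random_cds(20, rng)
        from dupscape.simulate import translate

        aln = divergence.backtranslate({"g": translate(cds)}, {"g": cds})
        assert aln.sequences["g"] == cds

    def test_gap_maps_to_triplet(self):
        aln = divergence.backtranslate(
            {"a": "M-F", "b": "MKF"}, {"a": "ATGTTT", "b": "ATGAAATTT"}
        )
        assert aln.sequences["a"] == "ATG---TTT"
        assert aln.sequences["b"] == "ATGAAATTT"

    def test_round_trip_strips_gaps(self, rng):
        from dupscape.simulate import translate

        for _ in range(20):
            cds = random_cds(int(rng.integers(10, 30)), rng)
            protein = translate(cds)
            gapped = ""
            for ch in protein:
                if rng.random() < 0.2:
                    gapped += "-"
                gapped += ch
            aln = divergence.backtranslate({"g": gapped}, {"g": cds})
            assert aln.sequences["g"].replace("-", "") == cds

    def test_translation_mismatch_names_gene_and_position(self):
        with pytest.raises(DivergenceInputError, match="'a'.*residue 2"):
            divergence.backtranslate({"a": "MF"}, {"a": "ATGATG"})


class TestFilterColumns:
    def test_gap_free_alignment_unchanged(self, rng):
        cds = random_cds(12, rng)
        aln = CodonAlignment({"a": cds, "b": cds})
        out = divergence.filter_columns(aln)
        assert out.sequences == aln.sequences and not out.empty

    def test_gapped_column_removed_everywhere(self):
        aln = CodonAlignment(
            {"a": "ATG---AAATTTGGGCCC", "b": "ATGCCCAAATTTGGGCCC"}
        )
        out = divergence.filter_columns(aln)
        assert out.sequences["a"] == "AAATTTGGGCCC"
        assert out.sequences["b"] == "AAATTTGGGCCC"

    def test_short_island_below_min_block_removed(self):
        # 2-codon island between gapped columns is dropped; a clean 27-codon
        # run of a 30-codon alignment is kept
        island = "AAATTT"
        keep = "ATGGCC" * 13 + "ATG"
        a = "---" + island + "---" + keep
        b = "CCC" + island + "GGG" + keep
        out = divergence.filter_columns(CodonAlignment({"a": a, "b": b}), min_block=3)
        assert out.sequences["a"] == keep
        assert out.sequences["b"] == keep

    def test_everything_filtered_is_flagged_not_raised(self):
        out = divergence.filter_columns(CodonAlignment({"a": "---AAA", "b": "AAA---"}))
        assert out.empty
        assert out.sequences["a"] == ""


class TestNg86:
    def test_identical_sequences(self, rng):
        cds = random_cds(15, rng)
        est = divergence.ds_ng86(cds, cds)
        assert est.ds == 0 and est.dn == 0 and not est.saturated

    def test_hand_example_ten_phe_codons(self):
        a = "TTT" * 10
        b = "TTC" + "TTT" * 9
        est = divergence.ds_ng86(a, b)
        assert est.syn_diffs == 1 and est.nonsyn_diffs == 0
        assert est.syn_sites == pytest.approx(10 / 3)
        assert est.ds == pytest.approx(-0.75 * math.log(0.6), abs=1e-9)

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = random_pair(rng, 8, 5)
            e1, e2 = divergence.ds_ng86(a, b), divergence.ds_ng86(b, a)
            assert e1.ds == pytest.approx(e2.ds) or (e1.saturated and e2.saturated)
            assert e1.syn_sites == pytest.approx(e2.syn_sites)

    def test_site_conservation(self, rng):
        for _ in range(20):
            a, b = random_pair(rng, 10, 6)
            est = divergence.ds_ng86(a, b)
            assert est.syn_sites + est.nonsyn_sites == pytest.approx(30.0, abs=1e-9)

    def test_matches_pathway_enumeration_oracle(self, rng):
        for _ in range(150):
            a, b = random_pair(rng, int(rng.integers(2, 9)), int(rng.integers(0, 7)))
            S, N, Sd, Nd = ng86_pair(a, b)
            est = divergence.ds_ng86(a, b)
            assert est.syn_sites == pytest.approx(S, abs=1e-9)
            assert est.syn_diffs == pytest.approx(Sd, abs=1e-9)
            assert est.nonsyn_diffs == pytest.approx(Nd, abs=1e-9)

    def test_mean_ds_nondecreasing_with_branch_length(self):
        cfg = SimConfig(subst_rate=0.002, omega=0.3, seed=8)
        rng = np.random.default_rng(8)
        means = []
        for duration in (25, 100, 400):
            values = []
            for _ in range(15):
                anc = random_cds(60, rng)
                d1, _, _ = evolve_sequences(anc, duration, cfg, rng=rng)
                d2, _, _ = evolve_sequences(anc, duration, cfg, rng=rng)
                est = divergence.ds_ng86(d1, d2)
                values.append(3.0 if est.saturated else est.ds)
            means.append(np.mean(values))
        assert means[0] <= means[1] <= means[2]

    def test_length_mismatch_and_stop_rejected(self):
        with pytest.raises(DivergenceInputError):
            divergence.ds_ng86("ATG", "ATGATG")
        with pytest.raises(DivergenceInputError):
            divergence.ds_ng86("TAA", "ATG")


class TestFamilySummary:
    def test_two_paralogs_min_equals_max(self, rng):
        a, b = random_pair(rng, 12, 4)
        out = divergence.family_ds_summary("f", {"Dmel": ["x", "y"]}, {"x": a, "y": b})
        summary, estimates = out
        assert summary.pair_count == 1
        assert summary.min_ds == summary.max_ds

    def test_three_paralogs_min_max_over_pairs(self, rng):
        seqs = {}
        anc = random_cds(40, rng)
        cfg = SimConfig(subst_rate=0.004, omega=0.2, seed=3)
        for name, duration in (("x", 5), ("y", 60), ("z", 200)):
            seqs[name], _, _ = evolve_sequences(anc, duration, cfg, rng=rng)
        out = divergence.family_ds_summary("f", {"Dmel": ["x", "y", "z"]}, seqs)
        summary, estimates = out
        finite = [e.ds for e in estimates.values() if not e.saturated]
        assert summary.pair_count == 3
        if finite:
            assert summary.min_ds == min(finite)
            assert summary.max_ds == max(finite)

    def test_fewer_than_two_paralogs_skipped(self):
        assert divergence.family_ds_summary("f", {"Dmel": ["x"]}, {"x": "ATG"}) is None

    def test_all_saturated_flagged(self):
        # maximally divergent codons: force saturation
        a = "TTT" * 12
        b = "GGG" * 12
        out = divergence.family_ds_summary("f", {"Dmel": ["x", "y"]}, {"x": a, "y": b})
        summary, _ = out
        assert summary.all_saturated
        assert math.isnan(summary.min_ds)


class TestOldFraction:
    def test_hand_fraction(self):
        assert divergence.old_fraction([0.5, 2.5, 3.0, 1.0]) == 0.5

    def test_all_below_threshold(self):
        assert divergence.old_fraction([0.1, 0.2]) == 0.0

    def test_saturated_counts_as_old(self):
        est = divergence.ds_ng86("TTT" * 12, "GGG" * 12)
        assert est.saturated
        assert divergence.old_fraction([est, 0.1]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(DivergenceInputError):
            divergence.old_fraction([])

    def test_deep_duplications_mostly_old(self):
        # pairs separated by >=2.5 expected synonymous substitutions per
        # site are nearly always binned old (saturated or dS > 2)
        cfg = SimConfig(subst_rate=0.005, omega=0.1, seed=0)
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = []
            for _ in range(10):
                anc = random_cds(80, rng)
                # 2 * 250 My * 0.005 = 2.5 proposals per site per pair path
                d1, _, _ = evolve_sequences(anc, 250, cfg, rng=rng)
                d2, _, _ = evolve_sequences(anc, 250, cfg, rng=rng)
                values.append(divergence.ds_ng86(d1, d2))
            fractions.append(divergence.old_fraction(values))
        assert np.mean(fractions) >= 0.9


class TestHistogram:
    def test_open_top_bin_collects_old_and_saturated(self):
        est = divergence.ds_ng86("TTT" * 12, "GGG" * 12)
        hist = divergence.ds_histogram([0.1, 0.6, 2.4, est])
        assert hist[0][2] == 1 and hist[1][2] == 1
        assert hist[-1][0] == 2.0 and math.isinf(hist[-1][1])
        assert hist[-1][2] == 2
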