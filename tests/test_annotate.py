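"""Duplex hybridization, hairpin folding and k-turn annotation."""

import pytest
from hypothesis import given, settings, strategies as st

from kturn.annotate import (
    AnnotationError,
    Bulge,
    HairpinModel,
    NoDuplexError,
    RNAStrand,
    annotate_positions,
    annotation_table,
    dot_bracket,
    fold_hairpin,
    hybridize_strands,
    scan_kturns,
    scan_sd_consensus,
    sd_overlap,
)
from oracles import oracle_best_duplex_score

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq):
    return "".join(COMP[c] for c in reversed(seq))


class TestRNAStrand:
    def test_rejects_dna_and_empty(self):
        with pytest.raises(ValueError, match="must use U"):
            RNAStrand("x", "ACGT")
        with pytest.raises(ValueError, match="empty"):
            RNAStrand("x", "")

    def test_normalizes_case(self):
        assert RNAStrand("x", "acgu").sequence == "ACGU"


class TestHybridize:
    def test_fret_duplex_geometry(self, fret_duplex):
        """The printed strand pair anneals into one 3-nt GAU bulge with
        12 pairs 5' of it and 13 pairs 3' of it."""
        assert fret_duplex.bulges == [Bulge("bulged", 12, 15)]
        bulge_seq = fret_duplex.bulged_strand.sequence[12:15]
        assert bulge_seq == "GAU"
        before = [p for p in fret_duplex.pairs if p[0] < 12]
        after = [p for p in fret_duplex.pairs if p[0] >= 15]
        assert (len(before), len(after)) == (12, 13)
        assert not fret_duplex.ambiguous

    def test_perfect_complement_fully_paired(self):
        d = hybridize_strands(RNAStrand("a", "GGGAAACCC"),
                              RNAStrand("b", "GGGUUUCCC"), max_bulge=0)
        assert len(d.pairs) == 9
        assert d.bulges == []
        assert d.score == 9

    def test_two_nt_insertion_matches_oracle(self):
        """A 10-nt strand with a 2-nt insertion against its complement
        scores exactly what exhaustive alignment enumeration finds."""
        core = "GCAUGGCAUC"
        bulged = core[:5] + "AA" + core[5:]
        partner = revcomp(core)
        d = hybridize_strands(RNAStrand("b", bulged), RNAStrand("p", partner),
                              max_bulge=2)
        assert d.score == oracle_best_duplex_score(bulged, partner, 2) == 10
        assert d.bulges and len(d.bulges[0]) == 2

    def test_no_duplex_error(self):
        with pytest.raises(NoDuplexError):
            hybridize_strands(RNAStrand("a", "AAAA"), RNAStrand("b", "CCCC"),
                              max_bulge=1)

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(st.data())
    def test_agrees_with_exhaustive_oracle(self, data):
        """Alignment score equals the brute-force enumeration over all
        non-crossing one-bulge alignments for random strands <= 12 nt."""
        bases = "ACGU"
        b = data.draw(st.text(bases, min_size=4, max_size=12))
        p = data.draw(st.text(bases, min_size=4, max_size=12))
        max_bulge = data.draw(st.integers(0, 3))
        expected = oracle_best_duplex_score(b, p, max_bulge)
        try:
            d = hybridize_strands(RNAStrand("b", b), RNAStrand("p", p),
                                  max_bulge=max_bulge)
        except NoDuplexError:
            assert expected < 4
            return
        assert d.score == expected
        # structural sanity: at most one bulge, pairs non-crossing
        assert len(d.bulges) <= 1
        ii = [i for i, _ in d.pairs]
        jj = [j for _, j in d.pairs]
        assert ii == sorted(ii) and jj == sorted(jj, reverse=True)


class TestScanAndAnnotate:
    def test_fret_duplex_single_kturn(self, fret_kturn):
        ann = fret_kturn
        assert ann.bulge_sequence == "GAU"
        assert ann.pair(1) == ("G", "A")
        assert ann.pair(2) == ("A", "G")
        assert ann.pair(-1) == ("C", "A")
        assert ann.pair(3) == ("A", "U")
        assert ann.c_helix_length == 12
        assert ann.nc_helix_length == 13
        assert ann.loop_polarity == "duplex"

    def test_helix_conservation(self, fret_duplex, fret_kturn):
        """C + NC pairing covers the whole partner strand; adding the
        bulge gives the bulged strand length (12 + 13 = 25; + 3 = 28)."""
        ann = fret_kturn
        total = ann.c_helix_length + ann.nc_helix_length
        assert total == len(fret_duplex.partner_strand) == 25
        assert total + len(ann.bulge_sequence) == len(fret_duplex.bulged_strand)

    def test_perfect_duplex_has_no_kturn(self):
        d = hybridize_strands(RNAStrand("a", "GGGAAACCC"),
                              RNAStrand("b", "GGGUUUCCC"), max_bulge=0)
        assert scan_kturns(d) == []

    def test_twofold_symmetric_two_core_duplex(self):
        """A duplex built from two copies of the k-turn core (the
        crystallization-style twofold design) yields two annotations
        with identical relative base content."""
        from kturn.synth import gen_two_core_duplex

        d = gen_two_core_duplex()
        sites = scan_kturns(d)
        assert len(sites) == 2
        for num in (-1, 1, 2, 3):
            assert sites[0].pair(num) == sites[1].pair(num)
        assert sites[0].bulge_sequence == sites[1].bulge_sequence == "GAU"

    def test_mirror_strand_swap_finds_same_sites(self, fret_duplex):
        """Scanning is symmetric in strand labelling: rebuilding the
        model with strands exchanged finds the same number of sites."""
        from kturn.annotate import DuplexModel

        mirror = DuplexModel(
            bulged_strand=fret_duplex.partner_strand,
            partner_strand=fret_duplex.bulged_strand,
            pairs=sorted((j, i) for i, j in fret_duplex.pairs),
            bulges=[],
        )
        assert len(scan_kturns(mirror)) == len(scan_kturns(fret_duplex)) == 1

    def test_round_trip_reads_back_sequences(self, fret_duplex, fret_kturn):
        """Reading every labelled position back off the strands
        reproduces the original sequences exactly."""
        got_b = {}
        got_n = {}
        for pos in fret_kturn.positions.values():
            store = got_b if pos.strand_id == "flu" else got_n
            store[pos.index] = pos.base
        b = fret_duplex.bulged_strand.sequence
        n = fret_duplex.partner_strand.sequence
        assert "".join(got_b[i] for i in sorted(got_b)) == b
        assert "".join(got_n[i] for i in sorted(got_n)) == n

    def test_annotation_deterministic_idempotent(self, fret_duplex):
        a1 = scan_kturns(fret_duplex)[0]
        a2 = scan_kturns(fret_duplex)[0]
        assert a1.positions == a2.positions
        a3 = annotate_positions((fret_duplex, a1.bulge))
        assert a3.positions == a1.positions

    def test_unclosed_bulge_rejected(self):
        strand = RNAStrand("s", "GGGAAAGAAGCUUCUUUCCC")
        model = fold_hairpin(strand)
        with pytest.raises(AnnotationError):
            annotate_positions((model, Bulge("hairpin", 0, 2)))


class TestHairpin:
    def test_terminal_loop_minimum(self):
        with pytest.raises(ValueError):
            HairpinModel(RNAStrand("s", "GGGCCC"), pairs=[], terminal_loop=(3, 4))

    def test_toy_utr_folds_to_truth(self):
        from kturn.synth import gen_toy_utr

        u = gen_toy_utr(seed=11)
        hp = fold_hairpin(u.strand)
        assert sorted(hp.pairs) == sorted(u.model.pairs)
        sites = scan_kturns(hp)
        assert len(sites) == 1
        assert sites[0].pair(-1) == ("C", "A")
        assert sites[0].loop_polarity == "NC-side"


class TestSDOverlap:
    def test_sd_in_stem_is_occluded(self):
        from kturn.synth import gen_toy_utr

        u = gen_toy_utr(sd_placement="in_stem", seed=5)
        ann = scan_kturns(fold_hairpin(u.strand))[0]
        rep = sd_overlap(u.strand, ann, u.sd_interval)
        assert rep.occluded_in_stem
        assert rep.overlapping_labels == {"-3n", "-4n", "-5n", "-6n", "-7n", "-8n"}

    def test_sd_downstream_not_occluded(self):
        from kturn.synth import gen_toy_utr

        u = gen_toy_utr(sd_placement="downstream", seed=5)
        ann = scan_kturns(fold_hairpin(u.strand))[0]
        rep = sd_overlap(u.strand, ann, u.sd_interval)
        assert not rep.occluded_in_stem
        assert rep.overlapping_labels == set()

    def test_sd_straddling_stem_boundary(self):
        """An SD window overhanging the stem 3' end by 2 nt reports
        exactly the 2 in-stem labelled positions."""
        from kturn.synth import gen_toy_utr

        u = gen_toy_utr(sd_placement="downstream", seed=5)
        ann = scan_kturns(fold_hairpin(u.strand))[0]
        stem_end = max(j for _, j in u.model.pairs) + 1
        rep = sd_overlap(u.strand, ann, (stem_end - 2, stem_end + 2))
        in_stem = {lab for lab, p in ann.positions.items()
                   if stem_end - 2 <= p.index < stem_end}
        assert rep.occluded_in_stem
        assert rep.overlapping_labels == in_stem
        assert len(in_stem) == 2

    def test_out_of_range_interval(self, fret_kturn, fret_strands):
        with pytest.raises(IndexError):
            sd_overlap(fret_strands[0], fret_kturn, (20, 40))

    def test_consensus_scan_finds_planted_sd(self):
        s = RNAStrand("u", "CCCCUUAGGAGGUUACCCC")
        assert scan_sd_consensus(s) == (6, 12)


class TestReports:
    def test_dot_bracket_and_table(self, fret_duplex, fret_kturn):
        db = dot_bracket(fret_duplex)
        b_part, n_part = db.split("&")
        assert b_part.count("(") == 25 and b_part[12:15] == "..."
        assert n_part.count(")") == 25
        table = annotation_table(fret_kturn)
        assert "L1\tflu\t12\t13\tG" in table
        assert "1b\tflu\t15\t16\tG" in table
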