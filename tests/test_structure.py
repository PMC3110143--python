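"""Folding, hairpin extraction and component segmentation."""

import hashlib

import numpy as np
import pytest

from mirsweep.structure import (
    InputError,
    NucleotideSequence,
    PlacementError,
    SecondaryStructure,
    derive_premirna,
    extract_hairpins,
    fold,
    get_backend,
    normalize_residues,
    pair_table,
    parse_ct,
    reverse_complement,
    segment_components,
)

from conftest import perfect_hairpin, random_folded_hairpins
from oracles import brute_stem_chains, nussinov_max_pairs, valid_nested_pairing


class TestNormalization:
    def test_t_maps_to_u_and_uppercase(self):
        assert normalize_residues("acgt") == "ACGU"

    def test_bad_residue_rejected(self):
        with pytest.raises(InputError):
            normalize_residues("ACGN")

    def test_offset_negative_rejected(self):
        with pytest.raises(InputError):
            NucleotideSequence(id="x", residues="ACGU", offset=-1)


class TestFold:
    def test_perfect_gc_stem_is_maximally_paired(self, backend):
        seq = NucleotideSequence.from_raw("toy", "GGGGGAAAAACCCCC")
        st = fold(seq, backend, min_length=0)
        assert valid_nested_pairing(seq.residues, st.pairs)
        assert st.n_pairs() == nussinov_max_pairs(seq.residues) == 5
        assert st.mfe < 0

    def test_homopolymer_has_no_structure(self, backend):
        seq = NucleotideSequence.from_raw("homo", "A" * 50)
        st = fold(seq, backend, min_length=0)
        assert st.n_pairs() == 0
        assert st.mfe == 0.0
        assert extract_hairpins(st, seq) == []

    def test_reversed_palindromic_stem_gives_mirror_structure(self, backend):
        residues = "GGGGGAAAAACCCCC"
        seq = NucleotideSequence.from_raw("pal", residues)
        rev = NucleotideSequence.from_raw("rev", residues[::-1])
        db = fold(seq, backend, min_length=0).dotbracket
        db_rev = fold(rev, backend, min_length=0).dotbracket
        mirror = db[::-1].translate(str.maketrans("()", ")("))
        assert db_rev == mirror

    def test_min_length_guard(self, backend):
        seq = NucleotideSequence.from_raw("short", "ACGUACGU")
        with pytest.raises(InputError):
            fold(seq, backend)  # default minimum 40 nt

    def test_unknown_backend_is_configuration_error(self):
        from mirsweep.structure import ConfigurationError

        with pytest.raises(ConfigurationError):
            get_backend("mfold-classic")

    def test_folding_determinism_hash(self, backend):
        rng = np.random.default_rng(3)
        residues = "".join(rng.choice(list("ACGU"), size=80))
        seq = NucleotideSequence(id="d", residues=residues)
        h = [
            hashlib.sha256(fold(seq, backend, min_length=0).dotbracket.encode()).hexdigest()
            for _ in range(3)
        ]
        assert len(set(h)) == 1

    def test_inprocess_and_subprocess_backends_agree(self, backend):
        cli = get_backend("rnafold-cli")
        rng = np.random.default_rng(5)
        for _ in range(3):
            residues = "".join(rng.choice(list("ACGU"), size=70))
            seq = NucleotideSequence(id="x", residues=residues)
            assert fold(seq, backend, min_length=0).dotbracket == \
                fold(seq, cli, min_length=0).dotbracket


class TestPairTable:
    def test_involution_and_no_pseudoknots_on_random_folds(self, backend):
        rng = np.random.default_rng(11)
        for _ in range(150):
            residues = "".join(rng.choice(list("ACGU"), size=int(rng.integers(40, 120))))
            st = fold(NucleotideSequence(id="r", residues=residues), backend, min_length=0)
            assert valid_nested_pairing(residues, st.pairs)
            assert len(st.dotbracket) == len(residues)

    def test_unbalanced_dotbracket_rejected(self):
        with pytest.raises(InputError):
            pair_table("((..)")


class TestParseCT:
    CT = """15 dG = -8.6 toy
1 G 0 2 15 1
2 G 1 3 14 2
3 G 2 4 13 3
4 G 3 5 12 4
5 G 4 6 11 5
6 A 5 7 0 6
7 A 6 8 0 7
8 A 7 9 0 8
9 A 8 10 0 9
10 A 9 11 0 10
11 C 10 12 5 11
12 C 11 13 4 12
13 C 12 14 3 13
14 C 13 15 2 14
15 C 14 0 1 15
"""

    def test_ct_roundtrip(self):
        residues, table, energy = parse_ct(self.CT)
        assert residues == "GGGGGAAAAACCCCC"
        assert table[0] == 14 and table[14] == 0 and table[5] is None
        assert energy == -8.6


class TestExtractHairpins:
    def test_perfect_stem_loop_spans_whole_molecule(self):
        seq, st, h = perfect_hairpin("GCGAUGCAUGCGAUGCGAUC")  # 20 bp
        assert h.span == (0, len(seq.residues))
        assert h.n_stem_pairs == 20
        assert h.trimmed == 0
        assert h.arm5[1] == h.loop[0] and h.loop[1] == h.arm3[0]

    def test_70bp_stem_trimmed_to_60_pair_levels(self):
        rng = np.random.default_rng(0)
        stem = "".join(rng.choice(list("GC"), size=70))
        seq, st, h = perfect_hairpin(stem)
        assert h.n_stem_pairs == 60
        assert h.trimmed == 10
        # trimmed region excluded from the span
        assert h.span == (h.outer_pair[0], h.outer_pair[1] + 1)
        assert h.span[0] == 10

    def test_cloverleaf_yields_three_hairpins_matching_oracle(self):
        db = ".((..((((....))))..(((....)))...((((....))))..)).."
        st = SecondaryStructure.from_dotbracket(db)
        hps = extract_hairpins(st)
        assert len(hps) == 3
        oracle_chains = brute_stem_chains(st.pairs)
        got = sorted(h.stem_pairs[-1] for h in hps)
        want = sorted(tuple(ch[-1]) for ch in oracle_chains)
        assert got == [tuple(w) for w in want]
        # per-hairpin stem chains agree with the oracle decomposition
        by_inner = {tuple(ch[-1]): [tuple(p) for p in ch] for ch in oracle_chains}
        for h in hps:
            assert list(h.stem_pairs) == by_inner[h.inner_pair]

    def test_flank_split_between_sibling_hairpins_tiles_without_overlap(self):
        db = "..((((....))))......((((....)))).."
        hps = extract_hairpins(SecondaryStructure.from_dotbracket(db))
        assert len(hps) == 2
        spans = sorted(h.span for h in hps)
        assert spans[0][1] == spans[1][0]  # shared run split, no overlap
        assert spans[0][0] == 0 and spans[1][1] == len(db)

    def test_stem_cap_property_random(self, backend):
        rng = np.random.default_rng(21)
        for _, _, h in random_folded_hairpins(rng, 25, backend):
            assert h.n_stem_pairs <= 60


class TestSegmentComponents:
    def stem30(self):
        rng = np.random.default_rng(1)
        stem = "".join(rng.choice(list("GC"), size=30))
        return perfect_hairpin(stem, loop_len=4)

    def test_pairwalk_example_30bp_stem(self):
        # mature over pair levels 5..26 of a 30-bp stem (0-based [4, 26))
        seq, st, h = self.stem30()
        comps = segment_components(h, (4, 26))
        assert comps.lower_stem[0] == (0, 4)
        assert comps.upper_stem[0] == (4, 26)
        assert comps.top_stem[0] == (26, 30)
        # 3' side mirrors through the pair table
        assert comps.upper_stem[1] == (st.pairs[25], st.pairs[4] + 1)
        assert comps.top_stem[1] == (h.loop[1], st.pairs[25])

    def test_mature_flush_to_loop_has_empty_top_stem(self):
        seq, st, h = self.stem30()
        comps = segment_components(h, (8, 30))
        assert comps.top_stem[0][0] == comps.top_stem[0][1]
        assert comps.top_stem[1][0] == comps.top_stem[1][1]

    def test_mature_covering_whole_arm_leaves_only_upper_stem_and_loop(self):
        seq, st, h = self.stem30()
        comps = segment_components(h, (0, 30))
        for iv5, iv3 in (comps.basal_segment, comps.lower_stem, comps.top_stem):
            assert iv5[0] == iv5[1] and iv3[0] == iv3[1]
        assert comps.upper_stem[0] == (0, 30)

    def test_placement_in_loop_rejected(self):
        seq, st, h = self.stem30()
        with pytest.raises(PlacementError):
            segment_components(h, (h.loop[0], h.loop[1]))

    def test_tiling_property_random_hairpins_and_placements(self, backend):
        rng = np.random.default_rng(33)
        checked = 0
        for seq, st, h in random_folded_hairpins(rng, 40, backend):
            l0, l1 = h.loop
            for arm_iv in (h.arm5, h.arm3):
                lo, hi = arm_iv
                if hi - lo < 8:
                    continue
                s = int(rng.integers(lo, hi - 5))
                e = int(rng.integers(s + 4, hi + 1))
                try:
                    comps = segment_components(h, (s, e))
                except PlacementError:
                    continue
                ivs = sorted(iv for iv in comps.all_intervals() if iv[1] > iv[0])
                # pairwise disjoint and union equals the span
                for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                    assert b1 <= a2
                covered = sum(b - a for a, b in ivs)
                assert covered == h.span[1] - h.span[0]
                assert ivs[0][0] == h.span[0] and ivs[-1][1] == h.span[1]
                checked += 1
        assert checked > 30


class TestDerivePremirna:
    def test_symmetric_whole_arm_gives_whole_hairpin(self):
        seq, st, h = perfect_hairpin("GCGCAUGCGCAUGCGCAUGC", loop_len=4)
        pre = derive_premirna(h, (0, 20))
        assert pre == h.span  # clip-limited: no room for the overhang

    def test_zero_overhang_ends_at_partner(self):
        seq, st, h = perfect_hairpin("GCGCAUGCGCAUGCGCAUGC", loop_len=4)
        pre = derive_premirna(h, (2, 18), overhang=0)
        assert pre == (2, st.pairs[2] + 1)

    def test_bulged_3prime_arm_shifts_the_end(self):
        # hand-built: 8-bp stem with a 3-nt bulge on the 3' arm
        db = "((((((((....))))...)))))"  # invalid lengths; build explicitly below
        db = "((((((((....))))...))))"
        # 8 opens, 4 loop, 4 closes, 3 bulge, 4 closes -> 23 chars
        st = SecondaryStructure.from_dotbracket(db)
        seq = NucleotideSequence(id="b", residues="GGGGGGGGAAAACCCCAAACCCC")
        (h,) = extract_hairpins(st, seq)
        pre = derive_premirna(h, (1, 8), overhang=2)
        # partner of position 1 is the last ')'; walked by hand: index 21
        assert st.pairs[1] == 21
        assert pre == (1, 23)  # 21+1+2 clipped to span end 23

    def test_5p_and_3p_agree_through_the_pair_table(self, backend):
        rng = np.random.default_rng(44)
        for seq, st, h in random_folded_hairpins(rng, 15, backend):
            l0, l1 = h.loop
            if h.arm3[1] - h.arm3[0] < 10:
                continue
            s = int(rng.integers(l1, h.arm3[1] - 8))
            e = s + 8
            try:
                pre = derive_premirna(h, (s, e))
            except Exception:
                continue
            assert h.span[0] <= pre[0] < pre[1] <= h.span[1]
            assert pre[0] < l0 and pre[1] > l1  # spans across the loop
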