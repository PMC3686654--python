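"""REP extraction: flanks, inverted pairs, stem-loop parsing, consensus merge."""

import numpy as np
import pytest

from oracles import enumerate_structure
from repatlas.rep_discovery import (
    NotARepError,
    RepStructure,
    classify_architecture,
    extract_flanks,
    find_inverted_pair,
    find_rep_structure,
    merge_to_consensus,
    trim_to_rep_unit,
)
from repatlas.seq_core import GenomeRecord, reverse_complement

SM1 = "GGTGGGTGCCGACCGTTGGTCGGCAC"
SM3 = "GTAGWTGCCAACCTTGGTTGGCA"
PF1 = "GTGGGAGGGGGCTTGCCCCCGAT"


class TestStructureFinder:
    @pytest.mark.parametrize(
        "seq,lead,off,stem,loop",
        [
            (SM1, 1, 0, 9, 3),
            (SM3, 0, 1, 8, 2),
            (PF1, 0, 2, 6, 2),  # frozen from the exhaustive oracle
        ],
    )
    def test_frozen_parses(self, seq, lead, off, stem, loop):
        s = find_rep_structure(seq)
        assert (s.lead_offset, s.arm_offset, s.stem_len, s.loop_len) == (
            lead, off, stem, loop,
        )

    def test_no_tetranucleotide(self):
        with pytest.raises(NotARepError, match="tetranucleotide"):
            find_rep_structure("CCCCCCCCCCCCCCCCCC")

    def test_no_stem(self):
        with pytest.raises(NotARepError, match="stem"):
            find_rep_structure("GTAGAAAAAAAAAAAAAAAA")

    def test_matches_oracle_on_catalog(self, catalog):
        for entry in catalog:
            seq = entry.consensus.iupac
            expected = enumerate_structure(seq)
            if expected is None:
                with pytest.raises(NotARepError):
                    find_rep_structure(seq)
                continue
            s = find_rep_structure(seq)
            assert (s.lead_offset, s.arm_offset, s.stem_len, s.loop_len) == expected, entry.label

    def test_matches_oracle_on_random_strings(self, rng):
        """500 random strings, half seeded with a tetranucleotide prefix so
        the interesting branch is exercised."""
        for k in range(500):
            n = int(rng.integers(15, 31))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            if k % 2:
                tetra = "GTAG" if rng.integers(2) else "GTGG"
                seq = tetra + seq[4:]
            expected = enumerate_structure(seq)
            if expected is None:
                with pytest.raises(NotARepError):
                    find_rep_structure(seq)
            else:
                s = find_rep_structure(seq)
                assert (s.lead_offset, s.arm_offset, s.stem_len, s.loop_len) == expected, seq


class TestArchitecture:
    def test_sm1_is_sm_like(self):
        assert classify_architecture(find_rep_structure(SM1)) == "SM-like"

    def test_pf1_is_pf_like(self):
        assert classify_architecture(find_rep_structure(PF1)) == "PF-like"

    def test_boundary_stem9_offset3_is_other(self):
        s = RepStructure(lead_offset=0, tetranucleotide="GTAG", arm_offset=3,
                         stem_len=9, loop_len=1, total_len=26)
        assert classify_architecture(s) == "other"

    def test_all_sm_classes_sm_like(self, catalog):
        stems = []
        for entry in catalog.group("SM"):
            assert entry.consensus.architecture == "SM-like", entry.label
            stems.append(entry.consensus.structure.stem_len)
        assert min(stems) == 8 and max(stems) == 9


class TestFlanks:
    def _genome(self):
        rng = np.random.default_rng(0)
        return GenomeRecord(id="g", sequence="".join(rng.choice(list("ACGT"), size=3000)))

    def test_windows(self):
        g = self._genome()
        up, down = extract_flanks(g, 1000, 2000, window=500)
        assert up == g.sequence[500:1000]
        assert down == g.sequence[2000:2500]

    def test_clipping_at_contig_edge(self):
        g = self._genome()
        up, _ = extract_flanks(g, 100, 200, window=500)
        assert up == g.sequence[0:100]

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            extract_flanks(self._genome(), 100, 200, window=0)


class TestInvertedPair:
    def _flanks_with(self, rep, rng, flank_len=300):
        up = "".join(rng.choice(list("ACGT"), size=flank_len))
        down = "".join(rng.choice(list("ACGT"), size=flank_len))
        up = up[:50] + rep + up[50 + len(rep):]
        rc = reverse_complement(rep)
        down = down[:200] + rc + down[200 + len(rc):]
        return up, down

    def test_planted_pair_found(self, rng):
        rep = "GTAGGAGCCGGCTTGCTGGCGAT"  # 23-mer
        up, down = self._flanks_with(rep, rng)
        pairs = find_inverted_pair(up, down)
        (u, d), *_ = pairs
        assert up[u[0]:u[1]].find(rep) != -1 or rep in up[u[0]:u[1]]
        assert reverse_complement(rep) in down[d[0]:d[1]]

    def test_no_shared_kmers_empty(self):
        assert find_inverted_pair("A" * 100, "A" * 100) == []
        # revcomp of poly-A is poly-T, shares no 12-mer with poly-A upstream

    def test_sm1_pair_recovered_exactly(self, rng):
        genome_up = "".join(rng.choice(list("ACGT"), size=200)) + SM1 + "C"
        genome_down = "G" + reverse_complement(SM1) + "".join(rng.choice(list("ACGT"), size=200))
        pairs = find_inverted_pair(genome_up, genome_down)
        assert pairs
        (u0, u1), (d0, d1) = pairs[0]
        assert SM1 in genome_up[u0:u1]
        assert reverse_complement(SM1) in genome_down[d0:d1]

    def test_seed_len_floor(self):
        with pytest.raises(ValueError):
            find_inverted_pair("ACGT" * 10, "ACGT" * 10, seed_len=4)


class TestTrim:
    def test_catalog_round_trip(self, catalog):
        """Trimming a full consensus is the identity for every parseable
        class whose right flank after the stem is within the 4-nt cap
        (PF9/PF19 carry longer flanks behind degenerate short-stem parses)."""
        for entry in catalog:
            if entry.consensus.structure is None:
                continue
            trimmed = trim_to_rep_unit(entry.consensus.iupac)
            if entry.label in ("PF9", "PF19"):
                assert entry.consensus.iupac.startswith(trimmed)
            else:
                assert trimmed == entry.consensus.iupac, entry.label

    def test_orientation_flip(self):
        assert trim_to_rep_unit(reverse_complement(SM1)) == SM1


class TestMergeConsensus:
    def test_pf10_variant_pair(self):
        merged = merge_to_consensus(
            ["GTGGGAGCGAGCTTGCTCGCGAA", "GTGGGAGCGAGCCTGCTCGCGAA"]
        )
        assert merged == "GTGGGAGCGAGCYTGCTCGCGAA"

    def test_single_variant_identity(self):
        assert merge_to_consensus(["GTAGATT" * 3]) == "GTAGATT" * 3

    def test_distance_budget(self):
        with pytest.raises(ValueError, match="> 3"):
            merge_to_consensus(["AAAA", "TTTT"])

    def test_unequal_lengths(self):
        with pytest.raises(ValueError, match="length"):
            merge_to_consensus(["ACGT", "ACG"])

    def test_degeneracy_budget(self):
        # pairwise distances all <= 3, but the union spans 5 positions
        base = "GTAG" + "A" * 16
        variants = [base]
        for extra in (6, 7, 8):
            v = list(base)
            v[4] = v[5] = v[extra] = "C"
            variants.append("".join(v))
        with pytest.raises(ValueError, match="degenerate"):
            merge_to_consensus(variants)

    def test_order_invariance(self, rng):
        variants = ["GTGGGAGCGAGCTTGCTCGCGAA", "GTGGGAGCGAGCCTGCTCGCGAA",
                    "GTGGGAGCGAGCTTGCTCGCGAT"]
        reference = merge_to_consensus(variants)
        for _ in range(5):
            perm = [variants[i] for i in rng.permutation(3)]
            assert merge_to_consensus(perm) == reference
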