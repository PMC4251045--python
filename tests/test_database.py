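"""Digestion, linkable-site marking, candidate filters and the pair database."""

import random

import pytest

from xlpm.chem import DSS, SDA, EndSpecificity, LabelingState, N_TERMINUS
from xlpm.database import (
    MIXED_LABELS,
    SINGLE_LABEL,
    TRYPSIN,
    ProteinRecord,
    annotate_sites,
    build_decoy,
    build_pair_database,
    digest,
    filter_candidates,
    find_linkable_sites,
    read_fasta,
)
from tests.conftest import brute_force_digest, make_peptide, random_protein


class TestDigest:
    def test_tryptic_example_with_missed_cleavage(self):
        peps = digest(ProteinRecord("p", "MAKDDGSKR"), TRYPSIN, max_missed=1)
        assert {p.sequence for p in peps} == {"MAK", "DDGSK", "R", "MAKDDGSK", "DDGSKR"}
        by_seq = {p.sequence: p for p in peps}
        assert (by_seq["DDGSK"].start, by_seq["DDGSK"].end) == (4, 8)
        assert by_seq["MAKDDGSK"].missed_cleavages == 1

    def test_protein_without_cleavage_sites(self):
        peps = digest(ProteinRecord("p", "GGAVGG"), TRYPSIN, max_missed=0)
        assert [(p.sequence, p.missed_cleavages) for p in peps] == [("GGAVGG", 0)]

    def test_proline_suppresses_tryptic_cleavage(self):
        peps = digest(ProteinRecord("p", "AKPG"), TRYPSIN, max_missed=0)
        assert {p.sequence for p in peps} == {"AKPG"}

    def test_coordinates_slice_the_protein(self):
        prot = ProteinRecord("p", "MAKDDGSKRLLK")
        for p in digest(prot, TRYPSIN, max_missed=2):
            assert prot.sequence[p.start - 1 : p.end] == p.sequence

    def test_matches_brute_force_enumeration(self):
        """Exhaustiveness on random proteins against an independent
        cleavage-window enumerator."""
        rng = random.Random(42)
        for _ in range(200):
            seq = random_protein(rng, 5, 60)
            max_missed = rng.randint(0, 3)
            got = {
                (p.sequence, p.start, p.end, p.missed_cleavages)
                for p in digest(ProteinRecord("p", seq), TRYPSIN, max_missed)
            }
            assert got == brute_force_digest(seq, TRYPSIN, max_missed)

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            ProteinRecord("p", "")


class TestLinkableSites:
    def test_internal_peptide_lysines(self):
        pep = make_peptide("DDGSKGTTLSLVQK", start=82)
        assert find_linkable_sites(pep, DSS.end1) == (5, 14)

    def test_protein_start_peptide_gains_alpha_amine(self):
        pep = make_peptide("MDFSK", start=1)
        assert find_linkable_sites(pep, DSS.end1) == (N_TERMINUS, 5)

    def test_wildcard_end_marks_every_residue(self):
        pep = make_peptide("GAVL")
        assert find_linkable_sites(pep, SDA.end2) == (1, 2, 3, 4)

    def test_internal_peptide_has_no_alpha_amine_site(self):
        pep = make_peptide("GAVL", start=7)
        assert find_linkable_sites(pep, DSS.end1) == ()


class TestFilters:
    def _annotated(self, sequences_with_starts, linker=DSS):
        peps = [make_peptide(s, start) for s, start in sequences_with_starts]
        return annotate_sites(peps, linker)

    def test_three_rules_on_the_tryptic_example(self):
        peps = self._annotated(
            [("MAK", 1), ("DDGSK", 4), ("R", 9), ("MAKDDGSK", 1), ("DDGSKR", 4)]
        )
        kept = {p.sequence for p in filter_candidates(peps, DSS)}
        # R: too short; DDGSK: sole link site is the C-terminal cleavage
        # residue (forced missed cleavage)
        assert kept == {"MAK", "MAKDDGSK", "DDGSKR"}

    def test_peptide_without_linkable_residue_removed(self):
        peps = self._annotated([("GAVLD", 10)])
        assert filter_candidates(peps, DSS) == []

    def test_nonspecific_linker_keeps_all_long_enough(self):
        peps = self._annotated([("GAVLD", 10), ("GA", 30)], linker=SDA)
        kept = filter_candidates(peps, SDA)
        assert [p.sequence for p in kept] == ["GAVLD"]

    def test_idempotence(self):
        peps = self._annotated(
            [("MAK", 1), ("DDGSK", 4), ("R", 9), ("MAKDDGSK", 1), ("DDGSKR", 4)]
        )
        once = filter_candidates(peps, DSS)
        assert filter_candidates(once, DSS) == once


class TestPairDatabase:
    def test_three_peptides_give_six_pairs(self):
        peps = [make_peptide(s, st) for s, st in
                [("MAK", 1), ("MAKDDGSK", 1), ("DDGSKR", 4)]]
        pairs = build_pair_database(peps, DSS)
        assert len(pairs) == 6  # 3 * 4 / 2, self-pairs included

    def test_pair_mass_matches_observed_precursor(self):
        """The DSS pair of two tryptic peptides lands within 1 ppm of the
        observed 5+ precursor neutral mass 3599.837891 Da."""
        peps = [make_peptide("KGALVYVEADAANYVFER", 64),
                make_peptide("DDGSKGTTLSLVQK", 82)]
        pairs = build_pair_database(peps, DSS)
        target = [p for p in pairs
                  if {p.peptide_a.sequence, p.peptide_b.sequence}
                  == {"KGALVYVEADAANYVFER", "DDGSKGTTLSLVQK"}]
        assert len(target) == 1
        ppm = abs(target[0].mass - 3599.837891) / 3599.837891 * 1e6
        assert ppm < 3.0

    def test_order_invariance(self):
        peps = [make_peptide(s, st) for s, st in
                [("MAK", 1), ("MAKDDGSK", 1), ("DDGSKR", 4), ("KLEDAK", 10)]]
        keys = lambda pairs: sorted(p.key() for p in pairs)
        assert keys(build_pair_database(peps, DSS)) == keys(
            build_pair_database(list(reversed(peps)), DSS)
        )

    def test_labeling_modes_expand_mass_variants(self):
        peps = [make_peptide("MAKGG", 1), make_peptide("DDGSKR", 10)]
        single = build_pair_database(peps, DSS, labeling_modes=SINGLE_LABEL)
        mixed = build_pair_database(peps, DSS, labeling_modes=MIXED_LABELS)
        hetero = [p for p in mixed
                  if {p.peptide_a.sequence, p.peptide_b.sequence}
                  == {"MAKGG", "DDGSKR"}]
        assert len(hetero) == 4  # {14,15} x {14,15}
        masses = sorted(p.mass for p in hetero)
        assert len(set(round(m, 4) for m in masses)) == 4
        # self-pairs: (14,15) and (15,14) collapse to one record
        self_pairs = [p for p in mixed
                      if p.peptide_a.sequence == p.peptide_b.sequence == "MAKGG"]
        assert len(self_pairs) == 3

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            assert build_pair_database([], DSS) == []


class TestDecoy:
    def test_reversal_and_flag(self):
        decoy = build_decoy(ProteinRecord("p1", "MAKR"))
        assert decoy.sequence == "RKAM"
        assert decoy.decoy and decoy.identifier == "decoy_p1"

    def test_palindrome_keeps_sequence(self):
        decoy = build_decoy(ProteinRecord("p", "GAKAG"))
        assert decoy.sequence == "GAKAG" and decoy.decoy

    def test_involution(self):
        prot = ProteinRecord("p", "MDFSKLEDAK")
        assert build_decoy(build_decoy(prot)).sequence == prot.sequence

    def test_decoy_peptides_flagged_through_digestion(self):
        decoy = build_decoy(ProteinRecord("p", "MAKDDGSKR"))
        assert all(p.decoy for p in digest(decoy, TRYPSIN, 1))


class TestFasta:
    def test_round_trip(self, toy_fasta, toy_proteins):
        records = read_fasta(str(toy_fasta))
        assert [(r.identifier, r.sequence) for r in records] == [
            (p.identifier, p.sequence) for p in toy_proteins
        ]
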