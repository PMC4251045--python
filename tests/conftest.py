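"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from xlpm.chem import WATER, RESIDUE_MASS
from xlpm.database import DigestedPeptide, EnzymeRule, ProteinRecord, TRYPSIN

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue nitrogen counts frozen from the standard molecular formulas,
#: independent of the composition tables the implementation consults.
NITROGEN_BY_RESIDUE = {
    "G": 1, "A": 1, "S": 1, "P": 1, "V": 1, "T": 1, "C": 1, "L": 1, "I": 1,
    "N": 2, "D": 1, "Q": 2, "K": 2, "E": 1, "M": 1, "H": 3, "F": 1, "R": 4,
    "Y": 1, "W": 2,
}


def brute_force_digest(sequence: str, rule: EnzymeRule, max_missed: int):
    """Independent digest oracle: enumerate all (start, end) windows and keep
    those bounded by cleavage points with at most max_missed internal ones."""
    points = set(rule.cleavage_points(sequence))
    boundaries = sorted({0, len(sequence)} | points)
    out = set()
    for a in boundaries:
        for b in boundaries:
            if b <= a:
                continue
            internal = [p for p in points if a < p < b]
            if len(internal) <= max_missed:
                out.add((sequence[a:b], a + 1, b, len(internal)))
    return out


def brute_force_fragment_counts(spectrum, b_ladder, y_ladder, z_p, tol):
    """Independent O(n * z * peaks) matcher for the b->complementary-y filter
    on one chain (exhaustive linear scans, no sorted-peak shortcuts)."""
    from xlpm.chem import HYDROGEN_ATOM

    peaks = list(spectrum.mz)
    n_frag = len(b_ladder)
    nmb = nmy = 0
    for i in range(n_frag):
        b_hit = y_hit = False
        for z_b in range(1, z_p):
            b_mz = (b_ladder[i] + z_b * HYDROGEN_ATOM) / z_b
            if any(abs(p - b_mz) <= tol for p in peaks):
                b_hit = True
                z_y = z_p - z_b
                y_mz = (y_ladder[n_frag - 1 - i] + z_y * HYDROGEN_ATOM) / z_y
                if any(abs(p - y_mz) <= tol for p in peaks):
                    y_hit = True
        nmb += b_hit
        nmy += y_hit
    return nmb, nmy


def mann_whitney_auc(scores, labels):
    """AUC oracle: P(score_pos > score_neg) + 0.5 P(tie) by exhaustive pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_protein(rng: random.Random, n_min=10, n_max=60) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(n_min, n_max)))


@pytest.fixture
def toy_proteins():
    """Two small proteins rich in lysines, enough for a varied pair database."""
    return [
        ProteinRecord("protA", "MDFSKLEDAKGTTLSKVQRYLKYSIASQPR"),
        ProteinRecord("protB", "MAKWDDGSKGTRVEANKFLHKSR"),
    ]


@pytest.fixture
def toy_fasta(tmp_path, toy_proteins):
    path = tmp_path / "toy.fasta"
    with open(path, "w") as fh:
        for p in toy_proteins:
            fh.write(f">{p.identifier}\n{p.sequence}\n")
    return path


def make_peptide(sequence: str, start: int = 1, protein: str = "P") -> DigestedPeptide:
    return DigestedPeptide(
        sequence=sequence, protein_id=protein, start=start,
        end=start + len(sequence) - 1, missed_cleavages=0,
    )
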