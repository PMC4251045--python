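"""In-silico digestion and the cross-linked candidate-pair database.

The search space is the set of unordered pairs of digested peptides, each
carrying at least one residue compatible with one end of the cross-linker.
Three filters prune the peptide list before pairing:

* peptides shorter than 3 residues are dropped;
* peptides without any linkable residue for either end are dropped;
* peptides whose *only* linkable residue is their C-terminal cleavage-site
  residue are dropped ("forced missed cleavage"): a cross-link on that
  residue would have blocked proteolysis there, so the true cross-linked
  peptide must extend past it and is already present as the missed-cleavage
  form.

Decoy databases reverse each protein sequence and run through the identical
pipeline; targets and decoys are searched separately.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO

from xlpm.chem import (
    AppliedModification,
    CrossLinker,
    EndSpecificity,
    LabelingState,
    Modification,
    N_TERMINUS,
    Site,
    peptide_monoisotopic_mass,
    site_sort_key,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRecord:
    identifier: str
    sequence: str
    decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.identifier!r} has an empty sequence")


@dataclass(frozen=True)
class EnzymeRule:
    """A proteolytic cleavage rule.

    ``side`` is ``"C"`` when the bond C-terminal to a cleavage residue is cut
    (trypsin) and ``"N"`` for N-terminal cutters.  ``exceptions`` are residues
    on the far side of the bond that suppress cleavage (P for trypsin).
    """

    name: str
    residues: frozenset[str]
    side: str = "C"
    exceptions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("enzyme cleavage residue set must be non-empty")
        if self.side not in ("C", "N"):
            raise ValueError(f"cleavage side must be 'C' or 'N', got {self.side!r}")

    def cleavage_points(self, sequence: str) -> list[int]:
        """0-based indices i such that the bond between sequence[i-1] and
        sequence[i] is cleaved (i.e. a fragment may start at i)."""
        points = []
        for i in range(1, len(sequence)):
            if self.side == "C":
                if sequence[i - 1] in self.residues and sequence[i] not in self.exceptions:
                    points.append(i)
            else:
                if sequence[i] in self.residues and sequence[i - 1] not in self.exceptions:
                    points.append(i)
        return points


TRYPSIN = EnzymeRule(
    name="trypsin", residues=frozenset("KR"), side="C", exceptions=frozenset("P")
)

BUILTIN_ENZYMES: dict[str, EnzymeRule] = {"trypsin": TRYPSIN}


@dataclass(frozen=True)
class DigestedPeptide:
    """A proteolytic fragment with protein coordinates and linkable sites.

    ``start``/``end`` are 1-based inclusive protein coordinates; linkable
    sites are 1-based peptide positions (or the N-terminus token) per
    cross-linker end, filled in by :func:`find_linkable_sites`.
    """

    sequence: str
    protein_id: str
    start: int
    end: int
    missed_cleavages: int
    sites_end1: tuple[Site, ...] = ()
    sites_end2: tuple[Site, ...] = ()
    decoy: bool = False

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def all_sites(self) -> tuple[Site, ...]:
        seen = dict.fromkeys(self.sites_end1)
        seen.update(dict.fromkeys(self.sites_end2))
        return tuple(sorted(seen, key=site_sort_key))

    def site_protein_coordinate(self, site: Site) -> int:
        """Protein position of a peptide link site (N-terminus -> 1)."""
        return 1 if site == N_TERMINUS else self.start + int(site) - 1


@dataclass(frozen=True)
class CandidatePair:
    """Two peptides joined by a cross-linker: the unit of precursor matching.

    ``peptide_a``/``peptide_b`` are in canonical order (sequence, protein,
    start) so that (A, B) and (B, A) collapse to a single record.  The pair's
    neutral mass is mass(A) + mass(B) + bridge delta, including modification
    deltas and per-chain 15N shifts.
    """

    peptide_a: DigestedPeptide
    peptide_b: DigestedPeptide
    linker: CrossLinker
    mods_a: tuple[AppliedModification, ...] = ()
    mods_b: tuple[AppliedModification, ...] = ()
    label_a: LabelingState = LabelingState.N14
    label_b: LabelingState = LabelingState.N14
    mass: float = 0.0

    @property
    def decoy(self) -> bool:
        return self.peptide_a.decoy or self.peptide_b.decoy

    @property
    def label_combo(self) -> str:
        return f"{self.label_a.value}x{self.label_b.value}"

    def key(self) -> tuple:
        return (
            self.peptide_a.sequence, self.peptide_a.protein_id, self.peptide_a.start,
            self.peptide_b.sequence, self.peptide_b.protein_id, self.peptide_b.start,
            tuple((m.mod.name, m.site) for m in self.mods_a),
            tuple((m.mod.name, m.site) for m in self.mods_b),
            self.label_a.value, self.label_b.value,
        )

    def site_combinations(self) -> list[tuple[Site, Site]]:
        """All (site on A, site on B) assignments compatible with the two
        linker ends, in deterministic sorted order."""
        combos = set()
        for sa in self.peptide_a.sites_end1:
            for sb in self.peptide_b.sites_end2:
                combos.add((sa, sb))
        for sa in self.peptide_a.sites_end2:
            for sb in self.peptide_b.sites_end1:
                combos.add((sa, sb))
        return sorted(combos, key=lambda c: (site_sort_key(c[0]), site_sort_key(c[1])))


# -- FASTA --------------------------------------------------------------------


def read_fasta(source: str | Path | TextIO) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into protein records.

    The full description line is preserved as the identifier.
    """
    records = [
        ProteinRecord(identifier=rec.description, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(source, "fasta")
    ]
    seen: set[str] = set()
    for rec in records:
        if rec.identifier in seen:
            raise ValueError(f"duplicate protein identifier {rec.identifier!r}")
        seen.add(rec.identifier)
    return records


# -- digestion ----------------------------------------------------------------


def digest(
    protein: ProteinRecord, rule: EnzymeRule, max_missed: int = 2
) -> list[DigestedPeptide]:
    """Exhaustive in-silico digest with up to ``max_missed`` missed cleavages.

    Every returned peptide is a join of at most ``max_missed + 1`` adjacent
    maximal-cleavage fragments, with correct 1-based protein coordinates.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be non-negative")
    seq = protein.sequence
    boundaries = [0] + rule.cleavage_points(seq) + [len(seq)]
    peptides = []
    n_frag = len(boundaries) - 1
    for i in range(n_frag):
        for j in range(i, min(i + max_missed + 1, n_frag)):
            start, end = boundaries[i], boundaries[j + 1]
            peptides.append(
                DigestedPeptide(
                    sequence=seq[start:end],
                    protein_id=protein.identifier,
                    start=start + 1,
                    end=end,
                    missed_cleavages=j - i,
                    decoy=protein.decoy,
                )
            )
    return peptides


def find_linkable_sites(
    peptide: DigestedPeptide, end: EndSpecificity
) -> tuple[Site, ...]:
    """Peptide positions reactive toward one cross-linker end.

    Residue-specific ends match side chains; amine-reactive ends additionally
    match the protein alpha-amine when the peptide starts at protein position
    1; a wildcard end matches every residue.
    """
    if end.wildcard:
        return tuple(range(1, len(peptide) + 1))
    sites: list[Site] = []
    if end.protein_nterm and peptide.start == 1:
        sites.append(N_TERMINUS)
    sites.extend(
        pos for pos, aa in enumerate(peptide.sequence, start=1) if aa in end.residues
    )
    return tuple(sites)


def annotate_sites(
    peptides: Iterable[DigestedPeptide], linker: CrossLinker
) -> list[DigestedPeptide]:
    """Attach the linkable positions for both linker ends to each peptide."""
    return [
        replace(
            p,
            sites_end1=find_linkable_sites(p, linker.end1),
            sites_end2=find_linkable_sites(p, linker.end2),
        )
        for p in peptides
    ]


def filter_candidates(
    peptides: Iterable[DigestedPeptide],
    linker: CrossLinker,
    enzyme: EnzymeRule = TRYPSIN,
) -> list[DigestedPeptide]:
    """Apply the three candidate filters (see the module docstring)."""
    kept = []
    for p in peptides:
        if len(p) < 3:
            continue
        sites = p.all_sites
        if not sites:
            continue
        cterm = len(p)
        if (
            len(sites) == 1
            and sites[0] == cterm
            and p.sequence[-1] in enzyme.residues
        ):
            # forced missed cleavage: a link on the C-terminal cleavage
            # residue would have blocked digestion there
            continue
        kept.append(p)
    return kept


# -- variable-modification expansion ------------------------------------------


def _mod_states(
    peptide: DigestedPeptide,
    mods: Sequence[Modification],
    max_variable: int,
) -> list[tuple[AppliedModification, ...]]:
    """All modification states of one peptide: every fixed mod applied at all
    its target sites, plus 0..max_variable variable mods over theirs."""
    fixed: list[AppliedModification] = []
    variable_sites: list[AppliedModification] = []
    for mod in mods:
        for pos, aa in enumerate(peptide.sequence, start=1):
            if aa in mod.targets:
                am = AppliedModification(mod, pos)
                (fixed if mod.fixed else variable_sites).append(am)
        if N_TERMINUS in mod.targets and peptide.start == 1:
            am = AppliedModification(mod, N_TERMINUS)
            (fixed if mod.fixed else variable_sites).append(am)
    states = []
    for k in range(0, min(max_variable, len(variable_sites)) + 1):
        for combo in itertools.combinations(variable_sites, k):
            states.append(tuple(fixed) + combo)
    return states


# -- pair database ------------------------------------------------------------

SINGLE_LABEL = ((LabelingState.N14, LabelingState.N14),)
MIXED_LABELS = tuple(itertools.product((LabelingState.N14, LabelingState.N15), repeat=2))


def build_pair_database(
    peptides: Sequence[DigestedPeptide],
    linker: CrossLinker,
    mods: Sequence[Modification] = (),
    labeling_modes: Sequence[tuple[LabelingState, LabelingState]] = SINGLE_LABEL,
    max_variable_mods: int = 2,
    annotate: bool = True,
    prefilter: bool = True,
) -> list[CandidatePair]:
    """Enumerate the cross-linked candidate-pair database.

    All unordered peptide pairs (including self-pairs, which real homodimer
    data produce) are crossed with the variable-modification states and the
    requested labeling combinations.  Pair records are deduplicated on a
    canonical ordering of the two chains.
    """
    peptides = list(peptides)
    if annotate:
        peptides = annotate_sites(peptides, linker)
    if prefilter:
        peptides = filter_candidates(peptides, linker)
    if not peptides:
        warnings.warn("no linkable peptides: pair database is empty", stacklevel=2)
        return []

    expanded: list[tuple[DigestedPeptide, tuple[AppliedModification, ...]]] = []
    for p in peptides:
        for state in _mod_states(p, mods, max_variable_mods):
            expanded.append((p, state))

    pairs: dict[tuple, CandidatePair] = {}
    for ia in range(len(expanded)):
        pa, ma = expanded[ia]
        for ib in range(ia, len(expanded)):
            pb, mb = expanded[ib]
            compatible = (pa.sites_end1 and pb.sites_end2) or (
                pa.sites_end2 and pb.sites_end1
            )
            if not compatible:
                continue
            for la, lb in labeling_modes:
                a, b = (pa, ma, la), (pb, mb, lb)
                # canonical chain order => unordered-pair deduplication
                if _chain_key(*b) < _chain_key(*a):
                    a, b = b, a
                pair = CandidatePair(
                    peptide_a=a[0], peptide_b=b[0], linker=linker,
                    mods_a=a[1], mods_b=b[1], label_a=a[2], label_b=b[2],
                    mass=(
                        peptide_monoisotopic_mass(a[0].sequence, a[1], a[2])
                        + peptide_monoisotopic_mass(b[0].sequence, b[1], b[2])
                        + linker.bridge_delta
                    ),
                )
                pairs.setdefault(pair.key(), pair)
    return sorted(pairs.values(), key=lambda p: p.key())


def _chain_key(
    p: DigestedPeptide, mods: tuple[AppliedModification, ...], label: LabelingState
) -> tuple:
    return (
        p.sequence, p.protein_id, p.start,
        tuple((m.mod.name, site_sort_key(m.site)) for m in mods),
        label.value,
    )


def build_decoy(protein: ProteinRecord) -> ProteinRecord:
    """Reversed-sequence decoy of a protein (an involution on the sequence)."""
    return ProteinRecord(
        identifier=protein.identifier
        if protein.decoy
        else f"decoy_{protein.identifier}",
        sequence=protein.sequence[::-1],
        decoy=not protein.decoy,
    )


def export_pairs_tsv(pairs: Sequence[CandidatePair], stream: TextIO) -> None:
    """Write the pair database as a TSV for inspection."""
    header = [
        "peptide_a", "protein_a", "start_a", "sites_a",
        "peptide_b", "protein_b", "start_b", "sites_b",
        "label_combo", "pair_mass",
    ]
    stream.write("\t".join(header) + "\n")
    for p in pairs:
        stream.write(
            "\t".join(
                [
                    p.peptide_a.sequence, p.peptide_a.protein_id, str(p.peptide_a.start),
                    ";".join(str(s) for s in p.peptide_a.all_sites),
                    p.peptide_b.sequence, p.peptide_b.protein_id, str(p.peptide_b.start),
                    ";".join(str(s) for s in p.peptide_b.all_sites),
                    p.label_combo, f"{p.mass:.6f}",
                ]
            )
            + "\n"
        )
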