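"""Monoisotopic mass arithmetic for peptides, fragments and cross-linkers.

All masses are monoisotopic and in Daltons.  The m/z <-> neutral-mass
convention used throughout is *hydrogen-atom* based::

    neutral mass = charge * m/z - charge * m(H)

i.e. each charge is carried by a hydrogen atom of mass 1.007825 Da.  Fragment
ladders follow the usual b/y definitions: ``b_i`` is the neutral prefix sum of
residue masses, ``y_j`` the neutral suffix sum plus one water, so that
``b_i + y_(n-i)`` equals the neutral peptide mass for every cleavage site.

A cross-link is treated as a site-localized modification: the partner chain
plus the linker bridge add a single mass delta at the linked residue, which
propagates into every fragment that contains that residue.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mass as _pt_mass

# -- fundamental constants (CODATA / unimod-style monoisotopic values) -------

HYDROGEN_ATOM: float = 1.00782503207
"""Mass of a hydrogen atom, Da; one unit of charge in the m/z convention."""

PROTON: float = 1.00727646688
"""Proton mass, Da (kept for reference; charge arithmetic uses the H atom)."""

WATER: float = 18.0105646837
"""Monoisotopic mass of H2O, Da (the peptide condensation terminus)."""

N15_MINUS_N14: float = 0.9970349
"""Mass shift per nitrogen atom under full 15N metabolic labeling, Da."""

#: Sentinel token for the protein N-terminus as a cross-linkable site.  It is
#: deliberately not an integer position: residue positions are 1-based and the
#: alpha-amine is a distinct chemical entity from residue 1's side chain.
N_TERMINUS = "N-term"

Site = int | str  # residue position (1-based) or N_TERMINUS


def site_sort_key(site: Site) -> int:
    """Total order over link sites: the N-terminus precedes every residue."""
    return 0 if site == N_TERMINUS else int(site)


# -- residue table ------------------------------------------------------------

#: letter -> monoisotopic residue mass, Da (standard 20 amino acids plus U/O).
RESIDUE_MASS: dict[str, float] = dict(_pt_mass.std_aa_mass)

#: letter -> number of nitrogen atoms in the residue (backbone + side chain);
#: drives the 15N metabolic-labeling mass shift.
RESIDUE_NITROGEN: dict[str, int] = {
    aa: comp.get("N", 0) for aa, comp in _pt_mass.std_aa_comp.items() if len(aa) == 1
}


class LabelingState(enum.Enum):
    """Nitrogen isotope state of one peptide chain."""

    N14 = "14N"
    N15 = "15N"


@dataclass(frozen=True)
class Modification:
    """A fixed or variable mass modification on residues or a terminus.

    ``nitrogen`` counts nitrogen atoms the modification *adds from the growth
    medium*; exogenous reagent nitrogens (e.g. the carbamidomethyl amide) are
    not metabolically labeled and default to 0.
    """

    name: str
    targets: frozenset[str]  # residue letters and/or N_TERMINUS
    delta: float  # Da
    fixed: bool = True
    nitrogen: int = 0

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"modification {self.name!r} has an empty target set")
        if not np.isfinite(self.delta):
            raise ValueError(f"modification {self.name!r} has a non-finite delta")


@dataclass(frozen=True)
class AppliedModification:
    """A modification instance placed at a concrete site of one peptide."""

    mod: Modification
    site: Site  # 1-based residue position or N_TERMINUS


@dataclass(frozen=True)
class EndSpecificity:
    """Reactive specificity of one cross-linker end."""

    residues: frozenset[str] = frozenset()
    protein_nterm: bool = False
    wildcard: bool = False  # reacts with any residue (post-photolysis diazirine)

    def __bool__(self) -> bool:
        return bool(self.residues) or self.protein_nterm or self.wildcard


@dataclass(frozen=True)
class CrossLinker:
    """A bifunctional cross-linking reagent.

    ``bridge_delta`` is the net monoisotopic mass added to the two linked
    peptides after both reactive groups have reacted and leaving groups left.
    """

    name: str
    end1: EndSpecificity
    end2: EndSpecificity
    bridge_delta: float

    def __post_init__(self) -> None:
        if not self.end1:
            raise ValueError("cross-linker end1 specificity must be non-empty")
        if not np.isfinite(self.bridge_delta):
            raise ValueError("bridge delta must be finite")
        if self.end1.wildcard and not self.end2.wildcard:
            raise ValueError("wildcard specificity is only allowed on end2 (or both)")


# Built-in reagents.  DSS bridges two primary amines (Lys side chains and the
# protein alpha-amine); its C8H10O2 spacer remains after both NHS esters are
# displaced.  SDA couples an amine at the NHS end; UV photolysis of the
# diazirine loses N2 and the carbene inserts into any nearby residue, leaving
# a C5H6O bridge.
DSS = CrossLinker(
    name="DSS",
    end1=EndSpecificity(residues=frozenset("K"), protein_nterm=True),
    end2=EndSpecificity(residues=frozenset("K"), protein_nterm=True),
    bridge_delta=138.06808,
)
SDA = CrossLinker(
    name="SDA",
    end1=EndSpecificity(residues=frozenset("K"), protein_nterm=True),
    end2=EndSpecificity(wildcard=True),
    bridge_delta=82.04186,
)

CARBAMIDOMETHYL = Modification(
    name="Carbamidomethyl",
    targets=frozenset("C"),
    delta=57.02146,
    fixed=True,
)

BUILTIN_LINKERS: dict[str, CrossLinker] = {"DSS": DSS, "SDA": SDA}
BUILTIN_MODIFICATIONS: dict[str, Modification] = {"Carbamidomethyl": CARBAMIDOMETHYL}


# -- mass arithmetic ----------------------------------------------------------


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for pos, letter in enumerate(sequence, start=1):
        if letter not in RESIDUE_MASS:
            raise ValueError(f"unknown residue {letter!r} at position {pos}")


def peptide_nitrogen_count(
    sequence: str, mods: Sequence[AppliedModification] = ()
) -> int:
    """Number of metabolically labelable nitrogen atoms in a peptide chain."""
    _check_sequence(sequence)
    n = sum(RESIDUE_NITROGEN[aa] for aa in sequence)
    n += sum(am.mod.nitrogen for am in mods)
    return n


def peptide_monoisotopic_mass(
    sequence: str,
    mods: Sequence[AppliedModification] = (),
    label: LabelingState = LabelingState.N14,
) -> float:
    """Neutral monoisotopic mass of a (modified, possibly 15N-labeled) peptide.

    mass = sum(residue masses) + water + sum(mod deltas) + label shift,
    where the 15N shift is ``N15_MINUS_N14`` per nitrogen atom in the chain.
    """
    _check_sequence(sequence)
    m = sum(RESIDUE_MASS[aa] for aa in sequence) + WATER
    m += sum(am.mod.delta for am in mods)
    if label is LabelingState.N15:
        m += N15_MINUS_N14 * peptide_nitrogen_count(sequence, mods)
    return m


def mz_to_neutral_mass(mz: float, charge: int) -> float:
    """Neutral mass from an observed m/z at the given positive charge."""
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return charge * mz - charge * HYDROGEN_ATOM


def neutral_mass_to_mz(mass: float, charge: int) -> float:
    """Observed m/z of a neutral mass at the given positive charge."""
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (mass + charge * HYDROGEN_ATOM) / charge


def _site_position(site: Site, length: int) -> int:
    """Map a link/mod site to the residue position carrying its mass."""
    if site == N_TERMINUS:
        return 1  # the alpha-amine travels with residue 1 in b/y fragments
    pos = int(site)
    if not 1 <= pos <= length:
        raise ValueError(f"site {pos} outside peptide of length {length}")
    return pos


def fragment_ladders(
    sequence: str,
    mods: Sequence[AppliedModification] = (),
    xl_site: Site | None = None,
    xl_delta: float = 0.0,
    label: LabelingState = LabelingState.N14,
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral b- and y-ion mass ladders of a peptide chain.

    Returns ``(b, y)`` arrays of length ``n - 1``: ``b[i-1]`` is the b_i ion
    and ``y[j-1]`` the y_j ion.  Site-localized deltas (modifications and the
    cross-linked partner-plus-bridge mass at ``xl_site``) are added to every
    fragment containing that site, so ``b_i + y_(n-i)`` always equals the full
    modified chain mass.
    """
    _check_sequence(sequence)
    n = len(sequence)
    residue = np.array([RESIDUE_MASS[aa] for aa in sequence])
    if label is LabelingState.N15:
        residue = residue + N15_MINUS_N14 * np.array(
            [RESIDUE_NITROGEN[aa] for aa in sequence], dtype=float
        )
    # per-position deltas; terminus-targeted mods ride with residue 1
    delta = np.zeros(n)
    for am in mods:
        delta[_site_position(am.site, n) - 1] += am.mod.delta
        if label is LabelingState.N15:
            delta[_site_position(am.site, n) - 1] += N15_MINUS_N14 * am.mod.nitrogen
    if xl_site is not None:
        delta[_site_position(xl_site, n) - 1] += xl_delta
    per_residue = residue + delta
    prefix = np.cumsum(per_residue)
    b = prefix[:-1]
    y = (prefix[-1] - prefix[:-1])[::-1] + WATER
    return b, y
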