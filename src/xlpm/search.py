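"""The search core: precursor matching, the b -> complementary-y filter,
cross-link site localization and the match score.

The fragment filter exploits a property of CID spectra: when a b ion is
observed at a charge below the precursor charge, its complementary y ion
tends to be present at the remaining charge, because the two fragments share
the precursor's protons.  For each candidate site assignment the partner
chain plus the linker bridge is treated as a site-localized modification,
theoretical b ions of both chains are matched against the spectrum at every
sub-precursor charge, and a complementary y ion is sought only for matched b
ions.  The score is

    score = Nmb/Ntb + (Nmy/Nty) / Ryb(z)

where Nmb/Nmy count matched b ions / complementary y ions (once per fragment
position), Ntb = Nty = sum over both chains of (length - 1), and Ryb(z) is
the median complementary y/b ratio for precursor charge z estimated from an
annotated linear-peptide library (see :mod:`xlpm.bystats`).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from xlpm.chem import (
    HYDROGEN_ATOM,
    Site,
    fragment_ladders,
    mz_to_neutral_mass,
    neutral_mass_to_mz,
    peptide_monoisotopic_mass,
    site_sort_key,
)
from xlpm.database import CandidatePair
from xlpm.spectra_io import Spectrum


@dataclass(frozen=True)
class RybTable:
    """Per-precursor-charge median complementary y/b ratio.

    Lookups for charges without an entry fall back to the nearest defined
    charge (ties toward the lower charge).  The shipped default is an
    explicit placeholder: regenerate from any annotated library with
    :func:`xlpm.bystats.ryb_table` for scores comparable across runs.
    """

    ratios: Mapping[int, float]

    def __post_init__(self) -> None:
        if not self.ratios:
            raise ValueError("Ryb table must define at least one charge")
        for z, r in self.ratios.items():
            if not (0 < r <= 1):
                raise ValueError(f"Ryb({z}) = {r} outside (0, 1]")

    def __getitem__(self, charge: int) -> float:
        if charge in self.ratios:
            return self.ratios[charge]
        nearest = min(self.ratios, key=lambda z: (abs(z - charge), z))
        return self.ratios[nearest]


#: Placeholder defaults, NOT library-derived values; always prefer a table
#: estimated from your own annotated data.
DEFAULT_RYB = RybTable({2: 0.50, 3: 0.40, 4: 0.30, 5: 0.25})


@dataclass(frozen=True)
class SearchConfig:
    """Tolerances and scoring options for one search run."""

    precursor_ppm: float = 10.0
    fragment_tol_da: float = 0.5
    ryb: RybTable = DEFAULT_RYB
    min_xl_charge: int = 2
    #: candidate charges tried when an MGF block carries no CHARGE line
    assumed_charges: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    #: 'y_only' divides only the y term by Ryb; 'global' divides the sum
    score_grouping: str = "y_only"

    def __post_init__(self) -> None:
        if self.precursor_ppm <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_xl_charge < 1:
            raise ValueError("minimum precursor charge must be >= 1")
        if self.score_grouping not in ("y_only", "global"):
            raise ValueError(f"unknown score grouping {self.score_grouping!r}")


@dataclass(frozen=True)
class MatchResult:
    """Fragment-match counts and score for one (spectrum, pair, sites)."""

    scan_id: str
    pair: CandidatePair
    site_a: Site
    site_b: Site
    n_matched_b: int
    n_total_b: int
    n_matched_y: int
    n_total_y: int
    score: float
    precursor_charge: int
    precursor_mass: float
    ambiguous_sites: tuple[tuple[Site, Site], ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.n_matched_b <= self.n_total_b):
            raise ValueError("matched b count outside [0, total b]")
        if not (0 <= self.n_matched_y <= self.n_total_y):
            raise ValueError("matched y count outside [0, total y]")
        if self.n_matched_y > self.n_matched_b:
            raise ValueError("complementary y ions cannot exceed matched b ions")

    @property
    def decoy(self) -> bool:
        return self.pair.decoy


# -- precursor matching -------------------------------------------------------


def match_precursors(
    spectra: Sequence[Spectrum],
    pair_db: Sequence[CandidatePair],
    config: SearchConfig,
) -> list[tuple[Spectrum, int, CandidatePair]]:
    """All (spectrum, assumed charge, pair) triples within the ppm tolerance.

    Every qualifying pair is returned; no best-only pruning happens before
    fragment scoring.  Spectra without a charge are tried at each configured
    candidate charge.
    """
    if not pair_db:
        raise ValueError("pair database is empty")
    masses = np.array([p.mass for p in pair_db])
    order = np.argsort(masses, kind="stable")
    sorted_masses = masses[order]
    out: list[tuple[Spectrum, int, CandidatePair]] = []
    for spec in spectra:
        charges = (spec.charge,) if spec.charge else config.assumed_charges
        for z in charges:
            if z < config.min_xl_charge:
                continue
            neutral = mz_to_neutral_mass(spec.precursor_mz, z)
            tol = neutral * config.precursor_ppm * 1e-6
            lo = np.searchsorted(sorted_masses, neutral - tol, side="left")
            hi = np.searchsorted(sorted_masses, neutral + tol, side="right")
            for idx in order[lo:hi]:
                pair = pair_db[idx]
                if abs(neutral - pair.mass) / pair.mass * 1e6 <= config.precursor_ppm:
                    out.append((spec, z, pair))
    return out


# -- fragment matching --------------------------------------------------------


def _has_peak(sorted_mz: np.ndarray, mz: float, tol: float) -> bool:
    """Nearest-peak lookup within an absolute Da tolerance (no consumption:
    one observed peak may satisfy several theoretical ions)."""
    i = bisect.bisect_left(sorted_mz, mz)
    if i < len(sorted_mz) and sorted_mz[i] - mz <= tol:
        return True
    return i > 0 and mz - sorted_mz[i - 1] <= tol


def _chain_ladders(pair: CandidatePair, site_a: Site, site_b: Site):
    """b/y ladders of both chains, each carrying partner + bridge at its
    link site."""
    mass_a = peptide_monoisotopic_mass(
        pair.peptide_a.sequence, pair.mods_a, pair.label_a
    )
    mass_b = peptide_monoisotopic_mass(
        pair.peptide_b.sequence, pair.mods_b, pair.label_b
    )
    delta_on_a = mass_b + pair.linker.bridge_delta
    delta_on_b = mass_a + pair.linker.bridge_delta
    ladders_a = fragment_ladders(
        pair.peptide_a.sequence, pair.mods_a, site_a, delta_on_a, pair.label_a
    )
    ladders_b = fragment_ladders(
        pair.peptide_b.sequence, pair.mods_b, site_b, delta_on_b, pair.label_b
    )
    return ladders_a, ladders_b


def by_filter_match(
    spectrum: Spectrum,
    pair: CandidatePair,
    site_a: Site,
    site_b: Site,
    config: SearchConfig,
    precursor_charge: int | None = None,
) -> MatchResult:
    """Count matched b ions and their complementary y ions for one site pair.

    For every theoretical b_i of each chain and every b charge
    z_b in 1..(z_precursor - 1), the spectrum is searched within the fragment
    tolerance; on a b match the complementary y_(n-i) is sought at charge
    (z_precursor - z_b).  A fragment position counts once toward Nmb (and
    once toward Nmy) no matter how many charge states matched.
    """
    z_p = precursor_charge if precursor_charge is not None else spectrum.charge
    if z_p is None:
        raise ValueError("precursor charge is required for fragment matching")
    tol = config.fragment_tol_da
    (b_a, y_a), (b_b, y_b) = _chain_ladders(pair, site_a, site_b)
    nmb = nmy = 0
    ntb = 0
    for b_ladder, y_ladder in ((b_a, y_a), (b_b, y_b)):
        n_frag = len(b_ladder)  # = chain length - 1
        ntb += n_frag
        for i in range(n_frag):
            b_neutral = b_ladder[i]
            y_neutral = y_ladder[n_frag - 1 - i]  # y_(n-i), the complement
            b_seen = y_seen = False
            for z_b in range(1, z_p):
                b_mz = neutral_mass_to_mz(b_neutral, z_b)
                if not _has_peak(spectrum.mz, b_mz, tol):
                    continue
                b_seen = True
                z_y = z_p - z_b
                y_mz = neutral_mass_to_mz(y_neutral, z_y)
                if _has_peak(spectrum.mz, y_mz, tol):
                    y_seen = True
            nmb += b_seen
            nmy += y_seen
    score = xlpm_score(nmb, ntb, nmy, ntb, config.ryb, z_p, config.score_grouping)
    return MatchResult(
        scan_id=spectrum.scan_id, pair=pair, site_a=site_a, site_b=site_b,
        n_matched_b=nmb, n_total_b=ntb, n_matched_y=nmy, n_total_y=ntb,
        score=score, precursor_charge=z_p,
        precursor_mass=mz_to_neutral_mass(spectrum.precursor_mz, z_p),
    )


def xlpm_score(
    n_matched_b: int,
    n_total_b: int,
    n_matched_y: int,
    n_total_y: int,
    ryb: RybTable,
    precursor_charge: int,
    grouping: str = "y_only",
) -> float:
    """Count-based match score; the y term is up-weighted by 1/Ryb(z)."""
    if n_total_b <= 0 or n_total_y <= 0:
        raise ValueError("total fragment counts must be positive")
    r = ryb[precursor_charge]
    b_term = n_matched_b / n_total_b
    y_term = n_matched_y / n_total_y
    if grouping == "y_only":
        return b_term + y_term / r
    if grouping == "global":
        return (b_term + y_term) / r
    raise ValueError(f"unknown score grouping {grouping!r}")


def localize_sites(
    spectrum: Spectrum,
    pair: CandidatePair,
    config: SearchConfig,
    precursor_charge: int | None = None,
) -> MatchResult:
    """Best-scoring link-site assignment over all compatible site pairs.

    Ties are broken toward the lexicographically smallest (site A, site B)
    and recorded in ``ambiguous_sites`` (all co-optimal assignments, in
    order) so that indistinguishable localizations are visible to callers.
    """
    combos = pair.site_combinations()
    if not combos:
        raise ValueError("candidate pair has no compatible site combination")
    results = [
        by_filter_match(spectrum, pair, sa, sb, config, precursor_charge)
        for sa, sb in combos
    ]
    best_score = max(r.score for r in results)
    co_optimal = [r for r in results if r.score == best_score]
    best = co_optimal[0]  # combos are pre-sorted lexicographically
    if len(co_optimal) > 1:
        best = replace(
            best,
            ambiguous_sites=tuple((r.site_a, r.site_b) for r in co_optimal),
        )
    return best
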