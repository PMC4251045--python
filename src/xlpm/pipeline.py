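"""End-to-end orchestration: database build -> precursor match -> fragment
scoring -> localization -> report, with a run manifest.

Every stage count lands in the manifest because the reported scores are
meaningless without the tolerances and the Ryb table that produced them.
Runs are deterministic: identical inputs and configuration give
byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO

from xlpm._version import __version__ as _version
from xlpm.chem import (
    CrossLinker,
    LabelingState,
    Modification,
    N_TERMINUS,
    neutral_mass_to_mz,
)
from xlpm.database import (
    CandidatePair,
    EnzymeRule,
    ProteinRecord,
    TRYPSIN,
    annotate_sites,
    build_decoy,
    build_pair_database,
    digest,
    filter_candidates,
    read_fasta,
    SINGLE_LABEL,
    MIXED_LABELS,
)
from xlpm.search import MatchResult, SearchConfig, localize_sites, match_precursors
from xlpm.spectra_io import ResultRow, Spectrum, read_mgf, write_results

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance and stage counts of one search run."""

    version: str = _version
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "input_digests": self.input_digests,
                "counts": self.counts,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _site_letter(peptide, site) -> str:
    return N_TERMINUS if site == N_TERMINUS else peptide.sequence[int(site) - 1]


def _result_row(res: MatchResult) -> ResultRow:
    pair = res.pair
    coord_a = pair.peptide_a.site_protein_coordinate(res.site_a)
    coord_b = pair.peptide_b.site_protein_coordinate(res.site_b)
    return ResultRow(
        mz=neutral_mass_to_mz(res.precursor_mass, res.precursor_charge),
        sequence_1=pair.peptide_a.sequence,
        sequence_2=pair.peptide_b.sequence,
        calculated_mass=pair.mass,
        precursor_mass=res.precursor_mass,
        charge=res.precursor_charge,
        score=res.score,
        crosslinked_residues=f"{coord_a}-{coord_b}",
        site_residues=(
            f"{_site_letter(pair.peptide_a, res.site_a)}-"
            f"{_site_letter(pair.peptide_b, res.site_b)}"
        ),
        scan_id=res.scan_id,
        label_combo=pair.label_combo,
        decoy=res.decoy,
    )


def search_spectra(
    spectra: Sequence[Spectrum],
    pairs: Sequence[CandidatePair],
    config: SearchConfig,
    best_per_spectrum: bool = True,
    matches: Sequence[tuple[Spectrum, int, CandidatePair]] | None = None,
) -> list[MatchResult]:
    """Score every precursor-matched (spectrum, pair) and localize sites.

    With ``best_per_spectrum`` only the top-scoring match of each spectrum is
    kept (ties broken by the pair's canonical key for reproducibility);
    otherwise all matches are returned.  Results are sorted by score
    descending, then scan id.
    """
    if matches is None:
        matches = match_precursors(spectra, pairs, config)
    results: list[MatchResult] = []
    for spec, charge, pair in matches:
        results.append(localize_sites(spec, pair, config, precursor_charge=charge))
    if best_per_spectrum:
        best: dict[str, MatchResult] = {}
        for res in results:
            cur = best.get(res.scan_id)
            if (
                cur is None
                or res.score > cur.score
                or (res.score == cur.score and res.pair.key() < cur.pair.key())
            ):
                best[res.scan_id] = res
        results = list(best.values())
    results.sort(key=lambda r: (-r.score, r.scan_id, r.pair.key()))
    return results


def run_search(
    fasta: str | Path,
    mgf: str | Path,
    config: SearchConfig,
    linker: CrossLinker,
    enzyme: EnzymeRule = TRYPSIN,
    mods: Sequence[Modification] = (),
    max_missed: int = 2,
    mixed_labels: bool = False,
    decoy: bool = False,
    out: str | Path | None = None,
    best_per_spectrum: bool = True,
) -> tuple[list[ResultRow], RunManifest]:
    """Full search of an MGF against a FASTA-derived cross-link database.

    With ``decoy=True`` every protein is sequence-reversed before digestion
    and the identical pipeline runs against the decoy database (the
    separate-search target/decoy design).  The result table is written only
    after the whole run succeeds; no partial output is produced.
    """
    proteins = read_fasta(fasta)
    if decoy:
        proteins = [build_decoy(p) for p in proteins]
    peptides = [p for prot in proteins for p in digest(prot, enzyme, max_missed)]
    annotated = annotate_sites(peptides, linker)
    filtered = filter_candidates(annotated, linker, enzyme)
    modes = MIXED_LABELS if mixed_labels else SINGLE_LABEL
    pairs = build_pair_database(
        filtered, linker, mods=mods, labeling_modes=modes,
        annotate=False, prefilter=False,
    )
    spectra = read_mgf(str(mgf))
    manifest = RunManifest(
        config={
            "linker": linker.name,
            "enzyme": enzyme.name,
            "decoy": decoy,
            "mixed_labels": mixed_labels,
            "precursor_ppm": config.precursor_ppm,
            "fragment_tol_da": config.fragment_tol_da,
            "ryb_table": dict(config.ryb.ratios),
            "min_xl_charge": config.min_xl_charge,
            "score_grouping": config.score_grouping,
            "max_missed": max_missed,
        },
        input_digests={"fasta": _sha256(fasta), "mgf": _sha256(mgf)},
    )
    manifest.counts["proteins"] = len(proteins)
    manifest.counts["peptides"] = len(peptides)
    manifest.counts["peptides_filtered"] = len(filtered)
    manifest.counts["pairs"] = len(pairs)
    manifest.counts["spectra"] = len(spectra)
    if spectra and pairs:
        precursor_matches = match_precursors(spectra, pairs, config)
        results = search_spectra(
            spectra, pairs, config, best_per_spectrum, matches=precursor_matches
        )
        manifest.counts["precursor_matches"] = len(precursor_matches)
    else:
        results = []
        manifest.counts["precursor_matches"] = 0
    manifest.counts["reported_ids"] = len(results)
    rows = [_result_row(r) for r in results]
    if out is not None:
        with open(out, "w") as fh:
            write_results(rows, fh)
        with open(str(out) + ".manifest.json", "w") as fh:
            fh.write(manifest.to_json())
    return rows, manifest
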