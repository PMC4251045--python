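"""Seeded simulator of CID spectra for cross-linked peptide pairs.

The generator provides ground truth for every other module: it emits b/y
ladders of both chains (the partner chain plus bridge riding as a mass on
the linked residue), partitions the precursor charge so each chain fragments
like an independent lower-charge peptide, couples complementary-y emission
to the detection of the corresponding b ion (the empirical behavior the
b->y filter exploits), and adds uniform noise peaks, peak dropout and m/z
jitter.  Intensities are exponential with unit mean — scoring is
count-based, so intensities only exercise I/O.  All randomness flows from a
single integer seed recorded in the truth table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from xlpm.chem import (
    CrossLinker,
    LabelingState,
    Site,
    neutral_mass_to_mz,
    site_sort_key,
)
from xlpm.database import (
    CandidatePair,
    DigestedPeptide,
    EnzymeRule,
    ProteinRecord,
    TRYPSIN,
    build_pair_database,
    digest,
    read_fasta,
    SINGLE_LABEL,
    MIXED_LABELS,
)
from xlpm.search import _chain_ladders
from xlpm.spectra_io import Spectrum, write_mgf


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the spectrum generator.

    Defaults emulate a moderately noisy ion-trap CID acquisition of tryptic
    cross-linked pairs: 80% fragment detection, complementary-y probability
    falling with precursor charge (the trend annotated libraries show),
    20 uniform noise peaks per spectrum and 0.2 Da peak jitter.
    """

    detect_prob: float = 0.8
    #: P(complementary y | matched b) per precursor-charge bin
    y_given_b: dict = field(
        default_factory=lambda: {2: 0.70, 3: 0.55, 4: 0.40, 5: 0.30}
    )
    noise_peaks: int = 20
    noise_mz_range: tuple[float, float] = (200.0, 2000.0)
    mz_jitter: float = 0.2  # Da, uniform in [-jitter, +jitter]
    charges: tuple[int, ...] = (4, 5, 6)

    def __post_init__(self) -> None:
        if not 0 <= self.detect_prob <= 1:
            raise ValueError("detect_prob must be in [0, 1]")
        for z, q in self.y_given_b.items():
            if not 0 <= q <= 1:
                raise ValueError(f"y_given_b[{z}] = {q} outside [0, 1]")
        if self.mz_jitter < 0 or self.noise_peaks < 0:
            raise ValueError("jitter and noise counts must be non-negative")

    def y_prob(self, precursor_charge: int) -> float:
        z = min(max(precursor_charge, min(self.y_given_b)), max(self.y_given_b))
        return self.y_given_b[z]


#: Noiseless settings: every fragment and every complement detected.
CLEAN_PARAMS = SimulationParams(
    detect_prob=1.0,
    y_given_b={z: 1.0 for z in (2, 3, 4, 5)},
    noise_peaks=0,
    mz_jitter=0.0,
)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated spectrum."""

    scan_id: str
    pair: CandidatePair
    site_a: Site
    site_b: Site
    precursor_charge: int
    label_combo: str


def simulate_spectrum(
    pair: CandidatePair,
    sites: tuple[Site, Site],
    charge: int,
    params: SimulationParams,
    seed: int | np.random.Generator,
    scan_id: str = "sim-0",
) -> tuple[Spectrum, TruthRecord]:
    """Simulate one CID spectrum of a cross-linked pair.

    For each chain and each backbone cleavage a b-ion charge is drawn from
    1..charge-1 (each chain behaving like a lower-charge peptide); the b ion
    appears with ``detect_prob`` and, when it does, the complementary y ion
    at the remaining charge appears with the per-charge coupling
    probability.  Deterministic for a fixed seed.
    """
    if charge < 2:
        raise ValueError("cross-linked precursors require charge >= 2")
    site_a, site_b = sites
    if site_a not in pair.peptide_a.all_sites and site_a != "N-term":
        raise ValueError(f"site {site_a!r} is not linkable on chain A")
    if site_b not in pair.peptide_b.all_sites and site_b != "N-term":
        raise ValueError(f"site {site_b!r} is not linkable on chain B")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    (b_a, y_a), (b_b, y_b) = _chain_ladders(pair, site_a, site_b)
    q_y = params.y_prob(charge)
    mz_list: list[float] = []
    for b_ladder, y_ladder in ((b_a, y_a), (b_b, y_b)):
        n_frag = len(b_ladder)
        for i in range(n_frag):
            z_b = int(rng.integers(1, charge))  # 1..charge-1
            if rng.random() >= params.detect_prob:
                continue
            mz_list.append(neutral_mass_to_mz(b_ladder[i], z_b))
            if rng.random() < q_y:
                y_neutral = y_ladder[n_frag - 1 - i]
                mz_list.append(neutral_mass_to_mz(y_neutral, charge - z_b))
    if params.mz_jitter > 0 and mz_list:
        jitter = rng.uniform(-params.mz_jitter, params.mz_jitter, size=len(mz_list))
        mz_list = list(np.asarray(mz_list) + jitter)
    lo, hi = params.noise_mz_range
    mz_list.extend(rng.uniform(lo, hi, size=params.noise_peaks))
    mz_arr = np.asarray(mz_list, dtype=float)
    intensity = rng.exponential(1.0, size=len(mz_arr))
    spectrum = Spectrum(
        scan_id=scan_id,
        precursor_mz=neutral_mass_to_mz(pair.mass, charge),
        charge=charge,
        mz=mz_arr,
        intensity=intensity,
    )
    truth = TruthRecord(
        scan_id=scan_id, pair=pair, site_a=site_a, site_b=site_b,
        precursor_charge=charge, label_combo=pair.label_combo,
    )
    return spectrum, truth


def generate_dataset(
    fasta: str | Path | Sequence[ProteinRecord],
    linker: CrossLinker,
    n_spectra: int,
    params: SimulationParams = SimulationParams(),
    seed: int = 0,
    enzyme: EnzymeRule = TRYPSIN,
    max_missed: int = 2,
    mixed_labels: bool = False,
    out_mgf: str | Path | None = None,
    out_truth: str | Path | None = None,
) -> tuple[list[Spectrum], list[TruthRecord]]:
    """Simulate a dataset of cross-linked spectra from protein sequences.

    Proteins are digested and paired exactly as the search does; pairs, link
    sites and precursor charges are then sampled uniformly.  Optionally
    writes a standard MGF plus a truth TSV whose header records the seed.
    """
    if n_spectra < 1:
        raise ValueError("n_spectra must be >= 1")
    proteins = (
        read_fasta(fasta) if isinstance(fasta, (str, Path)) else list(fasta)
    )
    peptides = [
        p for prot in proteins for p in digest(prot, enzyme, max_missed)
    ]
    modes = MIXED_LABELS if mixed_labels else SINGLE_LABEL
    pairs = build_pair_database(peptides, linker, labeling_modes=modes)
    pairs = [p for p in pairs if p.site_combinations()]
    if not pairs:
        raise ValueError("no valid cross-linkable pairs from the input proteins")
    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    truths: list[TruthRecord] = []
    for k in range(n_spectra):
        pair = pairs[int(rng.integers(len(pairs)))]
        combos = pair.site_combinations()
        sites = combos[int(rng.integers(len(combos)))]
        charge = int(rng.choice(params.charges))
        spec, truth = simulate_spectrum(
            pair, sites, charge, params, rng, scan_id=f"sim-{k}"
        )
        spectra.append(spec)
        truths.append(truth)
    if out_mgf is not None:
        write_mgf(spectra, str(out_mgf))
    if out_truth is not None:
        with open(out_truth, "w") as fh:
            write_truth_tsv(truths, fh, seed=seed)
    return spectra, truths


def write_truth_tsv(
    truths: Sequence[TruthRecord], stream: TextIO, seed: int | None = None
) -> None:
    if seed is not None:
        stream.write(f"# seed={seed}\n")
    stream.write(
        "scan\tpeptide_a\tpeptide_b\tsite_a\tsite_b\tcharge\tlabel_combo\tpair_mass\n"
    )
    for t in truths:
        stream.write(
            "\t".join(
                [
                    t.scan_id, t.pair.peptide_a.sequence, t.pair.peptide_b.sequence,
                    str(t.site_a), str(t.site_b), str(t.precursor_charge),
                    t.label_combo, f"{t.pair.mass:.6f}",
                ]
            )
            + "\n"
        )


def simulate_annotated_library(
    peptides: Sequence[str],
    n_spectra: int,
    charge_weights: dict[int, float] | None = None,
    b_detect_prob: float = 0.9,
    y_given_b: dict | None = None,
    seed: int = 0,
):
    """Simulate a linear-peptide annotated library for Ryb calibration.

    Each spectrum annotates b ions (one charge state in 1..z-1 per cleavage,
    detected with ``b_detect_prob``) and, independently per detected b, the
    complementary y with probability ``y_given_b[z]``.  Used to validate
    that the per-charge median ratio recovers the generating coupling
    probability.
    """
    from xlpm.chem import fragment_ladders
    from xlpm.spectra_io import AnnotatedSpectrum, IonAnnotation

    rng = np.random.default_rng(seed)
    if y_given_b is None:
        y_given_b = {2: 0.70, 3: 0.55, 4: 0.40, 5: 0.30}
    charges = sorted(y_given_b)
    if charge_weights is None:
        weights = np.full(len(charges), 1 / len(charges))
    else:
        weights = np.array([charge_weights.get(z, 0.0) for z in charges])
        weights = weights / weights.sum()
    library = []
    for k in range(n_spectra):
        pep = peptides[int(rng.integers(len(peptides)))]
        z_p = int(rng.choice(charges, p=weights))
        n = len(pep)
        b, y = fragment_ladders(pep)
        annotations: set[IonAnnotation] = set()
        mzs: list[float] = []
        for i in range(1, n):
            z_b = int(rng.integers(1, z_p))
            if rng.random() >= b_detect_prob:
                continue
            annotations.add(IonAnnotation("b", i, z_b))
            mzs.append(neutral_mass_to_mz(b[i - 1], z_b))
            if rng.random() < y_given_b[z_p]:
                annotations.add(IonAnnotation("y", n - i, z_p - z_b))
                mzs.append(neutral_mass_to_mz(y[n - i - 1], z_p - z_b))
        if not mzs:
            mzs = [100.0]
        from xlpm.chem import peptide_monoisotopic_mass

        library.append(
            AnnotatedSpectrum(
                spectrum=Spectrum(
                    scan_id=f"lib-{k}",
                    precursor_mz=neutral_mass_to_mz(
                        peptide_monoisotopic_mass(pep), z_p
                    ),
                    charge=z_p,
                    mz=np.array(mzs),
                    intensity=np.ones(len(mzs)),
                ),
                peptide=pep,
                annotations=frozenset(annotations),
            )
        )
    return library
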