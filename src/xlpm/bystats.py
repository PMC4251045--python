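"""Empirical calibration of the b -> complementary-y filter.

Given an annotated linear-peptide library, each spectrum yields the fraction
of its annotated sub-precursor-charge b ions whose complementary y ion (same
cleavage site, remaining charge) is also annotated.  The per-charge medians
of these ratios form the Ryb table that weights the y term of the match
score.  Counting is per ion: every annotated (b, i, z_b) with z_b below the
precursor charge contributes one unit to the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from xlpm.search import RybTable
from xlpm.spectra_io import AnnotatedSpectrum, IonAnnotation

#: Charge bins used for the per-charge medians; the last bin pools >= 5.
CHARGE_BINS = (2, 3, 4, 5)


def charge_bin(charge: int) -> int:
    """Map a precursor charge onto the reporting bins {2, 3, 4, 5+}."""
    return min(max(charge, CHARGE_BINS[0]), CHARGE_BINS[-1])


@dataclass(frozen=True)
class RatioRecord:
    """Complementary y/b ratio of one annotated spectrum."""

    scan_id: str
    precursor_charge: int
    n_b: int
    n_y_comp: int
    excluded: bool = False

    @property
    def ratio(self) -> float:
        if self.excluded:
            raise ValueError(f"spectrum {self.scan_id!r} has no qualifying b ions")
        return self.n_y_comp / self.n_b


def complementary_ratio(spectrum: AnnotatedSpectrum) -> RatioRecord:
    """Per-spectrum fraction of annotated b ions with an annotated complement.

    The complement of (b, i, z_b) in a length-n peptide at precursor charge
    z_p is (y, n-i, z_p - z_b).  Neutral-loss/isotope/internal annotations
    were already set aside at parse time; only plain b/y series count.
    Spectra without any qualifying b ion are flagged excluded.
    """
    z_p = spectrum.precursor_charge
    n = len(spectrum.peptide)
    annotations = spectrum.annotations
    n_b = n_y = 0
    for ann in annotations:
        if ann.series != "b" or ann.charge >= z_p:
            continue
        if not 1 <= ann.index <= n - 1:
            continue
        n_b += 1
        complement = IonAnnotation("y", n - ann.index, z_p - ann.charge)
        n_y += complement in annotations
    return RatioRecord(
        scan_id=spectrum.spectrum.scan_id,
        precursor_charge=z_p,
        n_b=n_b,
        n_y_comp=n_y,
        excluded=n_b == 0,
    )


def ryb_table(
    library: Iterable[AnnotatedSpectrum],
) -> tuple[RybTable, dict[int, np.ndarray]]:
    """Estimate the per-charge median complementary y/b ratio from a library.

    Returns the Ryb table over the populated charge bins plus the raw ratio
    arrays per bin (for histogram plotting / export).  Empty bins are left
    out with a warning; the table's nearest-charge fallback covers them at
    search time.
    """
    ratios: dict[int, list[float]] = {z: [] for z in CHARGE_BINS}
    for spec in library:
        rec = complementary_ratio(spec)
        if rec.excluded:
            continue
        ratios[charge_bin(rec.precursor_charge)].append(rec.ratio)
    histograms = {z: np.array(v) for z, v in ratios.items() if v}
    for z in CHARGE_BINS:
        if z not in histograms:
            warnings.warn(f"no valid spectra in charge bin {z}; bin omitted",
                          stacklevel=2)
    medians = {z: float(np.median(v)) for z, v in histograms.items()}
    # a median of exactly 0 cannot weight the score; clamp to a small floor
    table = RybTable({z: max(m, 1e-3) for z, m in medians.items()})
    return table, histograms


def write_ryb_tsv(table: RybTable, stream: TextIO) -> None:
    """Persist a Ryb table as a two-column TSV (charge, median ratio)."""
    stream.write("charge\tryb\n")
    for z in sorted(table.ratios):
        stream.write(f"{z}\t{table.ratios[z]:.6f}\n")


def read_ryb_tsv(source: TextIO) -> RybTable:
    """Load a Ryb table written by :func:`write_ryb_tsv`."""
    header = source.readline().strip().split("\t")
    if header != ["charge", "ryb"]:
        raise ValueError("unrecognized Ryb table header")
    ratios = {}
    for line in source:
        if not line.strip():
            continue
        z, r = line.split("\t")
        ratios[int(z)] = float(r)
    return RybTable(ratios)
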