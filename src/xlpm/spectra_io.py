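"""Peak-list I/O: MGF input, NIST-style MSP libraries, and the result table.

MGF reading and writing go through :mod:`pyteomics.mgf`; PEPMASS is always
interpreted as the precursor m/z.  MSP entries are parsed with a small
reader tailored to the NIST dialect (``Name:`` / ``MW:`` / ``Comment:`` /
``Num peaks:`` headers followed by ``mz intensity "annotation"`` lines);
plain b/y annotations such as ``b2/0.1`` or ``y5^2/0.2`` are decoded into
(series, index, charge) triples, anything else (neutral losses, isotopes,
internal ions) is kept as opaque text.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from pyteomics import mgf as _pt_mgf


@dataclass
class Spectrum:
    """One MS/MS spectrum: precursor plus a centroided peak list."""

    scan_id: str
    precursor_mz: float
    charge: int | None
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class IonAnnotation:
    series: str  # 'b' or 'y'
    index: int
    charge: int


@dataclass
class AnnotatedSpectrum:
    """A library spectrum with its peptide and per-peak ion annotations."""

    spectrum: Spectrum
    peptide: str
    annotations: frozenset[IonAnnotation]
    opaque_annotations: tuple[str, ...] = ()

    @property
    def precursor_charge(self) -> int:
        if self.spectrum.charge is None:
            raise ValueError(f"spectrum {self.spectrum.scan_id!r} has no charge")
        return self.spectrum.charge


@dataclass(frozen=True)
class ResultRow:
    """One reported cross-link identification (the output-table schema)."""

    mz: float
    sequence_1: str
    sequence_2: str
    calculated_mass: float
    precursor_mass: float
    charge: int
    score: float
    crosslinked_residues: str  # protein coordinates, "a-b"
    site_residues: str = ""  # linked residue letters, e.g. "K-K" or "N-term-K"
    scan_id: str = ""
    label_combo: str = "14Nx14N"
    decoy: bool = False


RESULT_COLUMNS = (
    "m/z", "Sequence 1", "Sequence 2", "Calculated mass", "Precursor mass",
    "Charge", "XLPM score", "Cross-linked residues", "Site residues",
    "Scan", "Label combo", "Decoy",
)


# -- MGF ----------------------------------------------------------------------


def read_mgf(source: str | Path | TextIO) -> list[Spectrum]:
    """Read every BEGIN/END IONS block of an MGF file.

    A missing CHARGE line leaves the charge unset; downstream search assigns
    candidate charges per configuration.
    """
    spectra: list[Spectrum] = []
    with _pt_mgf.MGF(source, convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"index={i}"))
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise ValueError(f"MGF block {title!r} lacks a PEPMASS line")
            mz0 = pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else None
            spectra.append(
                Spectrum(
                    scan_id=title,
                    precursor_mz=float(mz0),
                    charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    if not spectra:
        warnings.warn("MGF file contained no spectra", stacklevel=2)
    return spectra


def write_mgf(spectra: Iterable[Spectrum], target: str | Path | TextIO) -> None:
    """Write spectra as a standard MGF file."""
    entries = []
    for s in spectra:
        params = {"title": s.scan_id, "pepmass": s.precursor_mz}
        if s.charge is not None:
            params["charge"] = s.charge
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _pt_mgf.write(entries, target, file_mode="w")


# -- MSP ----------------------------------------------------------------------

_ANNOT_RE = re.compile(r"^([by])(\d+)(?:\^(\d+))?$")
_NAME_RE = re.compile(r"^Name:\s*(\S+)", re.IGNORECASE)


def _parse_annotation(text: str) -> IonAnnotation | None:
    """Decode a single MSP peak annotation; None when not a plain b/y ion."""
    head = text.split("/", 1)[0].strip()
    m = _ANNOT_RE.match(head)
    if m is None:
        return None
    return IonAnnotation(series=m.group(1), index=int(m.group(2)),
                         charge=int(m.group(3) or 1))


def read_msp(source: str | Path | TextIO) -> list[AnnotatedSpectrum]:
    """Read a NIST-style MSP annotated library.

    ``Name: PEPTIDE/charge`` supplies the sequence and precursor charge; the
    precursor m/z is reconstructed from ``MW:``/``PrecursorMZ:`` when present,
    otherwise from the peptide mass.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_msp(fh)
    entries: list[AnnotatedSpectrum] = []
    lines = list(source)
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        name_match = _NAME_RE.match(line)
        if not name_match:
            raise ValueError(f"expected a Name: header at line {i + 1}, got {line!r}")
        name = name_match.group(1)
        peptide, _, charge_str = name.partition("/")
        charge = int(charge_str) if charge_str else None
        header: dict[str, str] = {}
        i += 1
        num_peaks = None
        while i < len(lines):
            line = lines[i].strip()
            i += 1
            if not line:
                continue
            key, _, value = line.partition(":")
            header[key.strip().lower()] = value.strip()
            if key.strip().lower() == "num peaks":
                num_peaks = int(value)
                break
        if num_peaks is None:
            raise ValueError(f"MSP entry {name!r} lacks a 'Num peaks' header")
        mzs, intens = [], []
        annotations: set[IonAnnotation] = set()
        opaque: list[str] = []
        for _ in range(num_peaks):
            if i >= len(lines):
                raise ValueError(f"MSP entry {name!r} is truncated")
            parts = lines[i].strip().split(None, 2)
            i += 1
            mzs.append(float(parts[0]))
            intens.append(float(parts[1]))
            if len(parts) > 2:
                text = parts[2].strip().strip('"')
                if text and text != "?":
                    ann = _parse_annotation(text)
                    if ann is not None:
                        annotations.add(ann)
                    else:
                        opaque.append(text)
        if "precursormz" in header:
            prec_mz = float(header["precursormz"])
        elif "mw" in header and charge:
            prec_mz = float(header["mw"]) / charge
        else:
            prec_mz = max(mzs) if mzs else 1.0
        entries.append(
            AnnotatedSpectrum(
                spectrum=Spectrum(
                    scan_id=name, precursor_mz=prec_mz, charge=charge,
                    mz=np.array(mzs), intensity=np.array(intens),
                ),
                peptide=peptide,
                annotations=frozenset(annotations),
                opaque_annotations=tuple(opaque),
            )
        )
    return entries


# -- result table -------------------------------------------------------------


def write_results(rows: Sequence[ResultRow], stream: TextIO) -> None:
    """Write identifications as a TSV with the standard column layout."""
    stream.write("\t".join(RESULT_COLUMNS) + "\n")
    for r in rows:
        stream.write(
            "\t".join(
                [
                    f"{r.mz:.7f}", r.sequence_1, r.sequence_2,
                    f"{r.calculated_mass:.6f}", f"{r.precursor_mass:.6f}",
                    str(r.charge), f"{r.score:.9f}", r.crosslinked_residues,
                    r.site_residues, r.scan_id, r.label_combo, str(int(r.decoy)),
                ]
            )
            + "\n"
        )


def read_results(source: str | Path | TextIO) -> list[ResultRow]:
    """Read back a result TSV written by :func:`write_results`."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_results(fh)
    header = source.readline().rstrip("\n").split("\t")
    if tuple(header) != RESULT_COLUMNS:
        raise ValueError("unrecognized result-table header")
    rows = []
    for line in source:
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        rows.append(
            ResultRow(
                mz=float(f[0]), sequence_1=f[1], sequence_2=f[2],
                calculated_mass=float(f[3]), precursor_mass=float(f[4]),
                charge=int(f[5]), score=float(f[6]), crosslinked_residues=f[7],
                site_residues=f[8], scan_id=f[9], label_combo=f[10],
                decoy=bool(int(f[11])),
            )
        )
    return rows
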