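"""MassBank-format record assembly, serialization, validation and summary.

A record is a flat text file of ``TAG: value`` lines (with ``CH$``, ``AC$``,
``MS$`` and ``PK$`` prefixed blocks) terminated by ``//``.  Internally a
:class:`MassBankRecord` keeps an ordered list of (tag, value) fields plus a
parsed peak table, which makes ``parse(write(r)) == r`` exact and preserves
fields this package does not interpret.

Assembly enforces the library's curation gates: only confirmed (level 1)
assignments are eligible and spectra whose base peak is below 1e5 counts
are rejected.  Peak rows carry m/z (4 decimals), absolute intensity
(integer counts) and relative intensity scaled to 1..999 with the base
peak at 999.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chem
from .annotate import CleanSpectrum
from .isobars import Assignment, LEVEL_CONFIRMED
from .msio import CompoundEntry, Settings
from .splash import splash_ms

__all__ = [
    "MassBankRecord",
    "ValidationReport",
    "RecordRejected",
    "ACCESSION_RE",
    "relative_intensities",
    "compute_splash",
    "build_record",
    "write_record",
    "parse_record",
    "validate_record",
    "summarize_records",
]

ACCESSION_RE = re.compile(r"^MSBNK-[A-Za-z0-9_]+-[A-Za-z0-9_]+$")
BASE_PEAK_MIN = 1e5
FORMAT_VERSION = "2.6"

MANDATORY_TAGS = (
    "ACCESSION",
    "RECORD_TITLE",
    "DATE",
    "AUTHORS",
    "LICENSE",
    "CH$NAME",
    "CH$FORMULA",
    "CH$EXACT_MASS",
    "CH$SMILES",
    "CH$IUPAC",
    "AC$INSTRUMENT",
    "AC$INSTRUMENT_TYPE",
    "AC$MASS_SPECTROMETRY: MS_TYPE",
    "AC$MASS_SPECTROMETRY: ION_MODE",
    "PK$SPLASH",
    "PK$NUM_PEAK",
)


class RecordRejected(ValueError):
    """Spectrum does not meet the record-stage curation gates."""


@dataclass
class MassBankRecord:
    """One MassBank record: ordered metadata fields plus the peak table."""

    fields: List[Tuple[str, str]] = field(default_factory=list)
    peaks: List[Tuple[float, float, int]] = field(default_factory=list)
    # (m/z, intensity, relative intensity)

    def get(self, tag: str) -> Optional[str]:
        for key, value in self.fields:
            if key == tag:
                return value
        return None

    def get_all(self, tag: str) -> List[str]:
        return [value for key, value in self.fields if key == tag]

    def set(self, tag: str, value: str) -> None:
        for i, (key, _) in enumerate(self.fields):
            if key == tag:
                self.fields[i] = (tag, value)
                return
        self.fields.append((tag, value))

    @property
    def accession(self) -> str:
        return self.get("ACCESSION") or ""

    @property
    def splash(self) -> str:
        return self.get("PK$SPLASH") or ""

    @property
    def num_peak(self) -> Optional[int]:
        value = self.get("PK$NUM_PEAK")
        try:
            return int(value) if value is not None else None
        except ValueError:
            return None

    def __eq__(self, other) -> bool:
        if not isinstance(other, MassBankRecord):
            return NotImplemented
        return self.fields == other.fields and self.peaks == other.peaks


def relative_intensities(intensities: Sequence[float]) -> List[int]:
    """Scale to 1..999 with the base peak at 999 (floored at 1)."""
    values = np.asarray(intensities, dtype=float)
    if values.size == 0:
        raise ValueError("empty peak list")
    if np.any(values <= 0):
        raise ValueError("intensities must be positive")
    rel = np.rint(values / values.max() * 999.0).astype(int)
    return [max(1, int(v)) for v in rel]


def compute_splash(peaks: Sequence[Tuple[float, float]]) -> str:
    """SPLASH of an (m/z, intensity) peak list."""
    if not peaks:
        raise ValueError("empty peak list")
    mz = [p[0] for p in peaks]
    intensity = [p[1] for p in peaks]
    return splash_ms(mz, intensity)


def _inchi_of(smiles: str) -> Tuple[str, str]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise RecordRejected(f"unparseable structure {smiles!r}")
    inchi = Chem.MolToInchi(mol) or "N/A"
    key = Chem.InchiToInchiKey(inchi) if inchi != "N/A" else "N/A"
    return inchi, key or "N/A"


def build_record(entry: CompoundEntry, spectrum: CleanSpectrum,
                 assignment: Assignment, settings: Settings, serial: str,
                 adduct="[M+H]+", date: str = "2021.01.28",
                 base_peak_min: Optional[float] = None) -> MassBankRecord:
    """Assemble a record for one confirmed compound spectrum.

    ``serial`` is the contributor-local accession code (e.g. "LU109201").
    Raises :class:`RecordRejected` when the assignment is not level 1 or
    the base peak is below the intensity gate.
    """
    if assignment.level != LEVEL_CONFIRMED:
        raise RecordRejected(
            f"{entry.identifier}: assignment level {assignment.level}, "
            "only confirmed (level 1) spectra are recorded"
        )
    if spectrum.n_peaks == 0:
        raise RecordRejected(f"{entry.identifier}: empty spectrum")
    gate = BASE_PEAK_MIN if base_peak_min is None else base_peak_min
    if spectrum.base_peak_intensity < gate:
        raise RecordRejected(
            f"{entry.identifier}: base peak "
            f"{spectrum.base_peak_intensity:.3g} below {gate:.3g}"
        )
    if not entry.ms_ready_smiles:
        raise RecordRejected(f"{entry.identifier}: missing structure")
    adduct = chem.get_adduct(adduct) if isinstance(adduct, str) else adduct

    accession = f"MSBNK-{settings.contributor}-{serial}"
    ion_mode = "POSITIVE" if adduct.charge > 0 else "NEGATIVE"
    ce_text = (f"{spectrum.collision_energy:g}"
               if spectrum.collision_energy is not None else "")
    inchi, inchikey = _inchi_of(entry.ms_ready_smiles)
    if entry.inchikey:
        inchikey = entry.inchikey

    record = MassBankRecord()
    title_ce = f"; NCE {ce_text}" if ce_text else ""
    record.fields = [
        ("ACCESSION", accession),
        ("RECORD_TITLE",
         f"{entry.name}; {settings.instrument_type}; MS2"
         f"{title_ce}; {adduct.name}"),
        ("DATE", date),
        ("AUTHORS", settings.authors),
        ("LICENSE", settings.license),
    ]
    if settings.publication:
        record.fields.append(("PUBLICATION", settings.publication))
    record.fields.extend([
        ("COMMENT", f"INTERNAL_ID {entry.identifier}"),
        ("COMMENT", f"CONFIDENCE Level {assignment.level} "
                    f"({assignment.rationale})"),
        ("CH$NAME", entry.name),
        ("CH$COMPOUND_CLASS", "N/A; Environmental Standard"),
        ("CH$FORMULA", chem.hill_formula(entry.formula)),
        ("CH$EXACT_MASS", f"{entry.monoisotopic_mass:.4f}"),
        ("CH$SMILES", entry.ms_ready_smiles),
        ("CH$IUPAC", inchi),
        ("CH$LINK", f"INCHIKEY {inchikey}"),
        ("AC$INSTRUMENT", settings.instrument),
        ("AC$INSTRUMENT_TYPE", settings.instrument_type),
        ("AC$MASS_SPECTROMETRY: MS_TYPE", "MS2"),
        ("AC$MASS_SPECTROMETRY: ION_MODE", ion_mode),
        ("AC$MASS_SPECTROMETRY: IONIZATION", settings.ionization),
        ("AC$MASS_SPECTROMETRY: FRAGMENTATION_MODE",
         settings.fragmentation_mode),
    ])
    if ce_text:
        record.fields.append(
            ("AC$MASS_SPECTROMETRY: COLLISION_ENERGY",
             f"{ce_text} % (nominal)"))
    if settings.column_name:
        record.fields.append(
            ("AC$CHROMATOGRAPHY: COLUMN_NAME", settings.column_name))
    if settings.flow_gradient:
        record.fields.append(
            ("AC$CHROMATOGRAPHY: FLOW_GRADIENT", settings.flow_gradient))
    record.fields.extend([
        ("AC$CHROMATOGRAPHY: RETENTION_TIME",
         f"{spectrum.retention_time:.3f} min"),
        ("MS$FOCUSED_ION: PRECURSOR_M/Z", f"{spectrum.precursor_mz:.4f}"),
        ("MS$FOCUSED_ION: PRECURSOR_TYPE", adduct.name),
    ])
    rel = relative_intensities(spectrum.intensity)
    record.peaks = [
        (round(float(mz), 4), float(int(round(inten))), r)
        for mz, inten, r in zip(spectrum.mz, spectrum.intensity, rel)
    ]
    record.fields.append(
        ("PK$SPLASH", compute_splash([(p[0], p[1]) for p in record.peaks])))
    record.fields.append(("PK$NUM_PEAK", str(len(record.peaks))))
    return record


# ---------------------------------------------------------------------------
# Serialization


def write_record(record: MassBankRecord, path=None) -> str:
    """Render to MassBank record text; optionally write to ``path``."""
    lines = [
        (f"{tag} {value}" if ": " in tag else f"{tag}: {value}")
        for tag, value in record.fields
    ]
    lines.append("PK$PEAK: m/z int. rel.int.")
    for mz, inten, rel in record.peaks:
        lines.append(f"  {mz:.4f} {inten:.0f} {rel:d}")
    lines.append("//")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_record(text: str) -> MassBankRecord:
    """Inverse of :func:`write_record`; unknown tags are preserved."""
    record = MassBankRecord()
    lines = text.splitlines()
    if not lines or lines[-1].strip() != "//" and "//" not in [
            ln.strip() for ln in lines]:
        raise ValueError("truncated record: missing // terminator")
    in_peaks = False
    terminated = False
    for line in lines:
        if line.strip() == "//":
            terminated = True
            break
        if in_peaks:
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"malformed peak line {line!r}")
            record.peaks.append(
                (float(parts[0]), float(parts[1]), int(parts[2])))
            continue
        if line.startswith("PK$PEAK:"):
            in_peaks = True
            continue
        if ": " not in line:
            raise ValueError(f"malformed record line {line!r}")
        prefix, value = line.split(": ", 1)
        # subtag blocks keep "TAG: SUBTAG" as the field key
        if prefix in ("AC$MASS_SPECTROMETRY", "AC$CHROMATOGRAPHY",
                      "MS$FOCUSED_ION", "MS$DATA_PROCESSING"):
            subtag, _, rest = value.partition(" ")
            record.fields.append((f"{prefix}: {subtag}", rest))
        else:
            record.fields.append((prefix, value))
    if not terminated:
        raise ValueError("truncated record: missing // terminator")
    return record


def read_record(path) -> MassBankRecord:
    return parse_record(Path(path).read_text())


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    accession: str
    violations: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_record(record: MassBankRecord,
                    mass_tol_ppm: float = 5.0) -> ValidationReport:
    """Pre-submission checks: mandatory fields, accession shape, peak-count
    and sortedness, relative-intensity scale, formula/exact-mass agreement,
    SPLASH format and recomputation."""
    violations: List[str] = []
    for tag in MANDATORY_TAGS:
        if record.get(tag) is None:
            violations.append(f"missing field {tag}")
    accession = record.accession
    if accession and not ACCESSION_RE.match(accession):
        violations.append(f"malformed accession {accession!r}")
    n = record.num_peak
    if n is None:
        violations.append("PK$NUM_PEAK missing or non-integer")
    elif n != len(record.peaks):
        violations.append(
            f"PK$NUM_PEAK {n} != peak list length {len(record.peaks)}")
    mzs = [p[0] for p in record.peaks]
    if any(b < a for a, b in zip(mzs, mzs[1:])):
        violations.append("peaks not sorted by m/z")
    rels = [p[2] for p in record.peaks]
    if rels:
        if min(rels) < 1 or max(rels) > 999:
            violations.append("relative intensities outside 1..999")
        elif max(rels) != 999:
            violations.append("base peak relative intensity != 999")
    formula = record.get("CH$FORMULA")
    exact = record.get("CH$EXACT_MASS")
    if formula and exact:
        try:
            mass = chem.monoisotopic_mass(chem.parse_formula(formula))
            stated = float(exact)
            if mass > 0 and abs(stated - mass) / mass * 1e6 > mass_tol_ppm:
                violations.append(
                    f"CH$EXACT_MASS {stated} inconsistent with "
                    f"CH$FORMULA {formula} ({mass:.4f})")
        except (ValueError, chem.FormulaError) as exc:
            violations.append(f"formula/mass check failed: {exc}")
    stated_splash = record.splash
    if record.peaks and stated_splash:
        expected = compute_splash([(p[0], p[1]) for p in record.peaks])
        if stated_splash != expected:
            violations.append("PK$SPLASH does not match the peak list")
    return ValidationReport(accession=accession, violations=violations)


# ---------------------------------------------------------------------------
# Summary


def summarize_records(directory, fields: Sequence[str]) -> pd.DataFrame:
    """One row per record file in ``directory``, one column per requested
    field (missing fields are empty); mirrors a record-summary CSV export."""
    directory = Path(directory)
    rows = []
    for path in sorted(directory.glob("*.txt")):
        record = read_record(path)
        row: Dict[str, str] = {"file": path.name}
        for tag in fields:
            values = record.get_all(tag)
            row[tag] = "; ".join(values)
        rows.append(row)
    return pd.DataFrame(rows, columns=["file", *fields])
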