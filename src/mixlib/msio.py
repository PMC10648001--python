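"""Data contracts and readers/writers for runs, compound lists, set maps
and acquisition settings.

mzML reading and writing use a compact mzML 1.1.0 implementation in this
module (centroid spectra; base64 binary arrays, 32/64-bit, zlib or
uncompressed on read) covering the fields this pipeline uses: ms level,
retention time, polarity, peak lists, and for MS2 the precursor m/z,
isolation window, and collision energy.

Retention times are normalized to minutes internally regardless of the
unit attribute in the file.  When an MS2 scan carries no isolation window,
a 1 Da default is assumed (quadrupole isolation of the acquisition this
package models).
"""

from __future__ import annotations

import base64
import configparser
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import chem

__all__ = [
    "Scan",
    "Run",
    "CompoundEntry",
    "MixDesign",
    "Settings",
    "read_run",
    "write_run",
    "read_compound_list",
    "read_setid",
    "read_settings",
    "write_settings",
]

DEFAULT_ISOLATION_WIDTH = 1.0  # Da


class MsDataError(ValueError):
    """Input file violates the data contract."""


@dataclass
class Scan:
    """One centroided mass spectrum.

    ``mz`` / ``intensity`` are parallel arrays sorted by ascending m/z.
    MS2 scans carry precursor metadata; ``collision_energy`` is a nominal
    (normalized) collision energy, unitless.
    """

    ms_level: int
    retention_time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "+"
    precursor_mz: Optional[float] = None
    isolation_window_width: Optional[float] = None
    collision_energy: Optional[float] = None
    scan_id: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise MsDataError("m/z and intensity arrays differ in length")
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise MsDataError("negative intensity")
        if self.retention_time < 0:
            raise MsDataError("negative retention time")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise MsDataError("MS2 scan without precursor m/z")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class Run:
    """An ordered collection of scans from one mix / mode / CE acquisition."""

    scans: List[Scan]
    mix: str = ""
    mode: str = "+"
    collision_energy: Optional[float] = None

    def __post_init__(self):
        rts = [s.retention_time for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.scans = sorted(self.scans, key=lambda s: s.retention_time)
        pols = {s.polarity for s in self.scans}
        if len(pols) > 1:
            raise MsDataError("mixed polarity within one run")

    def __len__(self) -> int:
        return len(self.scans)

    def ms1_scans(self) -> List[Scan]:
        return [s for s in self.scans if s.ms_level == 1]

    def ms2_scans(self) -> List[Scan]:
        return [s for s in self.scans if s.ms_level == 2]


# ---------------------------------------------------------------------------
# mzML reading


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _iter_cv_params(element) -> Dict[str, Tuple[str, str]]:
    """Accession -> (name, value, unitName) for direct cvParam children."""
    params = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            params[child.get("accession")] = (
                child.get("name", ""), child.get("value", ""),
                child.get("unitName", ""))
    return params


def _decode_binary_array(ba_element) -> np.ndarray:
    import zlib

    params = _iter_cv_params(ba_element)
    dtype = "<f8" if "MS:1000523" in params else "<f4"
    compressed = "MS:1000574" in params  # zlib compression
    text = ""
    for child in ba_element:
        if _local(child.tag) == "binary":
            text = child.text or ""
    data = base64.b64decode(text)
    if compressed:
        data = zlib.decompress(data)
    return np.frombuffer(data, dtype=dtype).astype(float)


def _parse_spectrum(spec, filename: str) -> Scan:
    params = _iter_cv_params(spec)
    if "MS:1000128" in params:
        raise MsDataError(f"{filename}: profile-mode spectrum; centroid required")
    level = int(params.get("MS:1000511", ("", "1", ""))[1] or 1)
    pol = "-" if "MS:1000129" in params else "+"
    rt = None
    prec_mz = None
    iso_width = None
    ce = None
    mz = intensity = None
    for child in spec.iter():
        tag = _local(child.tag)
        if tag == "scan":
            scan_params = _iter_cv_params(child)
            if "MS:1000016" in scan_params:
                _, value, unit = scan_params["MS:1000016"]
                rt = float(value)
                if unit.lower() in ("second", "seconds", "s"):
                    rt /= 60.0
        elif tag == "precursor":
            lo = hi = None
            for sub in child.iter():
                stag = _local(sub.tag)
                if stag == "isolationWindow":
                    iso = _iter_cv_params(sub)
                    if "MS:1000828" in iso:
                        lo = float(iso["MS:1000828"][1])
                    if "MS:1000829" in iso:
                        hi = float(iso["MS:1000829"][1])
                elif stag == "selectedIon":
                    ion = _iter_cv_params(sub)
                    if "MS:1000744" in ion:
                        prec_mz = float(ion["MS:1000744"][1])
                elif stag == "activation":
                    act = _iter_cv_params(sub)
                    for acc in ("MS:1000138", "MS:1000045"):
                        if acc in act:
                            ce = float(act[acc][1])
                            break
            if lo is not None and hi is not None:
                iso_width = lo + hi
        elif tag == "binaryDataArray":
            array_params = _iter_cv_params(child)
            if "MS:1000514" in array_params:
                mz = _decode_binary_array(child)
            elif "MS:1000515" in array_params:
                intensity = _decode_binary_array(child)
    if rt is None:
        raise MsDataError(f"{filename}: scan without start time")
    if mz is None or intensity is None:
        mz = np.zeros(0) if mz is None else mz
        intensity = np.zeros(0) if intensity is None else intensity
    if level >= 2:
        if prec_mz is None:
            raise MsDataError(f"{filename}: MS2 scan without precursor m/z")
        if iso_width is None:
            iso_width = DEFAULT_ISOLATION_WIDTH
    return Scan(
        ms_level=level, retention_time=rt, mz=mz, intensity=intensity,
        polarity=pol, precursor_mz=prec_mz,
        isolation_window_width=iso_width, collision_energy=ce,
        scan_id=spec.get("id", ""),
    )


def read_run(path, mix: str = "", mode: str = "",
             collision_energy: Optional[float] = None) -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    Profile-mode spectra and MS2 scans lacking precursor information are
    rejected; intensities are preserved exactly as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scans: List[Scan] = []
    for event, element in ET.iterparse(str(path), events=("end",)):
        if _local(element.tag) == "spectrum":
            scans.append(_parse_spectrum(element, path.name))
            element.clear()
    if not scans:
        raise MsDataError(f"{path.name}: no spectra")
    return Run(scans=scans, mix=mix, mode=mode or scans[0].polarity,
               collision_energy=collision_energy)


# ---------------------------------------------------------------------------
# mzML writing (minimal 1.1.0 serializer)


def _encode_array(values: np.ndarray) -> str:
    data = struct.pack(f"<{values.size}d", *map(float, values))
    return base64.b64encode(data).decode("ascii")


def _cv(parent, accession, name, value="", unit=None):
    el = ET.SubElement(parent, "cvParam", cvRef="MS", accession=accession,
                       name=name, value=str(value))
    if unit:
        el.set("unitCvRef", "UO")
        el.set("unitAccession", unit[0])
        el.set("unitName", unit[1])
    return el


def write_run(run: Run, path) -> Path:
    """Serialize a :class:`Run` to minimal centroid mzML readable by
    pyteomics (and other HUPO-PSI mzML readers)."""
    path = Path(path)
    root = ET.Element(
        "mzML", xmlns="http://psi.hupo.org/ms/mzml", version="1.1.0")
    cvlist = ET.SubElement(root, "cvList", count="2")
    ET.SubElement(cvlist, "cv", id="MS",
                  fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
                  URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    ET.SubElement(cvlist, "cv", id="UO", fullName="Unit Ontology",
                  URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo")
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    slist = ET.SubElement(root, "softwareList", count="1")
    ET.SubElement(slist, "software", id="mixlib", version="0.1.0")
    iclist = ET.SubElement(root, "instrumentConfigurationList", count="1")
    ET.SubElement(iclist, "instrumentConfiguration", id="IC1")
    dplist = ET.SubElement(root, "dataProcessingList", count="1")
    dp = ET.SubElement(dplist, "dataProcessing", id="DP1")
    pm = ET.SubElement(dp, "processingMethod", order="0", softwareRef="mixlib")
    _cv(pm, "MS:1000544", "Conversion to mzML")
    mzml_run = ET.SubElement(root, "run", id=run.mix or "run",
                             defaultInstrumentConfigurationRef="IC1")
    speclist = ET.SubElement(mzml_run, "spectrumList",
                             count=str(len(run.scans)),
                             defaultDataProcessingRef="DP1")
    for i, scan in enumerate(run.scans):
        spec = ET.SubElement(
            speclist, "spectrum", index=str(i),
            id=scan.scan_id or f"scan={i + 1}",
            defaultArrayLength=str(scan.n_peaks))
        _cv(spec, "MS:1000511", "ms level", scan.ms_level)
        if scan.ms_level == 1:
            _cv(spec, "MS:1000579", "MS1 spectrum")
        else:
            _cv(spec, "MS:1000580", "MSn spectrum")
        _cv(spec, "MS:1000127", "centroid spectrum")
        if scan.polarity == "-":
            _cv(spec, "MS:1000129", "negative scan")
        else:
            _cv(spec, "MS:1000130", "positive scan")
        scan_list = ET.SubElement(spec, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        sc = ET.SubElement(scan_list, "scan")
        _cv(sc, "MS:1000016", "scan start time",
            repr(scan.retention_time), unit=("UO:0000031", "minute"))
        if scan.ms_level == 2:
            plist = ET.SubElement(spec, "precursorList", count="1")
            prec = ET.SubElement(plist, "precursor")
            width = scan.isolation_window_width
            if width is None:
                width = DEFAULT_ISOLATION_WIDTH
            iso = ET.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z",
                repr(scan.precursor_mz), unit=("MS:1000040", "m/z"))
            _cv(iso, "MS:1000828", "isolation window lower offset",
                repr(width / 2.0), unit=("MS:1000040", "m/z"))
            _cv(iso, "MS:1000829", "isolation window upper offset",
                repr(width / 2.0), unit=("MS:1000040", "m/z"))
            silist = ET.SubElement(prec, "selectedIonList", count="1")
            si = ET.SubElement(silist, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z",
                repr(scan.precursor_mz), unit=("MS:1000040", "m/z"))
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000422",
                "beam-type collision-induced dissociation")
            if scan.collision_energy is not None:
                _cv(act, "MS:1000045", "collision energy",
                    repr(scan.collision_energy),
                    unit=("UO:0000266", "electronvolt"))
        balist = ET.SubElement(spec, "binaryDataArrayList", count="2")
        for accession, name, values, unit in (
            ("MS:1000514", "m/z array", scan.mz, ("MS:1000040", "m/z")),
            ("MS:1000515", "intensity array", scan.intensity,
             ("MS:1000131", "number of detector counts")),
        ):
            encoded = _encode_array(values)
            ba = ET.SubElement(balist, "binaryDataArray",
                               encodedLength=str(len(encoded)))
            _cv(ba, "MS:1000523", "64-bit float")
            _cv(ba, "MS:1000576", "no compression")
            _cv(ba, accession, name, unit=unit)
            ET.SubElement(ba, "binary").text = encoded
    tree = ET.ElementTree(root)
    ET.indent(tree, space=" ")
    tree.write(path, xml_declaration=True, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Compound list / setID / settings


@dataclass
class CompoundEntry:
    """A screenable chemical from the compound list."""

    identifier: str
    name: str
    ms_ready_smiles: str
    formula: chem.ElementCounts = field(default_factory=dict)
    monoisotopic_mass: float = 0.0
    original_smiles: Optional[str] = None
    inchikey: Optional[str] = None

    @classmethod
    def from_smiles(cls, identifier: str, name: str, smiles: str,
                    original_smiles: Optional[str] = None,
                    inchikey: Optional[str] = None) -> "CompoundEntry":
        counts = chem.formula_of_smiles(smiles)
        return cls(
            identifier=identifier, name=name, ms_ready_smiles=smiles,
            formula=counts,
            monoisotopic_mass=chem.monoisotopic_mass(counts),
            original_smiles=original_smiles, inchikey=inchikey,
        )

    def ion_mz(self, adduct, electron_correction: bool = True) -> float:
        return chem.adduct_mz(self.monoisotopic_mass, adduct,
                              electron_correction=electron_correction)


#: Accepted header aliases (lower-cased) for the compound list CSV.
COMPOUND_COLUMN_ALIASES = {
    "identifier": ("identifier", "id"),
    "name": ("name", "preferred_name", "compound"),
    "smiles": ("smiles", "ms_ready_smiles", "msready_smiles"),
    "original_smiles": ("original_smiles", "mixture_smiles"),
    "inchikey": ("inchikey",),
}


def _find_column(df: pd.DataFrame, aliases: Sequence[str]) -> Optional[str]:
    lowered = {c.lower(): c for c in df.columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    return None


def read_compound_list(path, aliases: Dict[str, Sequence[str]] = None
                       ) -> Tuple[List[CompoundEntry], List[str]]:
    """Read the compound list CSV.

    Returns ``(entries, problems)`` where ``problems`` collects messages for
    rows skipped because of unparseable SMILES.  Duplicate identifiers are
    an error.
    """
    aliases = {**COMPOUND_COLUMN_ALIASES, **(aliases or {})}
    df = pd.read_csv(path, dtype=str).fillna("")
    cols = {key: _find_column(df, names) for key, names in aliases.items()}
    for required in ("identifier", "name", "smiles"):
        if cols[required] is None:
            raise MsDataError(
                f"compound list missing a {required} column "
                f"(accepted: {aliases[required]})"
            )
    dupes = df[cols["identifier"]][df[cols["identifier"]].duplicated()]
    if len(dupes):
        raise MsDataError(
            "duplicate compound identifiers: " + ", ".join(sorted(set(dupes)))
        )
    entries: List[CompoundEntry] = []
    problems: List[str] = []
    for _, row in df.iterrows():
        ident = row[cols["identifier"]].strip()
        smiles = row[cols["smiles"]].strip()
        try:
            entry = CompoundEntry.from_smiles(
                ident, row[cols["name"]].strip(), smiles,
                original_smiles=(row[cols["original_smiles"]].strip() or None
                                 if cols["original_smiles"] else None),
                inchikey=(row[cols["inchikey"]].strip() or None
                          if cols["inchikey"] else None),
            )
        except ValueError as exc:
            problems.append(f"{ident}: {exc}")
            continue
        entries.append(entry)
    return entries, problems


@dataclass
class MixDesign:
    """Map from mix name to the identifiers it contains."""

    mixes: Dict[str, Set[str]] = field(default_factory=dict)

    def compounds_in(self, mix: str) -> Set[str]:
        return self.mixes.get(mix, set())

    def mixes_of(self, identifier: str) -> List[str]:
        return sorted(m for m, ids in self.mixes.items() if identifier in ids)

    def all_identifiers(self) -> Set[str]:
        out: Set[str] = set()
        for ids in self.mixes.values():
            out |= ids
        return out


SETID_COLUMN_ALIASES = {
    "identifier": ("identifier", "id"),
    "mix": ("mix", "set", "set_name", "mix_name"),
}


def read_setid(path, compounds: Optional[Sequence[CompoundEntry]] = None
               ) -> MixDesign:
    """Read the setID CSV (identifier -> mix name).

    When ``compounds`` is given, identifiers absent from the compound list
    are an error (dangling references).  An empty file yields an empty
    design.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    cols = {k: _find_column(df, v) for k, v in SETID_COLUMN_ALIASES.items()}
    for required in ("identifier", "mix"):
        if cols[required] is None:
            raise MsDataError(f"setID file missing a {required} column")
    design = MixDesign()
    for _, row in df.iterrows():
        ident = row[cols["identifier"]].strip()
        mix = row[cols["mix"]].strip()
        if not ident or not mix:
            continue
        design.mixes.setdefault(mix, set()).add(ident)
    if compounds is not None:
        known = {c.identifier for c in compounds}
        dangling = sorted(design.all_identifiers() - known)
        if dangling:
            raise MsDataError(
                "setID references unknown identifiers: " + ", ".join(dangling)
            )
    return design


ALLOWED_LICENSES = ("CC0", "CC BY", "CC BY-SA", "CC BY-NC", "CC BY-NC-SA")

MANDATORY_SETTINGS = (
    "authors", "license", "instrument", "instrument_type", "ionization",
    "contributor",
)


@dataclass
class Settings:
    """Acquisition and record metadata from the settings INI."""

    authors: str
    license: str
    instrument: str
    instrument_type: str
    ionization: str
    contributor: str
    accession_prefix: str = "LU"
    fragmentation_mode: str = "HCD"
    column_name: str = ""
    flow_gradient: str = ""
    publication: str = ""
    base_peak_min: float = 1e5

    def __post_init__(self):
        if not self.contributor:
            raise MsDataError("contributor code must be non-empty")
        if self.license not in ALLOWED_LICENSES:
            raise MsDataError(
                f"license {self.license!r} not in {ALLOWED_LICENSES}"
            )


def read_settings(path) -> Settings:
    """Read the settings INI (a ``[record]`` section with metadata keys)."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(path)
    if "record" not in parser:
        raise MsDataError("settings file lacks a [record] section")
    section = parser["record"]
    missing = [k for k in MANDATORY_SETTINGS if not section.get(k)]
    if missing:
        raise MsDataError("settings missing keys: " + ", ".join(missing))
    return Settings(
        authors=section["authors"],
        license=section["license"],
        instrument=section["instrument"],
        instrument_type=section["instrument_type"],
        ionization=section["ionization"],
        contributor=section["contributor"],
        accession_prefix=section.get("accession_prefix", "LU"),
        fragmentation_mode=section.get("fragmentation_mode", "HCD"),
        column_name=section.get("column_name", ""),
        flow_gradient=section.get("flow_gradient", ""),
        publication=section.get("publication", ""),
        base_peak_min=float(section.get("base_peak_min", "1e5")),
    )


def write_settings(settings: Settings, path) -> Path:
    parser = configparser.ConfigParser()
    parser["record"] = {
        "authors": settings.authors,
        "license": settings.license,
        "instrument": settings.instrument,
        "instrument_type": settings.instrument_type,
        "ionization": settings.ionization,
        "contributor": settings.contributor,
        "accession_prefix": settings.accession_prefix,
        "fragmentation_mode": settings.fragmentation_mode,
        "column_name": settings.column_name,
        "flow_gradient": settings.flow_gradient,
        "publication": settings.publication,
        "base_peak_min": repr(settings.base_peak_min),
    }
    path = Path(path)
    with open(path, "w") as handle:
        parser.write(handle)
    return path
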