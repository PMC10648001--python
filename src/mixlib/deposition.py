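"""PubChem deposition artifacts from a record collection.

Two projections are produced: an MS/MS annotation table (one row per
record, the agreed display fields plus the Top-5 peaks) and a substance
table holding the structure fields (name, SMILES, InChI, InChIKey) after
clean-up: "N/A" structures, wildcard SMILES, bad-list SMILES and duplicate
structure triples are removed, with per-reason removal counts that balance
the input row count.  A mapping entry ties the annotation file version to
the deposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .records import MassBankRecord

__all__ = [
    "DEPOSITION_FIELDS",
    "DepositionRow",
    "BadList",
    "top5_peaks",
    "extract_fields",
    "build_substance_table",
    "build_annotation_table",
]

#: The agreed display fields, in deposition order.
DEPOSITION_FIELDS = [
    "Accession ID",
    "Authors",
    "Instrument",
    "Instrument Type",
    "MS Level",
    "Ionization Mode",
    "Ionization",
    "Collision Energy",
    "Fragmentation Mode",
    "Column Name",
    "Retention Time",
    "Precursor m/z",
    "Precursor Adduct",
    "License",
    "Publication",
    "SPLASH",
    "Top-5 Peaks",
    "Name",
    "SMILES",
    "InChI",
    "InChIKey",
]

#: Fields rendered as hyperlinks on the compound page.
LINK_FIELDS = ("Accession ID", "SPLASH")

_RECORD_TAG_OF = {
    "Accession ID": "ACCESSION",
    "Authors": "AUTHORS",
    "Instrument": "AC$INSTRUMENT",
    "Instrument Type": "AC$INSTRUMENT_TYPE",
    "MS Level": "AC$MASS_SPECTROMETRY: MS_TYPE",
    "Ionization Mode": "AC$MASS_SPECTROMETRY: ION_MODE",
    "Ionization": "AC$MASS_SPECTROMETRY: IONIZATION",
    "Collision Energy": "AC$MASS_SPECTROMETRY: COLLISION_ENERGY",
    "Fragmentation Mode": "AC$MASS_SPECTROMETRY: FRAGMENTATION_MODE",
    "Column Name": "AC$CHROMATOGRAPHY: COLUMN_NAME",
    "Retention Time": "AC$CHROMATOGRAPHY: RETENTION_TIME",
    "Precursor m/z": "MS$FOCUSED_ION: PRECURSOR_M/Z",
    "Precursor Adduct": "MS$FOCUSED_ION: PRECURSOR_TYPE",
    "License": "LICENSE",
    "Publication": "PUBLICATION",
    "SPLASH": "PK$SPLASH",
    "Name": "CH$NAME",
    "SMILES": "CH$SMILES",
    "InChI": "CH$IUPAC",
}


@dataclass
class DepositionRow:
    """Flattened record projection; field set matches the agreed list."""

    values: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - set(DEPOSITION_FIELDS)
        if unknown:
            raise ValueError(f"unexpected deposition fields: {sorted(unknown)}")
        for key in DEPOSITION_FIELDS:
            self.values.setdefault(key, "")

    def __getitem__(self, key: str) -> str:
        return self.values[key]


@dataclass
class BadList:
    """SMILES excluded from deposition (exact string membership)."""

    smiles: Set[str] = field(default_factory=set)

    @classmethod
    def from_file(cls, path) -> "BadList":
        lines = Path(path).read_text().splitlines()
        return cls({ln.strip() for ln in lines
                    if ln.strip() and not ln.startswith("#")})

    def __contains__(self, value: str) -> bool:
        return value in self.smiles


def top5_peaks(peaks: Sequence[Tuple[float, float]]) -> List[Tuple[float, float]]:
    """The five highest-intensity peaks, in descending intensity; intensity
    ties keep the lower m/z first."""
    ordered = sorted(peaks, key=lambda p: (-p[1], p[0]))
    return list(ordered[:5])


def _format_top5(peaks: Sequence[Tuple[float, float, int]]) -> str:
    top = top5_peaks([(mz, rel) for mz, _, rel in peaks])
    return ";".join(f"{mz:.4f}:{int(rel)}" for mz, rel in top)


def extract_fields(record: MassBankRecord) -> DepositionRow:
    """Project one record onto the agreed deposition fields; missing
    optional fields stay empty."""
    values: Dict[str, str] = {}
    for display, tag in _RECORD_TAG_OF.items():
        if display == "Name":
            names = record.get_all(tag)
            values[display] = names[0] if names else ""
        else:
            values[display] = record.get(tag) or ""
    for link in record.get_all("CH$LINK"):
        if link.startswith("INCHIKEY "):
            values["InChIKey"] = link.split(" ", 1)[1]
    values.setdefault("InChIKey", "")
    values["Top-5 Peaks"] = _format_top5(record.peaks)
    return DepositionRow(values=values)


_STRUCTURE_TRIPLE = ("SMILES", "InChI", "InChIKey")


def _normalize(value: str) -> str:
    return " ".join(value.split())


def build_substance_table(rows: Sequence[DepositionRow],
                          badlist: Optional[BadList] = None
                          ) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Cleaned substance table plus per-reason removal counts.

    Reasons, applied in order per row: ``na`` ("N/A" or empty structure),
    ``wildcard`` ('*' atom in SMILES), ``badlist``, ``duplicate`` (repeat
    of a structure triple already kept).  The counts plus the output length
    equal the input length.
    """
    badlist = badlist or BadList()
    counts = {"na": 0, "wildcard": 0, "badlist": 0, "duplicate": 0}
    seen: Set[Tuple[str, str, str]] = set()
    kept = []
    for row in rows:
        smiles = _normalize(row["SMILES"])
        triple = tuple(_normalize(row[k]) for k in _STRUCTURE_TRIPLE)
        if smiles in ("", "N/A") or any(v == "N/A" for v in triple):
            counts["na"] += 1
            continue
        if "*" in smiles:
            counts["wildcard"] += 1
            continue
        if smiles in badlist:
            counts["badlist"] += 1
            continue
        if triple in seen:
            counts["duplicate"] += 1
            continue
        seen.add(triple)
        kept.append({
            "Name": row["Name"],
            "SMILES": smiles,
            "InChI": triple[1],
            "InChIKey": triple[2],
            "Accession ID": row["Accession ID"],
        })
    df = pd.DataFrame(
        kept, columns=["Name", "SMILES", "InChI", "InChIKey", "Accession ID"])
    return df, counts


def build_annotation_table(rows: Sequence[DepositionRow],
                           version: str = "v1"
                           ) -> Tuple[pd.DataFrame, Optional[Dict[str, str]]]:
    """MS/MS annotation table (one row per record) and the mapping entry
    naming the annotation file version; empty input yields no mapping."""
    df = pd.DataFrame([row.values for row in rows],
                      columns=DEPOSITION_FIELDS)
    if df.empty:
        return df, None
    mapping = {
        "annotation_file": f"massbank_annotations_{version}.csv",
        "version": version,
        "rows": str(len(df)),
    }
    return df, mapping
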