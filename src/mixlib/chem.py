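"""Elemental formulas, monoisotopic masses, adduct arithmetic and MS-ready
structure handling.

The mass table is pinned to IUPAC monoisotopic (most abundant isotope)
masses so that every derived quantity in the package is bit-stable across
environments.  Ion m/z values include the electron mass by default, which is
the convention appropriate for Orbitrap-accurate data; a flag disables it
for comparisons against legacy software that ignores the electron.

Structure handling follows the "MS-ready" convention used for screening
known mixtures: the instrument observes a neutral, desalted form of the
substance, so counter-ions are dropped, formal charges neutralized and
stereo descriptors stripped.  Because stereo-stripped SMILES are often not
the registered database form, :func:`restore_stereo` reinstates the stereo
descriptors of the matching component of the original (salt/mixture) SMILES
onto the MS-ready skeleton.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "MONOISOTOPIC_MASS",
    "Adduct",
    "ADDUCTS",
    "StructureRecord",
    "parse_formula",
    "hill_formula",
    "monoisotopic_mass",
    "formula_of_smiles",
    "get_adduct",
    "adduct_mz",
    "ion_formula",
    "rdbe",
    "ms_ready",
    "restore_stereo",
]

#: Monoisotopic mass of the most abundant isotope, Da (IUPAC/CODATA).
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "Mg": 23.9850417,
    "Al": 26.98153863,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Cr": 51.9405075,
    "Mn": 54.9380451,
    "Fe": 55.9349375,
    "Co": 58.9331950,
    "Ni": 57.9353429,
    "Cu": 62.9295975,
    "Zn": 63.9291422,
    "As": 74.9215965,
    "Se": 79.9165213,
    "Br": 78.9183371,
    "Sn": 119.9021947,
    "I": 126.904473,
    "Hg": 201.970643,
    "Pb": 207.9766521,
}

ELECTRON_MASS = 0.000548579909  # Da
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.007276 Da

#: Ring-plus-double-bond valences (standard bonding states).
_RDBE_VALENCE = {
    "H": 1, "D": 1, "F": 1, "Cl": 1, "Br": 1, "I": 1, "Na": 1, "K": 1,
    "C": 4, "Si": 4, "Sn": 4,
    "N": 3, "P": 3, "B": 3, "As": 3, "Al": 3,
    "O": 2, "S": 2, "Se": 2,
}

ElementCounts = Dict[str, int]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed or chemically invalid formula string."""


def parse_formula(formula: str) -> ElementCounts:
    """Parse a molecular formula like ``"C10H13NO"`` into element counts.

    Counts accumulate over repeated symbols.  Unknown element symbols and
    malformed counts raise :class:`FormulaError`.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula")
    text = formula.strip()
    counts: ElementCounts = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {formula!r} at position {pos}")
        sym, num = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {sym!r} in {formula!r}")
        if num == "":
            n = 1
        else:
            n = int(num)
            if n == 0:
                raise FormulaError(f"zero count for {sym!r} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return counts


def hill_formula(counts: Mapping[str, int]) -> str:
    """Serialize element counts in Hill order (C, H, then alphabetical)."""
    items = {k: v for k, v in counts.items() if v}
    for sym, n in items.items():
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {sym!r}")
        if n < 0:
            raise FormulaError(f"negative count for {sym!r}")
    symbols = sorted(items)
    if "C" in items:
        symbols = ["C"] + (["H"] if "H" in items else []) + [
            s for s in symbols if s not in ("C", "H")
        ]
    return "".join(s + (str(items[s]) if items[s] > 1 else "") for s in symbols)


def monoisotopic_mass(counts: Mapping[str, int]) -> float:
    """Sum of most-abundant-isotope masses over the element counts, Da."""
    total = 0.0
    for sym, n in counts.items():
        if n < 0:
            raise FormulaError(f"negative count for {sym!r}")
        try:
            total += MONOISOTOPIC_MASS[sym] * n
        except KeyError:
            raise FormulaError(f"unknown element symbol {sym!r}") from None
    return total


def rdbe(counts: Mapping[str, int]) -> float:
    """Ring-plus-double-bond equivalents of a formula.

    RDBE = 1 + sum_i n_i (v_i - 2) / 2 over standard valences; half-integer
    values occur for ions / radicals.
    """
    total = 1.0
    for sym, n in counts.items():
        if n:
            total += n * (_RDBE_VALENCE.get(sym, 2) - 2) / 2.0
    return total


# ---------------------------------------------------------------------------
# Adducts


@dataclass(frozen=True)
class Adduct:
    """An ionization adduct: atoms gained/lost and the resulting charge."""

    name: str
    delta: Mapping[str, int]  # element -> signed count added to M
    charge: int

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")

    @property
    def polarity(self) -> str:
        return "+" if self.charge > 0 else "-"

    @property
    def delta_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[s] * n for s, n in self.delta.items())


ADDUCTS: Dict[str, Adduct] = {
    a.name: a
    for a in [
        Adduct("[M+H]+", {"H": 1}, +1),
        Adduct("[M+Na]+", {"Na": 1}, +1),
        Adduct("[M+K]+", {"K": 1}, +1),
        Adduct("[M+NH4]+", {"N": 1, "H": 4}, +1),
        Adduct("[M]+", {}, +1),
        Adduct("[M-H]-", {"H": -1}, -1),
        Adduct("[M+Cl]-", {"Cl": 1}, -1),
        Adduct("[M+HCOO]-", {"C": 1, "H": 1, "O": 2}, -1),
        Adduct("[M]-", {}, -1),
    ]
}


def get_adduct(name: str) -> Adduct:
    """Look up an adduct by name; unicode minus signs are normalized."""
    key = name.replace("−", "-").replace("–", "-")
    try:
        return ADDUCTS[key]
    except KeyError:
        raise KeyError(f"unknown adduct {name!r}") from None


def adduct_mz(neutral_mass: float, adduct: Adduct | str,
              electron_correction: bool = True) -> float:
    """m/z of the adduct ion of a neutral of the given monoisotopic mass.

    ``(M + delta - z * m_e) / |z|`` with the electron-mass term controlled
    by ``electron_correction``.
    """
    if neutral_mass < 0:
        raise ValueError("neutral mass must be non-negative")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    mass = neutral_mass + adduct.delta_mass
    if electron_correction:
        mass -= adduct.charge * ELECTRON_MASS
    return mass / abs(adduct.charge)


def ion_formula(counts: Mapping[str, int], adduct: Adduct | str) -> ElementCounts:
    """Element counts of the adduct ion (e.g. M+H for ``[M+H]+``)."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    out: ElementCounts = {k: v for k, v in counts.items() if v}
    for sym, n in adduct.delta.items():
        out[sym] = out.get(sym, 0) + n
        if out[sym] < 0:
            raise FormulaError(
                f"adduct {adduct.name} removes more {sym} than present"
            )
        if out[sym] == 0:
            del out[sym]
    return out


def formula_of_smiles(smiles: str) -> ElementCounts:
    """Element counts of a (neutral) structure given as SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    counts: ElementCounts = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# MS-ready structures


class StructureError(ValueError):
    """SMILES cannot be parsed or processed into the requested form."""


def _strip_stereo_canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def _neutralize(mol: "Chem.Mol") -> "Chem.Mol":
    uncharger = rdMolStandardize.Uncharger()
    return uncharger.uncharge(mol)


def _largest_organic_fragment(smiles: str) -> "Chem.Mol":
    """Pick the component with the most heavy atoms among those containing
    carbon; ties broken by mass, then canonical SMILES order."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [f for f in frags
               if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
    if not organic:
        raise StructureError(f"no organic component in {smiles!r}")
    return max(
        organic,
        key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.ExactMolWt(f),
                       Chem.MolToSmiles(f)),
    )


def ms_ready(original_smiles: str) -> str:
    """MS-ready form of a structure: largest organic component, neutralized,
    stereo stripped; returned as canonical SMILES.

    Charges that cannot be neutralized (e.g. quaternary nitrogen) are
    retained; callers can detect them via ``Chem.GetFormalCharge``.
    """
    frag = _largest_organic_fragment(original_smiles)
    frag = _neutralize(frag)
    Chem.RemoveStereochemistry(frag)
    return Chem.MolToSmiles(frag)


def restore_stereo(ms_ready_smiles: str, original_mixture_smiles: str) -> str:
    """Reinstate the original stereochemistry on an MS-ready skeleton.

    Finds the component of ``original_mixture_smiles`` whose neutralized,
    stereo-stripped constitution canonically equals ``ms_ready_smiles`` and
    returns that component, neutralized but with stereo descriptors kept.
    """
    target = _strip_stereo_canonical(ms_ready_smiles)
    mol = Chem.MolFromSmiles(original_mixture_smiles)
    if mol is None:
        raise StructureError(
            f"unparseable SMILES {original_mixture_smiles!r}"
        )
    for frag in Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True):
        neutral = _neutralize(frag)
        skeleton = Chem.Mol(neutral)
        Chem.RemoveStereochemistry(skeleton)
        if Chem.MolToSmiles(skeleton) == target:
            return Chem.MolToSmiles(neutral)
    raise StructureError(
        "no component of the original SMILES matches the MS-ready constitution"
    )


@dataclass
class StructureRecord:
    """Original, MS-ready and stereo-restored forms of one substance."""

    original: str
    ms_ready: str
    restored: str
    inchikey: Optional[str] = None

    @classmethod
    def from_original(cls, original_smiles: str,
                      inchikey: Optional[str] = None) -> "StructureRecord":
        ready = ms_ready(original_smiles)
        restored = restore_stereo(ready, original_smiles)
        return cls(original=original_smiles, ms_ready=ready,
                   restored=restored, inchikey=inchikey)
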