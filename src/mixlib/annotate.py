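"""Fragment sub-formula annotation, m/z recalibration and spectrum cleanup.

Every centroid of a matched MS2 spectrum is assigned the sub-formulas of
the precursor *ion* formula (e.g. C10H14NO for the [M+H]+ ion of C10H13NO)
whose theoretical ion m/z lies within a ppm tolerance; a peak with no
candidate is a "failpeak".  Annotation runs twice: once at a wide
pre-recalibration tolerance (default 10 ppm), then the observed-vs-
theoretical m/z pairs of the assigned peaks train a smooth error-curve
model which is applied to the spectra before re-annotation at the final
screening tolerance (default 2.5 ppm).

The error model is a LOWESS fit of error (ppm) against observed m/z
(span 0.75) with a straight-line fallback below 20 training pairs;
predictions outside the fitted m/z range are clamped to the boundary
values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import chem
from .chem import ELECTRON_MASS
from .msio import CompoundEntry, Scan

__all__ = [
    "FormulaCandidate",
    "AnnotatedPeak",
    "RecalModel",
    "CleanPolicy",
    "CleanSpectrum",
    "PRE_RECAL_PPM",
    "POST_RECAL_PPM",
    "ion_mz_of_formula",
    "enumerate_subformulas",
    "annotate_spectrum",
    "assignment_rate",
    "collect_calibration_pairs",
    "fit_recalibration",
    "apply_recalibration",
    "clean_spectrum",
    "spectrum_to_json",
    "spectrum_from_json",
]

PRE_RECAL_PPM = 10.0
POST_RECAL_PPM = 2.5
MIN_LOESS_PAIRS = 20
LOESS_SPAN = 0.75
RDBE_MIN = -0.5


def ion_mz_of_formula(counts: Mapping[str, int], charge_sign: int = +1) -> float:
    """m/z of a singly charged ion with the given element counts."""
    if charge_sign not in (+1, -1):
        raise ValueError("charge_sign must be +1 or -1")
    return chem.monoisotopic_mass(counts) - charge_sign * ELECTRON_MASS


@dataclass(frozen=True)
class FormulaCandidate:
    counts: Mapping[str, int]
    mz: float  # theoretical ion m/z
    error_ppm: float  # (observed - theoretical) / theoretical * 1e6

    @property
    def formula(self) -> str:
        return chem.hill_formula(self.counts)


@dataclass
class AnnotatedPeak:
    mz: float
    intensity: float
    candidates: Tuple[FormulaCandidate, ...] = ()

    @property
    def best(self) -> Optional[FormulaCandidate]:
        return self.candidates[0] if self.candidates else None

    @property
    def status(self) -> str:
        return "assigned" if self.candidates else "failpeak"


def enumerate_subformulas(precursor_ion: Mapping[str, int], fragment_mz: float,
                          tol_ppm: float, charge_sign: int = +1
                          ) -> List[FormulaCandidate]:
    """All sub-formulas of the precursor ion within ``tol_ppm`` of
    ``fragment_mz``, RDBE >= -0.5, sorted by absolute m/z error.

    The element set is restricted to the precursor's own elements.  Uses a
    depth-first count enumeration with residual-mass pruning, so it is
    exact (equivalent to exhaustive subset search).
    """
    if fragment_mz <= 0:
        raise ValueError("fragment m/z must be positive")
    elements = sorted((s, n) for s, n in precursor_ion.items() if n > 0)
    target = fragment_mz + charge_sign * ELECTRON_MASS  # neutral-atom mass sum
    half = fragment_mz * tol_ppm * 1e-6
    lo, hi = target - half, target + half
    masses = [chem.MONOISOTOPIC_MASS[s] for s, _ in elements]
    # max mass attainable from elements i..end
    suffix_max = [0.0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * elements[i][1]

    out: List[FormulaCandidate] = []
    counts: Dict[str, int] = {}

    def descend(i: int, mass_so_far: float) -> None:
        if mass_so_far > hi:
            return
        if i == len(elements):
            if lo <= mass_so_far <= hi:
                c = {s: n for s, n in counts.items() if n > 0}
                if not c or chem.rdbe(c) < RDBE_MIN:
                    return
                theo = mass_so_far - charge_sign * ELECTRON_MASS
                err = (fragment_mz - theo) / theo * 1e6
                out.append(FormulaCandidate(counts=c, mz=theo, error_ppm=err))
            return
        if mass_so_far + suffix_max[i] < lo:
            return
        sym, n_max = elements[i]
        m = masses[i]
        for n in range(n_max + 1):
            added = mass_so_far + n * m
            if added > hi:
                break
            counts[sym] = n
            descend(i + 1, added)
        counts.pop(sym, None)

    descend(0, 0.0)
    out.sort(key=lambda c: (abs(c.error_ppm), c.formula))
    return out


def annotate_spectrum(scan: Scan, entry: CompoundEntry, adduct,
                      tol_ppm: float = PRE_RECAL_PPM) -> List[AnnotatedPeak]:
    """Annotate every centroid of an MS2 scan with candidate sub-formulas
    of the compound's adduct ion."""
    if scan.n_peaks == 0:
        raise ValueError("cannot annotate an empty peak list")
    adduct = chem.get_adduct(adduct) if isinstance(adduct, str) else adduct
    precursor_ion = chem.ion_formula(entry.formula, adduct)
    sign = +1 if adduct.charge > 0 else -1
    return [
        AnnotatedPeak(
            mz=float(mz), intensity=float(inten),
            candidates=tuple(enumerate_subformulas(
                precursor_ion, float(mz), tol_ppm, charge_sign=sign)),
        )
        for mz, inten in zip(scan.mz, scan.intensity)
    ]


def assignment_rate(peaks: Sequence[AnnotatedPeak]) -> float:
    if not peaks:
        return 0.0
    return sum(1 for p in peaks if p.candidates) / len(peaks)


def collect_calibration_pairs(annotated: Iterable[Sequence[AnnotatedPeak]]
                              ) -> List[Tuple[float, float]]:
    """(observed, theoretical) m/z pairs from the best assignment of every
    annotated (non-fail) peak across spectra."""
    pairs = []
    for spectrum in annotated:
        for peak in spectrum:
            if peak.best is not None:
                pairs.append((peak.mz, peak.best.mz))
    return pairs


@dataclass
class RecalModel:
    """m/z-dependent mass-error model: observed m/z -> predicted error, ppm."""

    kind: str  # "local-regression" | "linear-fallback"
    x: np.ndarray  # knots (observed m/z, ascending)
    y: np.ndarray  # fitted error at knots, ppm
    training_size: int

    def predict(self, mz) -> np.ndarray:
        """Predicted error (ppm); clamped to boundary values outside the
        fitted range."""
        return np.interp(np.asarray(mz, dtype=float), self.x, self.y)


def fit_recalibration(pairs: Sequence[Tuple[float, float]],
                      min_loess: int = MIN_LOESS_PAIRS,
                      span: float = LOESS_SPAN) -> RecalModel:
    """Fit the error-vs-m/z curve from (observed, theoretical) pairs.

    LOWESS for ``len(pairs) >= min_loess``, otherwise a straight line;
    fewer than 2 pairs is an error.
    """
    if len(pairs) < 2:
        raise ValueError("recalibration requires at least 2 pairs")
    obs = np.array([p[0] for p in pairs], dtype=float)
    theo = np.array([p[1] for p in pairs], dtype=float)
    err = (obs - theo) / theo * 1e6
    order = np.argsort(obs, kind="stable")
    obs, err = obs[order], err[order]
    if len(pairs) >= min_loess:
        fitted = lowess(err, obs, frac=span, it=3, return_sorted=True)
        x, y = fitted[:, 0], fitted[:, 1]
        # collapse duplicate knots for interpolation
        x, idx = np.unique(x, return_index=True)
        y = y[idx]
        if x.size < 2:
            x = np.array([obs[0] - 1.0, obs[-1] + 1.0])
            y = np.array([y[0], y[0]]) if y.size else np.zeros(2)
        return RecalModel(kind="local-regression", x=x, y=y,
                          training_size=len(pairs))
    coeffs = np.polyfit(obs, err, deg=1)
    x = np.array([obs[0], obs[-1]])
    if x[0] == x[1]:
        x = np.array([x[0], x[0] + 1e-9])
    y = np.polyval(coeffs, x)
    return RecalModel(kind="linear-fallback", x=x, y=y,
                      training_size=len(pairs))


def apply_recalibration(scan: Scan, model: RecalModel) -> Scan:
    """Correct a scan's m/z axis: ``corrected = observed * (1 - e*1e-6)``
    with ``e`` the predicted error at the observed m/z."""
    pred = model.predict(scan.mz)
    corrected = scan.mz * (1.0 - pred * 1e-6)
    new = replace(scan)
    new.mz = corrected
    new.intensity = scan.intensity.copy()
    return new


# ---------------------------------------------------------------------------
# Cleanup


@dataclass(frozen=True)
class CleanPolicy:
    drop_failpeaks: bool = True
    min_relative_intensity: float = 1.0 / 999.0  # vs base peak
    merge_width_ppm: float = 2.0 * POST_RECAL_PPM

    def __post_init__(self):
        if not (0 <= self.min_relative_intensity < 1):
            raise ValueError("min_relative_intensity must be in [0, 1)")


@dataclass
class CleanSpectrum:
    """A cleaned, annotated MS2 spectrum ready for record assembly."""

    compound_id: str
    mix: str
    polarity: str
    collision_energy: Optional[float]
    precursor_mz: float
    retention_time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    formulas: List[Optional[str]] = field(default_factory=list)
    provenance: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            self.formulas = [self.formulas[i] for i in order]
        if np.any(self.intensity <= 0):
            raise ValueError("clean spectrum intensities must be positive")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.mz.size else 0.0


def clean_spectrum(annotated: Sequence[AnnotatedPeak], *, compound_id: str,
                   mix: str, polarity: str, collision_energy: Optional[float],
                   precursor_mz: float, retention_time: float,
                   policy: CleanPolicy = CleanPolicy(),
                   provenance: Optional[Dict[str, float]] = None
                   ) -> CleanSpectrum:
    """Drop failpeaks, merge near-duplicate centroids (intensity summed,
    intensity-weighted m/z), and apply the relative-intensity floor."""
    peaks = [p for p in annotated if p.intensity > 0]
    if policy.drop_failpeaks:
        peaks = [p for p in peaks if p.candidates]
    peaks.sort(key=lambda p: p.mz)
    merged: List[AnnotatedPeak] = []
    for peak in peaks:
        if merged:
            last = merged[-1]
            if (peak.mz - last.mz) / last.mz * 1e6 <= policy.merge_width_ppm:
                total = last.intensity + peak.intensity
                dominant = last if last.intensity >= peak.intensity else peak
                merged[-1] = AnnotatedPeak(
                    mz=(last.mz * last.intensity + peak.mz * peak.intensity)
                    / total,
                    intensity=total,
                    candidates=dominant.candidates,
                )
                continue
        merged.append(peak)
    if merged:
        base = max(p.intensity for p in merged)
        merged = [p for p in merged
                  if p.intensity >= policy.min_relative_intensity * base]
    return CleanSpectrum(
        compound_id=compound_id, mix=mix, polarity=polarity,
        collision_energy=collision_energy, precursor_mz=precursor_mz,
        retention_time=retention_time,
        mz=np.array([p.mz for p in merged]),
        intensity=np.array([p.intensity for p in merged]),
        formulas=[p.best.formula if p.best else None for p in merged],
        provenance=dict(provenance or {}),
    )


# ---------------------------------------------------------------------------
# JSON-lines serialization (one spectrum per line)


def spectrum_to_json(spectrum: CleanSpectrum) -> str:
    return json.dumps({
        "compound_id": spectrum.compound_id,
        "mix": spectrum.mix,
        "polarity": spectrum.polarity,
        "collision_energy": spectrum.collision_energy,
        "precursor_mz": spectrum.precursor_mz,
        "retention_time": spectrum.retention_time,
        "mz": [float(v) for v in spectrum.mz],
        "intensity": [float(v) for v in spectrum.intensity],
        "formulas": spectrum.formulas,
        "provenance": spectrum.provenance,
    }, sort_keys=True)


def spectrum_from_json(line: str) -> CleanSpectrum:
    data = json.loads(line)
    return CleanSpectrum(
        compound_id=data["compound_id"], mix=data["mix"],
        polarity=data["polarity"],
        collision_energy=data["collision_energy"],
        precursor_mz=data["precursor_mz"],
        retention_time=data["retention_time"],
        mz=np.array(data["mz"], dtype=float),
        intensity=np.array(data["intensity"], dtype=float),
        formulas=list(data["formulas"]),
        provenance=dict(data["provenance"]),
    )
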