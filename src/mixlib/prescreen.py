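"""EIC extraction and automated quality control per compound and run.

A compound passes QC in a given run when (a) its extracted ion chromatogram
has a chromatographic peak with apex intensity at or above the intensity
threshold, (b) that peak's signal-to-noise ratio meets the S/N threshold,
and (c) at least one MS2 scan was acquired whose precursor matches the
target m/z within the ppm tolerance and whose retention time lies within
the RT tolerance of the apex.  MS2 scans outside the RT tolerance are
"RT shifted" and excluded from the matches.

Defaults reproduce the screening thresholds used for Orbitrap acquisitions
of known mixtures: apex intensity 1e5 counts, S/N 3, +/-2.5 ppm,
+/-0.5 min.

The noise estimate behind S/N is the median absolute deviation of the EIC
trace scaled to a Gaussian sigma (x1.4826), with the trace median as the
baseline; both are robust to the small fraction of scans that
chromatographic peaks occupy.  The criterion (S/N) is standard, the
estimator is this package's choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .chem import Adduct, get_adduct
from .msio import CompoundEntry, Run

__all__ = [
    "EIC",
    "ChromPeak",
    "QCThresholds",
    "QCResult",
    "extract_eic",
    "detect_peaks",
    "qc_compound",
    "qc_run",
    "prescreen_table",
]

#: QC check identifiers.
CHECK_INTENSITY = "intensity"
CHECK_SNR = "snr"
CHECK_MS2 = "ms2_present"
CHECK_RT_SHIFT = "rt_shift"


@dataclass
class EIC:
    """Extracted ion chromatogram: one point per MS1 scan."""

    target_mz: float
    ppm: float
    retention_time: np.ndarray  # minutes
    intensity: np.ndarray  # counts

    def __post_init__(self):
        self.retention_time = np.asarray(self.retention_time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)


@dataclass(frozen=True)
class ChromPeak:
    """A chromatographic peak on an EIC."""

    rt: float  # apex, minutes
    intensity: float  # apex, counts
    snr: float
    left: float  # minutes
    right: float  # minutes


@dataclass(frozen=True)
class QCThresholds:
    min_intensity: float = 1e5  # counts, MS1 apex
    min_snr: float = 3.0
    ppm: float = 2.5
    rt_tol: float = 0.5  # minutes

    def __post_init__(self):
        for name in ("min_intensity", "min_snr", "ppm", "rt_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class QCResult:
    compound_id: str
    mix: str
    polarity: str
    collision_energy: Optional[float]
    verdict: bool
    failed: FrozenSet[str]
    peaks: Tuple[ChromPeak, ...] = ()
    best_peak: Optional[ChromPeak] = None
    ms2_matches: Tuple[int, ...] = ()  # indices into run.scans, nearest first

    def __post_init__(self):
        assert self.verdict == (not self.failed)


def extract_eic(run: Run, target_mz: float, ppm: float) -> EIC:
    """Sum in-window centroid intensities per MS1 scan.

    The window is ``|obs - target| / target * 1e6 <= ppm``; scans with no
    in-window centroid contribute zero.
    """
    ms1 = run.ms1_scans()
    if not ms1:
        raise ValueError("run has no MS1 scans")
    half = target_mz * ppm * 1e-6
    lo, hi = target_mz - half, target_mz + half
    rts = np.empty(len(ms1))
    ints = np.zeros(len(ms1))
    for i, scan in enumerate(ms1):
        rts[i] = scan.retention_time
        a = np.searchsorted(scan.mz, lo, side="left")
        b = np.searchsorted(scan.mz, hi, side="right")
        if b > a:
            ints[i] = scan.intensity[a:b].sum()
    return EIC(target_mz=target_mz, ppm=ppm,
               retention_time=rts, intensity=ints)


def _mad_sigma(values: np.ndarray) -> float:
    if values.size == 0:
        return 0.0
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def detect_peaks(eic: EIC, min_points: int = 3,
                 noise_multiplier: float = 2.0,
                 rel_prominence: float = 0.05) -> List[ChromPeak]:
    """Local maxima of the EIC, with baseline-corrected apex intensity and
    S/N from the out-of-peak noise; returned in retention-time order.

    Candidate maxima need a prominence of at least ``noise_multiplier``
    robust sigmas of the trace (and ``rel_prominence`` of the trace
    maximum, which suppresses shot-noise ripples on peak flanks) and a
    two-sample width, which suppresses single-scan spikes.  The prominence
    floor sits deliberately below the QC S/N threshold so that a peak can
    be detected and still fail the S/N criterion.  Apex intensity and S/N
    are both measured above the trace-median baseline; on a noise-free
    trace the noise floor is one count, so S/N is then bounded by the apex
    counts.
    """
    y = eic.intensity
    if y.size < min_points or not np.any(y > 0):
        return []
    sigma0 = _mad_sigma(y)
    floor = max(noise_multiplier * sigma0, rel_prominence * float(y.max()),
                1.0)
    idx, props = find_peaks(y, prominence=floor, width=2.0, rel_height=0.5)
    if idx.size == 0:
        return []
    # peak extent from the half-prominence width, widened by one sample
    bounds = [
        (max(int(np.floor(li)) - 1, 0), min(int(np.ceil(ri)) + 1, y.size - 1))
        for li, ri in zip(props["left_ips"], props["right_ips"])
    ]
    # baseline and noise from the full trace: median/MAD are robust to the
    # small fraction of scans chromatographic peaks occupy, and masking
    # detected maxima would clip the upper tail of the noise distribution
    # and bias S/N upward
    baseline = float(np.median(y))
    noise = sigma0
    if noise <= 0:
        noise = 1.0
    peaks = [
        ChromPeak(
            rt=float(eic.retention_time[apex]),
            intensity=float(y[apex] - baseline),
            snr=float((y[apex] - baseline) / noise),
            left=float(eic.retention_time[lb]),
            right=float(eic.retention_time[rb]),
        )
        for apex, (lb, rb) in zip(idx, bounds)
    ]
    return sorted(peaks, key=lambda p: p.rt)


def _match_ms2(run: Run, target_mz: float, ppm: float) -> List[int]:
    """Indices of MS2 scans whose precursor matches the target within ppm."""
    half = target_mz * ppm * 1e-6
    out = []
    for i, scan in enumerate(run.scans):
        if scan.ms_level == 2 and scan.precursor_mz is not None:
            if abs(scan.precursor_mz - target_mz) <= half:
                out.append(i)
    return out


def qc_compound(run: Run, entry: CompoundEntry, adduct: Adduct | str,
                thresholds: QCThresholds = QCThresholds()) -> QCResult:
    """Apply the QC rules to one compound in one run."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    target = entry.ion_mz(adduct)
    eic = extract_eic(run, target, thresholds.ppm)
    peaks = detect_peaks(eic)
    failed = set()
    best = max(peaks, key=lambda p: p.intensity) if peaks else None
    if best is None or best.intensity < thresholds.min_intensity:
        failed.add(CHECK_INTENSITY)
    if best is None or best.snr < thresholds.min_snr:
        failed.add(CHECK_SNR)
    candidates = _match_ms2(run, target, thresholds.ppm)
    matches: List[int] = []
    if not candidates:
        failed.add(CHECK_MS2)
    elif best is not None:
        in_tol = [i for i in candidates
                  if abs(run.scans[i].retention_time - best.rt)
                  <= thresholds.rt_tol]
        if not in_tol:
            failed.add(CHECK_RT_SHIFT)
        else:
            matches = sorted(
                in_tol,
                key=lambda i: (abs(run.scans[i].retention_time - best.rt), i))
    else:
        # no chromatographic peak to anchor the MS2 check against
        failed.add(CHECK_RT_SHIFT)
    return QCResult(
        compound_id=entry.identifier,
        mix=run.mix,
        polarity=run.mode or (run.scans[0].polarity if run.scans else "+"),
        collision_energy=run.collision_energy,
        verdict=not failed,
        failed=frozenset(failed),
        peaks=tuple(peaks),
        best_peak=best,
        ms2_matches=tuple(matches),
    )


def qc_run(run: Run, entries: Sequence[CompoundEntry], adduct: Adduct | str,
           thresholds: QCThresholds = QCThresholds()) -> List[QCResult]:
    return [qc_compound(run, e, adduct, thresholds) for e in entries]


def prescreen_table(results: Sequence[QCResult]) -> pd.DataFrame:
    """One row per compound x mix x mode x CE, CSV-ready."""
    rows = []
    for r in sorted(results, key=lambda r: (r.mix, str(r.collision_energy),
                                            r.polarity, r.compound_id)):
        rows.append({
            "compound": r.compound_id,
            "mix": r.mix,
            "mode": r.polarity,
            "collision_energy": r.collision_energy,
            "verdict": "pass" if r.verdict else "fail",
            "failed_checks": ";".join(sorted(r.failed)),
            "apex_rt": r.best_peak.rt if r.best_peak else np.nan,
            "apex_intensity": r.best_peak.intensity if r.best_peak else 0.0,
            "snr": r.best_peak.snr if r.best_peak else 0.0,
            "n_peaks": len(r.peaks),
            "n_ms2_matched": len(r.ms2_matches),
        })
    columns = ["compound", "mix", "mode", "collision_energy", "verdict",
               "failed_checks", "apex_rt", "apex_intensity", "snr",
               "n_peaks", "n_ms2_matched"]
    return pd.DataFrame(rows, columns=columns)
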