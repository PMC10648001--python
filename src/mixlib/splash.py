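"""Spectral hashing in the splash10 layout.

A SPLASH is a deterministic, non-proprietary identifier of a mass
spectrum's peak list with four dash-separated blocks:

1. ``splash10`` -- format identifier, version 1, spectrum type 0 (MS);
2. a 4-character base-36 *top-ten hash* over the m/z values of the ten
   most intense ions;
3. a 10-digit wrapped intensity histogram (ten 100-Da bins, m/z wrapped
   modulo 1000, bin sums scaled so the largest bin is 9);
4. the first 20 hex characters of the SHA-256 of the full peak list.

Intensities are normalized to the base peak before hashing, so any uniform
scaling of the spectrum leaves the SPLASH unchanged.  m/z values enter the
hashes scaled by 1e6 and rounded to integers; normalized intensities are
scaled to 0..999.

The block layout and the m/z scaling follow the published SPLASH design;
the exact rounding and separator conventions are pinned by this module (and
by an independently coded duplicate in the test suite) so that hashes are
stable for this library.
"""

from __future__ import annotations

import hashlib
from typing import Sequence, Tuple

import numpy as np

__all__ = ["splash_ms", "SPLASH_PREFIX"]

SPLASH_PREFIX = "splash10"
_BASE36 = "0123456789abcdefghijklmnopqrstuvwxyz"


def _to_base36(value: int, width: int) -> str:
    digits = []
    while value:
        value, rem = divmod(value, 36)
        digits.append(_BASE36[rem])
    text = "".join(reversed(digits)) or "0"
    return text.rjust(width, "0")[-width:]


def _prepare(mz: Sequence[float], intensity: Sequence[float]
             ) -> Tuple[np.ndarray, np.ndarray]:
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size == 0:
        raise ValueError("SPLASH requires at least one peak")
    if mz.shape != intensity.shape:
        raise ValueError("m/z and intensity lengths differ")
    if np.any(intensity < 0) or not np.any(intensity > 0):
        raise ValueError("intensities must be non-negative with a base peak")
    keep = intensity > 0
    mz, intensity = mz[keep], intensity[keep]
    rel = intensity / intensity.max() * 999.0
    return mz, rel


def _top_ten_block(mz: np.ndarray, rel: np.ndarray) -> str:
    order = np.lexsort((mz, -rel))  # intensity desc, m/z asc
    top = np.sort(mz[order[:10]])
    text = " ".join(str(int(round(v * 1e6))) for v in top)
    digest = hashlib.sha256(text.encode("ascii")).hexdigest()
    return _to_base36(int(digest[:10], 16) % 36**4, 4)


def _histogram_block(mz: np.ndarray, rel: np.ndarray) -> str:
    bins = np.zeros(10)
    idx = (np.floor(mz / 100.0).astype(int)) % 10
    for i, r in zip(idx, rel):
        bins[i] += r
    top = bins.max()
    if top <= 0:
        return "0" * 10
    scaled = np.floor(bins * 9.0 / top + 1e-9).astype(int)
    return "".join(str(v) for v in scaled)


def _spectrum_block(mz: np.ndarray, rel: np.ndarray) -> str:
    order = np.lexsort((rel, mz))  # m/z asc, intensity asc
    parts = [
        f"{int(round(mz[i] * 1e6))}:{int(round(rel[i]))}" for i in order
    ]
    digest = hashlib.sha256(" ".join(parts).encode("ascii")).hexdigest()
    return digest[:20]


def splash_ms(mz: Sequence[float], intensity: Sequence[float]) -> str:
    """SPLASH of an MS peak list (block layout ``splash10-xxxx-nnnnnnnnnn-
    hhhhhhhhhhhhhhhhhhhh``)."""
    mz, rel = _prepare(mz, intensity)
    return "-".join([
        SPLASH_PREFIX,
        _top_ten_block(mz, rel),
        _histogram_block(mz, rel),
        _spectrum_block(mz, rel),
    ])
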