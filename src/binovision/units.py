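"""Canonical unit conversions for contrast, interocular balance, and disparity.

Conventions used throughout the package:

* **dB contrast** — ``20 * log10(c)`` of linear RMS contrast ``c`` expressed
  as a fraction of the maximum (so ``c = 1`` is 100% contrast and physical
  stimuli have non-positive dB values).
* **Balance point (BP)** — an interocular contrast ratio (left/right)
  expressed in dB, ``20 * log10(ratio)``.  0 dB means the two eyes contribute
  equally to the fused percept; positive values mean the left eye needs less
  contrast (left dominant).  A raw ``log10`` accessor is provided for
  compatibility with analyses that report the plain logarithm.
* **Stereoacuity** — disparity thresholds in arc seconds, analysed on a
  ``log2`` axis so that a one-unit change is a doubling of disparity.
"""

from __future__ import annotations

import math

__all__ = [
    "rms_to_db",
    "db_to_rms",
    "db_to_percent",
    "percent_to_db",
    "ratio_to_db",
    "db_to_ratio",
    "ratio_to_log10",
    "log2_to_arcsec",
    "arcsec_to_log2",
    "interocular_contrasts",
]


def rms_to_db(c: float) -> float:
    """Convert linear RMS contrast (fraction, ``0 < c``) to dB contrast."""
    if not c > 0:
        raise ValueError(f"RMS contrast must be positive, got {c!r}")
    return 20.0 * math.log10(c)


def db_to_rms(x: float) -> float:
    """Convert dB contrast back to linear RMS contrast (fraction)."""
    return 10.0 ** (x / 20.0)


def db_to_percent(x: float) -> float:
    """dB contrast to percent contrast (0–100 scale), e.g. -6.936 dB -> 45%."""
    return 100.0 * db_to_rms(x)


def percent_to_db(c_pct: float) -> float:
    """Percent contrast (0–100 scale) to dB contrast."""
    if not c_pct > 0:
        raise ValueError(f"percent contrast must be positive, got {c_pct!r}")
    return rms_to_db(c_pct / 100.0)


def ratio_to_db(r: float) -> float:
    """Interocular contrast ratio (left/right) to balance-point dB."""
    if not r > 0:
        raise ValueError(f"contrast ratio must be positive, got {r!r}")
    return 20.0 * math.log10(r)


def db_to_ratio(x: float) -> float:
    """Balance-point dB back to a linear interocular contrast ratio."""
    return 10.0 ** (x / 20.0)


def ratio_to_log10(r: float) -> float:
    """Plain ``log10`` of the interocular ratio (alternative BP unit)."""
    if not r > 0:
        raise ValueError(f"contrast ratio must be positive, got {r!r}")
    return math.log10(r)


def log2_to_arcsec(x: float, rounded: bool = False) -> float:
    """log2 disparity threshold to arc seconds.

    With ``rounded=True`` the result is rounded half-away-from-zero to an
    integer arc second, the convention used when printing linear
    stereoacuities alongside their log2 values.
    """
    v = 2.0**x
    if rounded:
        return float(math.floor(v + 0.5))
    return v


def arcsec_to_log2(a: float) -> float:
    """Disparity in arc seconds to its log2 value."""
    if not a > 0:
        raise ValueError(f"disparity must be positive, got {a!r}")
    return math.log2(a)


def interocular_contrasts(base_pct: float, ratio: float) -> tuple[float, float]:
    """Per-eye contrasts (percent) realising an interocular ratio.

    Both eyes are scaled symmetrically about the base contrast so that
    ``left / right == ratio`` and ``sqrt(left * right) == base``.  For a 45%
    base and a 4:1 ratio this gives (90.0, 22.5).
    """
    if not base_pct > 0 or not ratio > 0:
        raise ValueError("base contrast and ratio must be positive")
    s = math.sqrt(ratio)
    return base_pct * s, base_pct / s
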