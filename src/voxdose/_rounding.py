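"""Reporting-layer rounding.

All internal arithmetic is carried out at full double precision; rounding is
applied only when values are formatted for report tables.  The convention is
round-half-away-from-zero with one guard digit: the value is first quantized
at ``nd + 1`` decimals, then at ``nd``.  This matches the rounding chain of
dose report tables produced by statistics software that exports intermediate
values at higher precision (e.g. 11.745 -> 11.75 -> 11.8).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["round_report"]

_EPS = 1e-9  # absorbs float representation error below the guard digit


def _half_away(x: float, nd: int) -> float:
    s = -1.0 if x < 0 else 1.0
    return s * math.floor(abs(x) * 10**nd + 0.5 + _EPS) / 10**nd


def round_report(x, nd: int = 1):
    """Round ``x`` to ``nd`` decimals for reporting (guard digit, half away
    from zero).  Accepts scalars or array-likes and preserves shape."""
    arr = np.asarray(x, dtype=float)

    def _one(v: float) -> float:
        if not math.isfinite(v):
            return v
        return _half_away(_half_away(v, nd + 1), nd)

    if arr.ndim == 0:
        return _one(float(arr))
    return np.vectorize(_one)(arr)
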