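"""Small shared numerics: report rounding and undefined-value sentinels."""

from __future__ import annotations

import math

__all__ = ["round_half_away", "UNDEFINED", "is_undefined"]

#: Sentinel for quantities that are undefined (0/0 divisions, zero areas...).
UNDEFINED = float("nan")


def is_undefined(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


def round_half_away(x: float, digits: int = 0) -> float:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3).

    Report tables round this way; Python's builtin ``round`` is banker's
    rounding and would disagree on exact halves.
    """
    if is_undefined(x):
        return x
    factor = 10.0 ** digits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    out = rounded / factor
    return out if digits > 0 else float(int(out))
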