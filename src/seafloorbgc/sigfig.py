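"""Significant-figure rounding helpers.

Published global flux estimates are quoted to one or two significant
figures; comparisons against those printed values must round the computed
numbers the same way.
"""

from __future__ import annotations

import math


def round_sigfigs(x: float, n: int) -> float:
    """Round ``x`` to ``n`` significant figures.

    Parameters
    ----------
    x : float
        Value to round. Zero is returned unchanged.
    n : int
        Number of significant figures, ``n >= 1``.
    """
    if n < 1:
        raise ValueError("need at least one significant figure")
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, n - 1 - exponent)


def format_sigfigs(x: float, n: int) -> str:
    """Format ``x`` at ``n`` significant figures in scientific notation."""
    return f"{round_sigfigs(x, n):.{max(n - 1, 0)}e}"
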