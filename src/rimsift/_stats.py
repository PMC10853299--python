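"""Shared numeric primitives pinned once and reused by every stage.

The percentile estimator is the linear-interpolation ("closest ranks")
estimator: for a sorted sample x[0..n-1] the p-th percentile sits at
fractional index (n-1)*p/100 and is linearly interpolated between the
two neighbouring order statistics. Pinning it here keeps the p5 lesion
feature, the normalization landmarks and the tests bit-consistent.
"""

from __future__ import annotations

import decimal

import numpy as np

__all__ = ["percentile", "round_half_up"]


def percentile(values: np.ndarray, q) -> np.ndarray | float:
    """Percentile(s) of ``values`` with linear interpolation at index (n-1)q/100."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of an empty sample is undefined")
    return np.percentile(values, q, method="linear")


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero, matching printed-report precision."""
    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)
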