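"""Small shared statistical primitives."""

from __future__ import annotations

import numpy as np

from .errors import CondmapError


def benjamini_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, clipped to 1.
    Order-preserving: returns q in the input order. NaN inputs yield NaN
    outputs and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if pv.size == 0:
        return out
    if (pv < 0).any() or (pv > 1).any():
        raise CondmapError("p-values must lie in [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out[mask] = q
    return out
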