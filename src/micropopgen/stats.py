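"""Shared statistical utilities."""

from __future__ import annotations

import numpy as np


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted ascending, adj_(i) = min_{j >= i} p_(j) * m / j capped at 1,
    then restored to the input order; NaN entries are ignored (returned as
    NaN, not counted in m)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    restored = np.empty(m)
    restored[order] = adjusted
    out[valid] = restored
    return out
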