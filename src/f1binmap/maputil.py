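"""Map functions: recombination fraction <-> genetic distance (cM)."""

from __future__ import annotations

import numpy as np


def kosambi(r):
    """Kosambi map distance d = 25*ln((1+2r)/(1-2r)) cM for r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    out = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return out if out.ndim else float(out)


def kosambi_inverse(d_cM):
    """Inverse Kosambi: r = tanh(d/50)/2."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    out = 0.5 * np.tanh(d / 50.0)
    return out if out.ndim else float(out)


def haldane(r):
    """Haldane map distance d = -50*ln(1-2r) cM."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    out = -50.0 * np.log(1.0 - 2.0 * r)
    return out if out.ndim else float(out)


def haldane_inverse(d_cM):
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    out = 0.5 * (1.0 - np.exp(-d / 50.0))
    return out if out.ndim else float(out)


def map_fn(name):
    return {"kosambi": kosambi, "haldane": haldane}[name]


def inverse_map(d_cM, name="kosambi"):
    return {"kosambi": kosambi_inverse, "haldane": haldane_inverse}[name](d_cM)
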