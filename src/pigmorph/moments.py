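"""Geometric image moments and the seven Hu invariants of a binary mask.

For a binary image f(x, y) ∈ {0, 1} the raw moments are

    M_pq = Σ_x Σ_y x^p y^q f(x, y),

the centroid (x̄, ȳ) = (M₁₀/M₀₀, M₀₁/M₀₀), the central moments

    μ_pq = Σ_x Σ_y (x − x̄)^p (y − ȳ)^q f(x, y),

and the normalized central moments η_pq = μ_pq / μ₀₀^γ with
γ = 1 + (p + q)/2.  The seven Hu invariants φ₁…φ₇ are the standard
polynomial combinations of the η_pq of order ≤ 3; they are invariant to
translation, scale and rotation, and φ₇ changes sign under reflection.

Raw moments are computed in exact integer arithmetic (pixel coordinates are
integers); central and normalized moments are floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyMaskError
from .mask_io import BinaryMask

__all__ = ["MomentSet", "compute_moments", "hu_invariants"]


@dataclass
class MomentSet:
    m: dict[tuple[int, int], int]
    centroid: tuple[float, float]
    mu: dict[tuple[int, int], float]
    eta: dict[tuple[int, int], float]
    max_order: int = 3
    phi: np.ndarray | None = field(default=None)


def compute_moments(mask: BinaryMask, max_order: int = 3) -> MomentSet:
    """Raw, central and normalized moments up to total order ``max_order``.

    Raw moments are exact integers.  Raises EmptyMaskError on an empty mask.
    """
    ys, xs = np.nonzero(mask.grid)
    if xs.size == 0:
        raise EmptyMaskError("cannot compute moments of an empty mask")
    xs64 = xs.astype(np.int64)
    ys64 = ys.astype(np.int64)

    xpow = [np.ones_like(xs64)]
    ypow = [np.ones_like(ys64)]
    for _ in range(max_order):
        xpow.append(xpow[-1] * xs64)
        ypow.append(ypow[-1] * ys64)

    m: dict[tuple[int, int], int] = {}
    for p in range(max_order + 1):
        for q in range(max_order + 1 - p):
            m[(p, q)] = int(np.sum(xpow[p] * ypow[q]))

    m00 = m[(0, 0)]
    xbar = m[(1, 0)] / m00
    ybar = m[(0, 1)] / m00

    dx = xs64 - xbar
    dy = ys64 - ybar
    dxpow = [np.ones_like(dx)]
    dypow = [np.ones_like(dy)]
    for _ in range(max_order):
        dxpow.append(dxpow[-1] * dx)
        dypow.append(dypow[-1] * dy)

    mu: dict[tuple[int, int], float] = {}
    eta: dict[tuple[int, int], float] = {}
    for p in range(max_order + 1):
        for q in range(max_order + 1 - p):
            val = float(np.sum(dxpow[p] * dypow[q]))
            if (p, q) in ((1, 0), (0, 1)):
                val = 0.0  # zero by construction; clear float residue
            mu[(p, q)] = val
            gamma = 1.0 + (p + q) / 2.0
            eta[(p, q)] = val / (m00 ** gamma)

    return MomentSet(m=m, centroid=(xbar, ybar), mu=mu, eta=eta, max_order=max_order)


def hu_invariants(ms: MomentSet) -> np.ndarray:
    """The seven Hu invariants φ₁…φ₇ from normalized central moments.

    Values are returned on their raw scale (no log transform).
    """
    if ms.m[(0, 0)] == 0:
        raise EmptyMaskError("Hu invariants undefined for an empty mask")
    if ms.max_order < 3:
        raise ValueError("Hu invariants require moments up to order 3")
    e = ms.eta
    n20, n02, n11 = e[(2, 0)], e[(0, 2)], e[(1, 1)]
    n30, n03 = e[(3, 0)], e[(0, 3)]
    n21, n12 = e[(2, 1)], e[(1, 2)]

    phi1 = n20 + n02
    phi2 = (n20 - n02) ** 2 + 4.0 * n11 ** 2
    phi3 = (n30 - 3.0 * n12) ** 2 + (3.0 * n21 - n03) ** 2
    phi4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    phi5 = (n30 - 3.0 * n12) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3.0 * (n21 + n03) ** 2
    ) + (3.0 * n21 - n03) * (n21 + n03) * (
        3.0 * (n30 + n12) ** 2 - (n21 + n03) ** 2
    )
    phi6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4.0 * n11 * (
        n30 + n12
    ) * (n21 + n03)
    phi7 = (3.0 * n21 - n03) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3.0 * (n21 + n03) ** 2
    ) - (n30 - 3.0 * n12) * (n21 + n03) * (
        3.0 * (n30 + n12) ** 2 - (n21 + n03) ** 2
    )

    phi = np.array([phi1, phi2, phi3, phi4, phi5, phi6, phi7])
    ms.phi = phi
    return phi


def signed_log(phi: np.ndarray) -> np.ndarray:
    """Optional conditioning transform: sign(φ)·log10|φ| (0 stays 0)."""
    out = np.zeros_like(phi, dtype=float)
    nz = phi != 0
    out[nz] = np.sign(phi[nz]) * np.log10(np.abs(phi[nz]))
    return out
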