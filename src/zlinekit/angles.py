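"""Nematic angle utilities.

Orientations of z-lines and actin fibrils are nematic: θ and θ + π describe
the same structure.  All angles in this package are canonicalized to the
half-open interval [0, π), measured counter-clockwise from the +x (column)
axis in a y-up mathematical frame.  Raster (row-down) coordinates are
converted at the point where gradients or step vectors are formed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "canonicalize",
    "unit_vectors",
    "nematic_cos",
    "orientation_tensor",
    "tensor_director",
]


def canonicalize(theta: np.ndarray | float) -> np.ndarray | float:
    """Map angles into the canonical nematic range [0, π).

    NaNs (the invalid-pixel sentinel) pass through unchanged.
    """
    return np.mod(theta, np.pi)


def unit_vectors(theta: np.ndarray | float) -> np.ndarray:
    """Unit pseudo-vectors r = (cos θ, sin θ), stacked on the last axis."""
    theta = np.asarray(theta, dtype=float)
    return np.stack([np.cos(theta), np.sin(theta)], axis=-1)


def nematic_cos(theta_a: np.ndarray | float, theta_b: np.ndarray | float) -> np.ndarray | float:
    """|cos(θa − θb)|: 1 for parallel nematic directions, 0 for perpendicular.

    The absolute value removes the sign ambiguity of pseudo-vector dot
    products, so the result is invariant under θ → θ + π on either operand.
    """
    return np.abs(np.cos(np.asarray(theta_a, dtype=float) - theta_b))


def orientation_tensor(theta: np.ndarray) -> np.ndarray:
    """Mean nematic structure tensor T = ⟨2 r rᵀ − I⟩ of a set of angles.

    T is symmetric and traceless with eigenvalues ±q, q ∈ [0, 1]; q is the
    orientational order parameter of the angle set.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.size == 0:
        raise ValueError("orientation_tensor requires at least one angle")
    c2 = np.mean(np.cos(2.0 * theta))
    s2 = np.mean(np.sin(2.0 * theta))
    # 2 r rᵀ − I == [[cos 2θ, sin 2θ], [sin 2θ, −cos 2θ]]
    return np.array([[c2, s2], [s2, -c2]])


def tensor_director(tensor: np.ndarray) -> tuple[float, float]:
    """Director angle (canonical [0, π)) and max eigenvalue of a 2×2 nematic tensor."""
    evals, evecs = np.linalg.eigh(tensor)
    vx, vy = evecs[:, -1]
    return float(canonicalize(np.arctan2(vy, vx))), float(evals[-1])
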