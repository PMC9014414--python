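"""Real Fourier (cos/sin product) basis on the 2-torus [-pi, pi)^2.

Per-axis ordering (index u, 0..2N):
    u = 0       -> 1
    u = 2k - 1  -> cos(k x)
    u = 2k      -> sin(k x)        for k = 1..N

A 2D basis function is a product of one function per axis; the flat
index of the pair (u_phi, u_psi) is ``u_phi * (2N+1) + u_psi``, so a
coefficient set is naturally a (2N+1) x (2N+1) matrix.  This spans the
same space as complex exponentials e^{i k.z} with |k_i| <= N but keeps
all coefficients real.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "n_axis_functions",
    "axis_design_matrix",
    "basis_functions",
    "axis_index",
    "flat_index",
    "describe_axis_function",
]


def n_axis_functions(order: int) -> int:
    """Number of per-axis basis functions, 2N+1."""
    if order < 1:
        raise ValueError(f"expansion order must be >= 1, got {order}")
    return 2 * order + 1


def axis_design_matrix(x: np.ndarray, order: int, derivative: bool = False) -> np.ndarray:
    """Evaluate the per-axis basis (or its derivative) at points ``x``.

    Returns an array of shape (len(x), 2N+1).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    m = n_axis_functions(order)
    out = np.empty((x.size, m))
    if derivative:
        out[:, 0] = 0.0
    else:
        out[:, 0] = 1.0
    for k in range(1, order + 1):
        if derivative:
            out[:, 2 * k - 1] = -k * np.sin(k * x)
            out[:, 2 * k] = k * np.cos(k * x)
        else:
            out[:, 2 * k - 1] = np.cos(k * x)
            out[:, 2 * k] = np.sin(k * x)
    return out


def basis_functions(z: tuple[float, float] | np.ndarray, order: int) -> np.ndarray:
    """Full 2D basis vector at a single torus point, length (2N+1)^2.

    Flat ordering is row-major over (u_phi, u_psi).
    """
    phi, psi = float(z[0]), float(z[1])
    f_phi = axis_design_matrix(np.array([phi]), order)[0]
    f_psi = axis_design_matrix(np.array([psi]), order)[0]
    return np.outer(f_phi, f_psi).ravel()


def axis_index(k: int, kind: str) -> int:
    """Per-axis index of cos(kx) (kind='c') or sin(kx) (kind='s'); k=0 -> constant."""
    if k < 0:
        raise ValueError("wavenumber must be non-negative")
    if k == 0:
        if kind != "c":
            raise ValueError("k=0 carries only the constant (cos) function")
        return 0
    if kind == "c":
        return 2 * k - 1
    if kind == "s":
        return 2 * k
    raise ValueError(f"kind must be 'c' or 's', got {kind!r}")


def flat_index(k1: int, kind1: str, k2: int, kind2: str, order: int) -> int:
    """Flat index of the product basis function t1(k1*phi) * t2(k2*psi)."""
    m = n_axis_functions(order)
    u, v = axis_index(k1, kind1), axis_index(k2, kind2)
    if u >= m or v >= m:
        raise ValueError("wavenumber exceeds expansion order")
    return u * m + v


def describe_axis_function(u: int) -> tuple[int, str]:
    """Inverse of :func:`axis_index`: per-axis index -> (k, kind)."""
    if u == 0:
        return 0, "c"
    k = (u + 1) // 2
    return k, "c" if u % 2 == 1 else "s"
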