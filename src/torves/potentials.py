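"""Analytic 2pi-periodic model potentials on the (Phi, Psi) torus.

These potentials stand in for the free-energy surfaces that full
atomistic simulations would produce: every estimator downstream can be
scored against the exact energy and gradient evaluated here.

A potential is a sum of inverted product-von-Mises wells,

    U(z) = - sum_i depth_i * exp(conc_i * (cos(Phi - Phi_i) + cos(Psi - Psi_i) - 2))

optionally plus an explicit Fourier part, minus a constant offset so
that the minimum of a well-based potential is pinned at 0 kJ/mol.
The von-Mises kernel is smooth, exactly periodic, and its barrier
heights are easy to calibrate: an isolated well of depth d sits d
below the surrounding plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import axis_design_matrix, flat_index, n_axis_functions

__all__ = [
    "FourierTerm",
    "ModelPotential",
    "make_four_state_potential",
    "DEFAULT_CENTERS",
    "pr_like_preset",
    "pfr_like_preset",
    "four_state_test_preset",
]

#: Schematic basin layout: middle, horizontal, vertical, corner.
DEFAULT_CENTERS = {
    "S_m": (0.0, 0.0),
    "S_h": (np.pi, 0.0),
    "S_v": (0.0, np.pi),
    "S_c": (np.pi, np.pi),
}


@dataclass(frozen=True)
class FourierTerm:
    """One explicit basis term: coeff * t1(k1*Phi) * t2(k2*Psi)."""

    k1: int
    kind1: str  # 'c' or 's'
    k2: int
    kind2: str
    coeff: float  # kJ/mol


def _toroidal_sep(a, b) -> float:
    d = np.abs(np.mod(np.asarray(a) - np.asarray(b) + np.pi, 2 * np.pi) - np.pi)
    return float(np.sqrt(np.sum(d**2)))


@dataclass(frozen=True)
class ModelPotential:
    """Periodic 2D potential with exact analytic gradient.

    ``wells`` is an (n, 4) array of rows (center_phi, center_psi,
    depth kJ/mol, concentration); ``fourier`` an optional explicit
    term list.  ``offset`` is subtracted from the raw sum.
    """

    wells: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))
    fourier: tuple[FourierTerm, ...] = ()
    offset: float = 0.0

    def __post_init__(self):
        wells = np.atleast_2d(np.asarray(self.wells, dtype=float))
        if wells.size == 0:
            wells = np.zeros((0, 4))
        if wells.shape[1] != 4:
            raise ValueError("wells must have rows (phi, psi, depth, concentration)")
        if np.any(wells[:, 2] <= 0):
            raise ValueError("well depths must be positive")
        if np.any(wells[:, 3] <= 0):
            raise ValueError("well concentrations must be positive")
        object.__setattr__(self, "wells", wells)

    @property
    def fourier_order(self) -> int:
        ks = [max(t.k1, t.k2) for t in self.fourier]
        return max(ks) if ks else 0

    def fourier_coeff_matrix(self) -> np.ndarray:
        """Dense (2M+1)x(2M+1) coefficient matrix of the Fourier part."""
        order = max(self.fourier_order, 1)
        m = n_axis_functions(order)
        mat = np.zeros((m, m))
        for t in self.fourier:
            idx = flat_index(t.k1, t.kind1, t.k2, t.kind2, order)
            mat[idx // m, idx % m] += t.coeff
        return mat

    def energy(self, phi, psi) -> np.ndarray:
        """U at (arrays of) torus points, kJ/mol."""
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        u = np.zeros(np.broadcast(phi, psi).shape)
        for cp, cq, depth, conc in self.wells:
            u -= depth * np.exp(conc * (np.cos(phi - cp) + np.cos(psi - cq) - 2.0))
        if self.fourier:
            order = self.fourier_order
            fp = axis_design_matrix(np.ravel(phi), order)
            fq = axis_design_matrix(np.ravel(psi), order)
            mat = self.fourier_coeff_matrix()
            u = u + np.einsum("ni,ij,nj->n", fp, mat, fq).reshape(u.shape)
        return u - self.offset

    def gradient(self, phi, psi) -> tuple[np.ndarray, np.ndarray]:
        """(dU/dPhi, dU/dPsi) at (arrays of) torus points, kJ/mol/rad."""
        phi = np.asarray(phi, dtype=float)
        psi = np.asarray(psi, dtype=float)
        gp = np.zeros(np.broadcast(phi, psi).shape)
        gq = np.zeros_like(gp)
        for cp, cq, depth, conc in self.wells:
            e = depth * np.exp(conc * (np.cos(phi - cp) + np.cos(psi - cq) - 2.0))
            gp += conc * np.sin(phi - cp) * e
            gq += conc * np.sin(psi - cq) * e
        if self.fourier:
            order = self.fourier_order
            mat = self.fourier_coeff_matrix()
            fp = axis_design_matrix(np.ravel(phi), order)
            fq = axis_design_matrix(np.ravel(psi), order)
            dfp = axis_design_matrix(np.ravel(phi), order, derivative=True)
            dfq = axis_design_matrix(np.ravel(psi), order, derivative=True)
            gp = gp + np.einsum("ni,ij,nj->n", dfp, mat, fq).reshape(gp.shape)
            gq = gq + np.einsum("ni,ij,nj->n", fp, mat, dfq).reshape(gq.shape)
        return gp, gq

    def evaluate(self, z) -> tuple[float, tuple[float, float]]:
        """Energy and exact gradient at a single torus point."""
        e = float(self.energy(z[0], z[1]))
        gp, gq = self.gradient(z[0], z[1])
        return e, (float(gp), float(gq))

    def max_gradient_norm(self, n_grid: int = 257) -> float:
        """Coarse-grid upper estimate of max |grad U| (stability guard)."""
        x = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
        pp, qq = np.meshgrid(x, x, indexing="ij")
        gp, gq = self.gradient(pp, qq)
        return float(np.max(np.hypot(gp, gq)))

    def shifted_to_zero_min(self, n_grid: int = 512) -> "ModelPotential":
        """Return a copy whose minimum over a fine grid is exactly 0."""
        x = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
        pp, qq = np.meshgrid(x, x, indexing="ij")
        u = self.energy(pp, qq)
        return ModelPotential(self.wells, self.fourier, self.offset + float(u.min()))


def evaluate_potential(p: ModelPotential, z):
    """Functional form of :meth:`ModelPotential.evaluate`."""
    return p.evaluate(z)


def make_four_state_potential(
    centers=None,
    depths=(30.0, 20.0, 28.0, 15.0),
    concentrations=6.0,
) -> ModelPotential:
    """Four-basin torus potential with the S_m/S_h/S_v/S_c layout.

    ``centers`` is a mapping label -> (Phi, Psi) or a sequence of four
    points in the order (S_m, S_h, S_v, S_c); depths are kJ/mol below
    the inter-well plateau.  The result is shifted so min U = 0.
    """
    if centers is None:
        centers = DEFAULT_CENTERS
    if isinstance(centers, dict):
        pts = [centers[k] for k in ("S_m", "S_h", "S_v", "S_c")]
    else:
        pts = list(centers)
    depths = np.broadcast_to(np.asarray(depths, dtype=float), (len(pts),))
    concs = np.broadcast_to(np.asarray(concentrations, dtype=float), (len(pts),))
    if np.any(depths <= 0):
        raise ValueError("well depths must be positive")
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if _toroidal_sep(pts[i], pts[j]) < 1e-9:
                raise ValueError(f"well centers {i} and {j} coincide on the torus")
    wells = np.column_stack([np.asarray(pts, dtype=float), depths, concs])
    return ModelPotential(wells).shifted_to_zero_min()


def four_state_test_preset() -> ModelPotential:
    """Low-barrier four-state surface used for converged desk-scale runs."""
    return make_four_state_potential(depths=(30.0, 20.0, 28.0, 15.0), concentrations=6.0)


def pr_like_preset() -> ModelPotential:
    """Phantom resting-state landscape: global amplitude 140 kJ/mol.

    S_h (the resting-form X-ray basin) is deepest; S_m lies 25 kJ/mol
    above it.  Pipeline self-consistency fixture only, not a
    reproduction of any measured landscape.
    """
    return make_four_state_potential(
        depths=(115.0, 140.0, 75.0, 85.0),  # S_m, S_h, S_v, S_c
        concentrations=6.0,
    )


def pfr_like_preset() -> ModelPotential:
    """Phantom illuminated-state landscape: global amplitude 125 kJ/mol, S_m deepest."""
    return make_four_state_potential(
        depths=(125.0, 123.0, 65.0, 55.0),  # S_m, S_h, S_v, S_c
        concentrations=6.0,
    )
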