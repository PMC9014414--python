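"""Geometric collective variables: dihedral angles, planar angles, wrapping.

The two CVs driving the photoisomerization workflow are the dihedral
angles about the double (Phi) and single (Psi) carbon bonds linking the
chromophore's C- and D-ring pyrroles; the in-plane rotation angle is a
three-point planar angle quantifying rotation of the chromophore plane
relative to a protein anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import CVTrajectory

__all__ = ["CVDefinition", "dihedral", "inplane_angle", "wrap_periodic", "compute_cv_series"]


@dataclass(frozen=True)
class CVDefinition:
    """A named geometric observable over trajectory atom indices (0-based)."""

    kind: str  # "dihedral" | "planar_angle"
    atoms: tuple[int, ...]
    label: str

    def __post_init__(self):
        arity = {"dihedral": 4, "planar_angle": 3}.get(self.kind)
        if arity is None:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if len(self.atoms) != arity:
            raise ValueError(f"{self.kind} requires {arity} atom indices, got {len(self.atoms)}")


def wrap_periodic(x):
    """Wrap angle(s) to [-pi, pi); idempotent; pi maps to -pi."""
    x = np.asarray(x, dtype=float)
    wrapped = np.mod(x + np.pi, 2.0 * np.pi) - np.pi
    return float(wrapped) if wrapped.ndim == 0 else wrapped


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (IUPAC convention) in [-pi, pi).

    Uses the atan2 formulation: with b1 = p2-p1, b2 = p3-p2, b3 = p4-p3,
    theta = atan2(|b2| b1 . (b2 x b3), (b1 x b2) . (b2 x b3)).
    A planar cis arrangement gives 0, trans gives -pi (pi wrapped).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12:
        raise ValueError("degenerate dihedral: central bond has zero length")
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate dihedral: three consecutive points are collinear")
    return float(wrap_periodic(np.arctan2(b2n * np.dot(b1, n2), np.dot(n1, n2))))


def inplane_angle(a, b, c) -> float:
    """Angle at vertex b between rays b->a and b->c, in [0, pi]."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u = a - b
    v = c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("degenerate planar angle: zero-length ray")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cosang))


def compute_cv_series(traj, defs: list[CVDefinition]) -> CVTrajectory:
    """Evaluate CV definitions on every frame of an atom trajectory.

    Returns a CV series with one column per definition label, preserving
    frame times; the bias column is zero (unbiased data).
    """
    labels = [d.label for d in defs]
    if len(set(labels)) != len(labels):
        raise ValueError("CV labels must be unique")
    n_atoms = traj.coords.shape[1]
    for d in defs:
        if any(i < 0 or i >= n_atoms for i in d.atoms):
            raise ValueError(f"CV {d.label!r}: atom index out of range")
    columns: dict[str, np.ndarray] = {lab: np.empty(traj.n_frames) for lab in labels}
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        for d in defs:
            pts = [xyz[i] for i in d.atoms]
            if d.kind == "dihedral":
                columns[d.label][f] = dihedral(*pts)
            else:
                columns[d.label][f] = inplane_angle(*pts)
    return CVTrajectory(traj.frame_times.copy(), columns)
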