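"""Trajectory-level structural observables.

Superposition RMSD (Kabsch least-squares fit on a chosen atom set),
per-residue RMSF, geometric hydrogen-bond count distributions, and
residue-residue close-contact frequencies.  The H-bond criterion is
the common geometric one -- donor-acceptor distance <= 0.35 nm and
H-D-A angle <= 30 degrees -- since different analysis packages vary
only slightly around it; both parameters are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cvs import inplane_angle
from .toyprotein import AtomTrajectory

__all__ = [
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "hbond_counts",
    "contact_frequency",
    "ContactMatrix",
    "HBOND_R_CUT",
    "HBOND_ANGLE_CUT",
    "CONTACT_R_CUT",
]

HBOND_R_CUT = 0.35  # nm, donor-acceptor
HBOND_ANGLE_CUT = np.deg2rad(30.0)  # H-D-A
CONTACT_R_CUT = 0.35  # nm, closest heavy atoms


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray, fit_indices=None):
    """Optimal rigid transform (proper rotation R, translation t) mapping
    ``mobile`` onto ``reference`` in the least-squares sense over
    ``fit_indices``; apply as x @ R.T + t."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.arange(mobile.shape[0]) if fit_indices is None else np.asarray(fit_indices)
    if idx.size < 3:
        raise ValueError("need at least 3 fit atoms")
    x = mobile[idx]
    y = reference[idx]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    if np.linalg.matrix_rank(xc, tol=1e-10) < 2:
        raise ValueError("degenerate fit set: fit atoms are collinear or coincident")
    h = xc.T @ yc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = y.mean(axis=0) - x.mean(axis=0) @ rot.T
    return rot, trans


def _superposed(traj: AtomTrajectory, reference: np.ndarray, fit_indices) -> np.ndarray:
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        rot, trans = kabsch_superpose(traj.coords[f], reference, fit_indices)
        out[f] = traj.coords[f] @ rot.T + trans
    return out


def rmsd_series(
    traj: AtomTrajectory,
    reference: np.ndarray,
    fit_indices=None,
    measure_indices=None,
) -> np.ndarray:
    """Per-frame RMSD (nm) over ``measure_indices`` after fitting each
    frame to the reference on ``fit_indices``."""
    reference = np.asarray(reference, dtype=float)
    measure = (
        np.arange(traj.n_atoms) if measure_indices is None else np.asarray(measure_indices)
    )
    fitted = _superposed(traj, reference, fit_indices)
    diff = fitted[:, measure, :] - reference[measure]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


def rmsf_per_residue(traj: AtomTrajectory, fit_indices=None) -> dict[int, float]:
    """Per-residue RMSF (nm): superpose all frames on the first frame,
    take each atom's RMS deviation from its time-average position, then
    average atoms within each residue."""
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    fitted = _superposed(traj, traj.coords[0], fit_indices)
    mean_pos = fitted.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((fitted - mean_pos) ** 2, axis=2), axis=0))
    out: dict[int, float] = {}
    for resid in np.unique(traj.residue_ids):
        atoms = traj.atom_indices_of_residue(int(resid))
        out[int(resid)] = float(per_atom[atoms].mean())
    return out


def hbond_counts(
    traj: AtomTrajectory,
    donor_triples,
    r_cut: float = HBOND_R_CUT,
    angle_cut: float = HBOND_ANGLE_CUT,
) -> tuple[np.ndarray, dict[int, float]]:
    """Per-frame hydrogen-bond counts and the normalized count histogram.

    ``donor_triples`` is a sequence of (donor, hydrogen, acceptor) atom
    index triples; a bond is present in a frame iff dist(D, A) <= r_cut
    and the H-D-A angle <= angle_cut.
    """
    triples = [tuple(t) for t in donor_triples]
    for t in triples:
        if len(t) != 3 or max(t) >= traj.n_atoms or min(t) < 0:
            raise ValueError(f"invalid donor-hydrogen-acceptor triple {t}")
    counts = np.zeros(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        for d, h, a in triples:
            if np.linalg.norm(xyz[a] - xyz[d]) > r_cut:
                continue
            if inplane_angle(xyz[h], xyz[d], xyz[a]) <= angle_cut:
                counts[f] += 1
    values, freq = np.unique(counts, return_counts=True)
    hist = {int(v): float(c) / traj.n_frames for v, c in zip(values, freq)}
    return counts, hist


@dataclass
class ContactMatrix:
    """Symmetric residue-pair contact frequencies in [0, 1]."""

    residues: np.ndarray
    frequencies: np.ndarray  # (n_res, n_res), diagonal zero
    cutoff: float
    n_frames: int

    def frequency(self, res_i: int, res_j: int) -> float:
        i = int(np.flatnonzero(self.residues == res_i)[0])
        j = int(np.flatnonzero(self.residues == res_j)[0])
        return float(self.frequencies[i, j])


def contact_frequency(
    traj: AtomTrajectory,
    r_cut: float = CONTACT_R_CUT,
    heavy_only: bool = True,
    exclusion_window: int = 1,
) -> ContactMatrix:
    """Residue-residue close-contact occurrence frequencies.

    Two residues are in contact in a frame iff their minimum (heavy-)
    atom pair distance is <= r_cut; pairs within ``exclusion_window`` in
    sequence are excluded.
    """
    residues = np.unique(traj.residue_ids)
    n_res = residues.size
    atom_mask = traj.heavy_atom_mask() if heavy_only else np.ones(traj.n_atoms, dtype=bool)
    groups = [
        np.flatnonzero((traj.residue_ids == r) & atom_mask) for r in residues
    ]
    in_contact = np.zeros((n_res, n_res), dtype=int)
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        for i in range(n_res):
            gi = groups[i]
            if gi.size == 0:
                continue
            for j in range(i + 1, n_res):
                if abs(int(residues[j]) - int(residues[i])) <= exclusion_window:
                    continue
                gj = groups[j]
                if gj.size == 0:
                    continue
                d = np.linalg.norm(xyz[gi][:, None, :] - xyz[gj][None, :, :], axis=2)
                if d.min() <= r_cut:
                    in_contact[i, j] += 1
                    in_contact[j, i] += 1
    freq = in_contact / traj.n_frames
    return ContactMatrix(residues, freq, r_cut, traj.n_frames)
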