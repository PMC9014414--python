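"""Toy-protein coordinate trajectories with plantable structural features.

A minimal surrogate for atomistic trajectories: a chain of four-atom
residues (N, H, CA, O) laid out along x, plus a special chromophore-like
residue carrying a driven dihedral quadruple.  The generator can plant

* a programmed dihedral angle series (exact before noise),
* a mobile region with isotropic Gaussian jitter,
* donor-H-acceptor hydrogen-bond geometries present in a stated
  fraction of frames,
* residue-residue contacts at a stated distance and frame fraction,

so that every structural observable downstream has a constructable
ground truth.  Coordinates are nm; PDB output converts to Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AtomTrajectory",
    "PlantedHBond",
    "PlantedContact",
    "ToyProteinSpec",
    "make_toy_protein_trajectory",
    "write_pdb",
    "read_pdb",
]

ATOMS_PER_RESIDUE = ("N", "H", "CA", "O")
_RESIDUE_SPACING = 0.5  # nm along x
_LIGAND_Z = 1.0  # nm offset of the driven-dihedral quadruple


@dataclass
class AtomTrajectory:
    """frames x atoms x 3 coordinates (nm) plus atom/residue metadata."""

    coords: np.ndarray
    atom_names: list[str]
    residue_ids: np.ndarray
    residue_names: list[str]
    frame_times: np.ndarray = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        n_atoms = self.coords.shape[1]
        if len(self.atom_names) != n_atoms or len(self.residue_names) != n_atoms:
            raise ValueError("metadata length must match atom count")
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if np.any(np.diff(self.residue_ids) < 0):
            raise ValueError("residue indices must be non-decreasing along the chain")
        if self.frame_times is None:
            self.frame_times = np.arange(self.coords.shape[0], dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_indices_of_residue(self, resid: int) -> np.ndarray:
        return np.flatnonzero(self.residue_ids == resid)

    def heavy_atom_mask(self) -> np.ndarray:
        return np.array([not name.startswith("H") for name in self.atom_names])


@dataclass(frozen=True)
class PlantedHBond:
    """Donor-H-acceptor triple planted collinear at ``distance`` (D-A, nm)
    in a ``fraction`` of frames; the acceptor is parked far away otherwise."""

    donor: int
    hydrogen: int
    acceptor: int
    distance: float = 0.28
    fraction: float = 1.0


@dataclass(frozen=True)
class PlantedContact:
    """Residue pair brought to ``distance`` (nm, closest atoms) in a
    ``fraction`` of frames and separated otherwise."""

    residue_i: int
    residue_j: int
    distance: float = 0.30
    fraction: float = 1.0


@dataclass
class ToyProteinSpec:
    n_residues: int = 20
    n_frames: int = 100
    mobile_residues: tuple[int, ...] = ()
    jitter_sigma: float = 0.0  # nm, isotropic per coordinate
    #: programmed torsion values (rad), one per frame, for the ligand quadruple
    driven_dihedral_series: np.ndarray | None = None
    hbonds: tuple[PlantedHBond, ...] = ()
    contacts: tuple[PlantedContact, ...] = ()


def _base_structure(n_residues: int):
    names, resids, resnames, xyz = [], [], [], []
    offsets = {
        "N": (0.0, 0.0, 0.0),
        "H": (0.0, 0.1, 0.0),
        "CA": (0.15, 0.0, 0.0),
        "O": (0.30, -0.1, 0.0),
    }
    for r in range(n_residues):
        x0 = r * _RESIDUE_SPACING
        for name in ATOMS_PER_RESIDUE:
            names.append(name)
            resids.append(r)
            resnames.append("GLY")
            dx, dy, dz = offsets[name]
            xyz.append((x0 + dx, dy, dz))
    return names, np.array(resids), resnames, np.array(xyz)


def _planted_frames(fraction: float, n_frames: int) -> np.ndarray:
    k = int(round(fraction * n_frames))
    out = np.zeros(n_frames, dtype=bool)
    out[:k] = True
    return out


def make_toy_protein_trajectory(spec: ToyProteinSpec, seed: int = 0) -> AtomTrajectory:
    """Generate a trajectory realizing the planted features of ``spec``.

    The driven dihedral quadruple is appended as a separate ligand
    residue (resname CHR, atoms C1-C4, indices n_residues*4 ..
    n_residues*4+3) with p1=(0.3,0,z), p2=(0,0,z), p3=(0,0,z+0.3),
    p4=0.3*(cos t, sin t, .)+p3, whose torsion equals the programmed
    angle exactly before noise.
    """
    names, resids, resnames, base = _base_structure(spec.n_residues)
    series = spec.driven_dihedral_series
    n_frames = spec.n_frames if series is None else len(series)
    if series is not None:
        lig_res = spec.n_residues
        names += ["C1", "C2", "C3", "C4"]
        resids = np.concatenate([resids, [lig_res] * 4])
        resnames += ["CHR"] * 4
        lig = np.array([
            (0.3, 0.0, _LIGAND_Z),
            (0.0, 0.0, _LIGAND_Z),
            (0.0, 0.0, _LIGAND_Z + 0.3),
            (0.3, 0.0, _LIGAND_Z + 0.3),
        ])
        base = np.vstack([base, lig])
    n_atoms = base.shape[0]
    for res in spec.mobile_residues:
        if res < 0 or res >= spec.n_residues:
            raise ValueError(f"mobile residue {res} out of range")
    for hb in spec.hbonds:
        if max(hb.donor, hb.hydrogen, hb.acceptor) >= n_atoms:
            raise ValueError("H-bond atom index out of range")
    for ct in spec.contacts:
        if max(ct.residue_i, ct.residue_j) >= spec.n_residues:
            raise ValueError("contact residue index out of range")

    rng = np.random.default_rng(seed)
    coords = np.repeat(base[None, :, :], n_frames, axis=0)

    if series is not None:
        theta = np.asarray(series, dtype=float)
        i4 = n_atoms - 1
        coords[:, i4, 0] = 0.3 * np.cos(theta)
        coords[:, i4, 1] = 0.3 * np.sin(theta)

    for hb in spec.hbonds:
        on = _planted_frames(hb.fraction, n_frames)
        d_pos = coords[:, hb.donor, :]
        h_pos = coords[:, hb.hydrogen, :]
        u = h_pos - d_pos
        norms = np.linalg.norm(u, axis=1, keepdims=True)
        u = u / np.where(norms > 0, norms, 1.0)
        coords[on, hb.acceptor, :] = d_pos[on] + hb.distance * u[on]
        coords[~on, hb.acceptor, :] = d_pos[~on] + np.array([0.0, 0.0, -2.0])

    for ct in spec.contacts:
        on = _planted_frames(ct.fraction, n_frames)
        src = np.flatnonzero(resids == ct.residue_i)[0]  # residue_i N atom
        tgt = np.flatnonzero(resids == ct.residue_j)[-1]  # residue_j O atom
        anchor = coords[:, src, :]
        coords[on, tgt, :] = anchor[on] + np.array([0.0, 0.0, 1.0]) * ct.distance
        coords[~on, tgt, :] = anchor[~on] + np.array([0.0, 0.0, 1.0])

    if spec.jitter_sigma > 0 and spec.mobile_residues:
        mobile_atoms = np.flatnonzero(np.isin(resids, spec.mobile_residues))
        coords[:, mobile_atoms, :] += rng.normal(
            0.0, spec.jitter_sigma, size=(n_frames, mobile_atoms.size, 3)
        )

    return AtomTrajectory(coords, names, resids, resnames, np.arange(n_frames, dtype=float))


def write_pdb(traj: AtomTrajectory, path) -> None:
    """Minimal multi-model PDB (MODEL/ATOM/ENDMDL), coordinates in Angstrom."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a] * 10.0
                fh.write(
                    "ATOM  {serial:5d} {name:<4s} {res:<3s} A{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}\n".format(
                        serial=a + 1,
                        name=traj.atom_names[a][:4],
                        res=traj.residue_names[a][:3],
                        resid=int(traj.residue_ids[a]) + 1,
                        x=x, y=y, z=z,
                    )
                )
            fh.write("ENDMDL\n")


def read_pdb(path) -> AtomTrajectory:
    """Read the minimal multi-model PDB written by :func:`write_pdb`."""
    frames = []
    names: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    current = None
    first = True
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                current = []
            elif line.startswith("ATOM"):
                if current is None:
                    raise ValueError("ATOM record outside MODEL block")
                if first:
                    names.append(line[12:16].strip())
                    resnames.append(line[17:20].strip())
                    resids.append(int(line[22:26]) - 1)
                x = float(line[30:38]) / 10.0
                y = float(line[38:46]) / 10.0
                z = float(line[46:54]) / 10.0
                current.append((x, y, z))
            elif line.startswith("ENDMDL"):
                frames.append(current)
                current = None
                first = False
    if not frames:
        raise ValueError(f"{path}: no MODEL/ENDMDL blocks found")
    return AtomTrajectory(np.array(frames), names, np.array(resids), resnames)
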