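"""Free-energy landscapes from biased CV samples by umbrella reweighting.

Each stored sample carries the bias energy V it experienced at
sampling time; its statistical weight is e^{beta V}.  Weights are
scaled to [0, 1] (divided by their maximum) for numerical stability,
a leading burn-in fraction is discarded because the adaptive bias --
hence the weights -- is not yet equilibrated early in a run, and the
unbiased density is estimated by a weighted histogram:

    F(bin) = -(1/beta) ln p_hat(bin),  min finite F pinned to 0.

Empty bins are flagged (NaN) and excluded from all arithmetic rather
than being filled with a large placeholder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, beta as beta_of
from .trajectory import CVTrajectory

__all__ = [
    "WeightedSamples",
    "FESGrid",
    "compute_weights",
    "estimate_fes_2d",
    "marginal_profile",
    "global_barrier",
    "minimax_path_barrier",
    "write_fes",
    "read_fes",
]


@dataclass
class WeightedSamples:
    """CV samples with reweighting weights and a burn-in mask."""

    times: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    bias: np.ndarray
    weights: np.ndarray  # scaled to [0, 1]; max over unmasked = 1
    mask: np.ndarray  # True = kept (survives burn-in)
    beta: float

    @property
    def raw_weights(self) -> np.ndarray:
        """Unscaled e^{beta V}; may be astronomically large for deep biases."""
        return np.exp(self.beta * self.bias)

    def n_unmasked(self) -> int:
        return int(np.count_nonzero(self.mask))

    def subset(self, keep: np.ndarray) -> "WeightedSamples":
        """Restrict to ``keep`` (bool mask or index array) and re-scale weights."""
        ws = WeightedSamples(
            self.times[keep], self.phi[keep], self.psi[keep],
            self.bias[keep], self.weights[keep], self.mask[keep], self.beta,
        )
        if ws.n_unmasked() == 0:
            raise ValueError("subset leaves no unmasked samples")
        ws.weights = ws.weights / ws.weights[ws.mask].max()
        return ws


def compute_weights(
    traj: CVTrajectory,
    beta: float | None = None,
    burn_in_fraction: float = 0.02,
    temperature: float = DEFAULT_TEMPERATURE,
) -> WeightedSamples:
    """Statistical weights e^{beta V} from the recorded bias energies.

    The leading ``burn_in_fraction`` of rows is masked out.  Weights are
    computed as exp(beta (V - max V)) so the scaled maximum is exactly 1
    regardless of how deep the converged bias is.
    """
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    if beta is None:
        beta = beta_of(temperature)
    n = len(traj)
    n_burn = int(np.floor(burn_in_fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[n_burn:] = True
    if not mask.any():
        raise ValueError("burn-in masks every sample")
    v = traj.bias
    vmax = v[mask].max()
    weights = np.exp(beta * (v - vmax))
    return WeightedSamples(traj.times, traj.phi, traj.psi, v, weights, mask, beta)


@dataclass
class FESGrid:
    """Free energy on a regular periodic grid over [-pi, pi)^2.

    ``values`` is (nbins, nbins) kJ/mol with NaN flagging empty bins;
    bin 0 is adjacent to bin n-1 along both axes.
    """

    edges_phi: np.ndarray
    edges_psi: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    beta: float

    @property
    def nbins(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def centers_phi(self) -> np.ndarray:
        return 0.5 * (self.edges_phi[:-1] + self.edges_phi[1:])

    @property
    def centers_psi(self) -> np.ndarray:
        return 0.5 * (self.edges_psi[:-1] + self.edges_psi[1:])

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def bin_of(self, phi: float, psi: float) -> tuple[int, int]:
        i = int(np.searchsorted(self.edges_phi, phi, side="right")) - 1
        j = int(np.searchsorted(self.edges_psi, psi, side="right")) - 1
        i = np.clip(i, 0, self.values.shape[0] - 1)
        j = np.clip(j, 0, self.values.shape[1] - 1)
        return i, j


def estimate_fes_2d(ws: WeightedSamples, nbins: int = 100) -> FESGrid:
    """Weighted-histogram FES estimate; deepest finite bin pinned at 0."""
    edges = np.linspace(-np.pi, np.pi, nbins + 1)
    phi = ws.phi[ws.mask]
    psi = ws.psi[ws.mask]
    w = ws.weights[ws.mask]
    if phi.size == 0:
        raise ValueError("no unmasked samples")
    hist, _, _ = np.histogram2d(phi, psi, bins=(edges, edges), weights=w)
    counts, _, _ = np.histogram2d(phi, psi, bins=(edges, edges))
    total = hist.sum()
    if total <= 0:
        raise ValueError("no occupied bins")
    with np.errstate(divide="ignore"):
        f = -np.log(hist / total) / ws.beta
    f[hist == 0] = np.nan
    f -= np.nanmin(f)
    return FESGrid(edges, edges.copy(), f, counts.astype(int), ws.beta)


def marginal_profile(fes: FESGrid, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """1D profile along ``axis`` by integrating out the other CV.

    F1(x) = -(1/beta) ln sum_y e^{-beta F(x,y)} over finite bins,
    re-shifted to min 0.  Returns (bin centers, profile); coordinates
    with no finite bin are NaN.
    """
    f = fes.values if axis == 0 else fes.values.T
    centers = fes.centers_phi if axis == 0 else fes.centers_psi
    out = np.full(f.shape[0], np.nan)
    for i in range(f.shape[0]):
        row = f[i][np.isfinite(f[i])]
        if row.size:
            m = row.min()
            out[i] = m - np.log(np.exp(-fes.beta * (row - m)).sum()) / fes.beta
    if np.all(np.isnan(out)):
        raise ValueError("no finite bins along the requested axis")
    out -= np.nanmin(out)
    return centers, out


def global_barrier(fes: FESGrid) -> float:
    """Max finite F minus min finite F (the latter is 0 by construction)."""
    finite = fes.values[fes.finite_mask()]
    if finite.size == 0:
        raise ValueError("grid has no finite bins")
    return float(finite.max() - finite.min())


def minimax_path_barrier(fes: FESGrid, start: tuple[int, int], end: tuple[int, int]) -> float:
    """Bottleneck barrier between two bins on the periodic grid.

    Over all 4-connected paths, minimize the maximum F along the path;
    return that saddle height minus F(start).  NaN bins are impassable.
    Computed exactly by Kruskal-style level sweeping with union-find.
    """
    f = fes.values
    ni, nj = f.shape
    si, sj = start
    ei, ej = end
    if not np.isfinite(f[si, sj]) or not np.isfinite(f[ei, ej]):
        raise ValueError("start and end bins must be finite")
    if start == tuple(end):
        return 0.0
    order = np.argsort(f, axis=None, kind="stable")
    parent = np.full(ni * nj, -1, dtype=np.int64)

    def find(a):
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    s_flat = si * nj + sj
    e_flat = ei * nj + ej
    for flat in order:
        val = f.flat[flat]
        if not np.isfinite(val):
            break  # NaNs sort last
        parent[flat] = flat
        i, j = divmod(int(flat), nj)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = ((i + di) % ni) * nj + (j + dj) % nj
            if parent[nb] >= 0:
                ra, rb = find(flat), find(nb)
                if ra != rb:
                    parent[ra] = rb
        if parent[s_flat] >= 0 and parent[e_flat] >= 0 and find(s_flat) == find(e_flat):
            return float(val - f[si, sj])
    raise ValueError("end bin is unreachable through finite bins")


def write_fes(fes: FESGrid, path) -> None:
    """Three-column (phi, psi, F) text in grid-major order with a header."""
    ni, nj = fes.values.shape
    with open(path, "w") as fh:
        fh.write(f"# torves fes nbins_phi={ni} nbins_psi={nj} beta={fes.beta!r} domain=[-pi,pi)^2\n")
        fh.write("# phi psi free_energy_kj_mol\n")
        cp, cq = fes.centers_phi, fes.centers_psi
        for i in range(ni):
            for j in range(nj):
                fh.write(f"{cp[i].item()!r} {cq[j].item()!r} {fes.values[i, j].item()!r}\n")


def read_fes(path) -> FESGrid:
    with open(path) as fh:
        header = fh.readline()
        if "torves fes" not in header:
            raise ValueError(f"{path}: not a torves FES file")
        fields = dict(tok.split("=") for tok in header.split() if "=" in tok)
        ni = int(fields["nbins_phi"])
        nj = int(fields["nbins_psi"])
        beta = float(fields["beta"])
        values = np.full((ni, nj), np.nan)
        k = 0
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _, _, v = line.split()
            values[k // nj, k % nj] = float(v)
            k += 1
    edges = np.linspace(-np.pi, np.pi, ni + 1)
    return FESGrid(edges, np.linspace(-np.pi, np.pi, nj + 1), values, np.zeros((ni, nj), dtype=int), beta)
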