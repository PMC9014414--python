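"""Convergence diagnostics for enhanced-sampling runs.

The main diagnostic is a statistical distance between whole free-energy
landscapes computed at successive time checkpoints: each grid is turned
back into a probability distribution p ~ e^{-beta F} over the jointly
finite bins and compared with the symmetrized (Jeffreys) Kullback-
Leibler divergence; Jensen-Shannon is selectable.  A run is declared
converged at the earliest checkpoint from which the sliding-window mean
absolute slope of the distance series stays below tolerance through the
end.  Also here: the late-window per-bin FES variability, bootstrap
estimation of circular means, and wrap-aware mode counting for angular
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .fes import FESGrid, WeightedSamples, estimate_fes_2d

__all__ = [
    "ConvergenceSeries",
    "fes_checkpoints",
    "statistical_distance",
    "convergence_series",
    "fes_variability",
    "bootstrap_circular",
    "count_modes",
]


@dataclass
class ConvergenceSeries:
    checkpoint_times: np.ndarray
    distances: np.ndarray  # distance of each checkpoint to its predecessor
    plateau_time: float | None
    window: int
    slope_tol: float

    @property
    def converged(self) -> bool:
        return self.plateau_time is not None


def fes_checkpoints(ws: WeightedSamples, times, nbins: int = 100) -> list[FESGrid]:
    """Cumulative FES estimates from all unmasked samples up to each time."""
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("checkpoint times must be non-decreasing")
    first_kept = ws.times[ws.mask].min()
    grids = []
    for t in times:
        if t < first_kept:
            raise ValueError(f"checkpoint {t} precedes the end of burn-in ({first_kept})")
        grids.append(estimate_fes_2d(ws.subset(ws.times <= t), nbins=nbins))
    return grids


def _prob_vectors(a: FESGrid, b: FESGrid) -> tuple[np.ndarray, np.ndarray]:
    if a.values.shape != b.values.shape or a.beta != b.beta:
        raise ValueError("grids must share shape and beta")
    joint = a.finite_mask() & b.finite_mask()
    if not joint.any():
        raise ValueError("no jointly finite bins")
    fa = a.values[joint]
    fb = b.values[joint]
    p = np.exp(-a.beta * (fa - fa.min()))
    q = np.exp(-b.beta * (fb - fb.min()))
    return p / p.sum(), q / q.sum()


def statistical_distance(fes_a: FESGrid, fes_b: FESGrid, kind: str = "jeffreys") -> float:
    """Symmetrized KL (default) or Jensen-Shannon distance between the
    Boltzmann distributions induced by two landscapes; dimensionless >= 0."""
    p, q = _prob_vectors(fes_a, fes_b)
    if kind == "jeffreys":
        return float(0.5 * (np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p))))
    if kind == "js":
        m = 0.5 * (p + q)
        return float(0.5 * np.sum(p * np.log(p / m)) + 0.5 * np.sum(q * np.log(q / m)))
    raise ValueError(f"unknown distance kind {kind!r}")


def convergence_series(
    checkpoints: list[FESGrid],
    checkpoint_times,
    window: int = 5,
    slope_tol: float = 0.01,
    kind: str = "jeffreys",
) -> ConvergenceSeries:
    """Successive-checkpoint distances with plateau detection.

    The plateau time is the earliest checkpoint time from which every
    sliding window of ``window`` successive distance slopes has mean
    absolute slope (per checkpoint interval) below ``slope_tol`` through
    the end of the series; None if never.
    """
    times = np.asarray(checkpoint_times, dtype=float)
    if len(checkpoints) != times.size:
        raise ValueError("one time per checkpoint required")
    if len(checkpoints) < 3:
        raise ValueError("need at least 3 checkpoints")
    d = np.array([
        statistical_distance(checkpoints[i - 1], checkpoints[i], kind)
        for i in range(1, len(checkpoints))
    ])
    slopes = np.abs(np.diff(d))
    if window > slopes.size:
        raise ValueError("window longer than the slope series")
    wmeans = np.convolve(slopes, np.ones(window) / window, mode="valid")
    ok = wmeans < slope_tol
    plateau = None
    # window j covers slopes j..j+window-1; require all windows from j on to comply
    for j in range(ok.size):
        if ok[j:].all():
            plateau = float(times[j + 1])  # time of the checkpoint opening the window
            break
    return ConvergenceSeries(times, d, plateau, window, slope_tol)


def fes_variability(checkpoints: list[FESGrid], window: int | None = None) -> float:
    """Mean over bins of the per-bin std of F across the last ``window``
    checkpoints (population std; jointly finite bins only), kJ/mol."""
    if window is not None:
        checkpoints = checkpoints[-window:]
    if len(checkpoints) < 2:
        raise ValueError("need at least 2 checkpoints in the window")
    stack = np.stack([c.values for c in checkpoints])
    joint = np.all(np.isfinite(stack), axis=0)
    if not joint.any():
        raise ValueError("no jointly finite bins")
    return float(np.mean(np.std(stack[:, joint], axis=0)))


def circular_mean(values: np.ndarray) -> float:
    s, c = np.mean(np.sin(values)), np.mean(np.cos(values))
    if np.hypot(s, c) < 1e-9:
        raise ValueError("mean resultant length ~ 0; circular mean undefined")
    return float(np.arctan2(s, c))


def bootstrap_circular(
    values,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap circular mean and CI half-width (radians).

    Bootstrap means are expressed as wrapped deviations from the full-
    sample mean so the interval is seam-safe; the half-width is half the
    percentile interval width.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    mean = circular_mean(values)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    s = np.mean(np.sin(values[idx]), axis=1)
    c = np.mean(np.cos(values[idx]), axis=1)
    boots = np.arctan2(s, c)
    dev = np.mod(boots - mean + np.pi, 2 * np.pi) - np.pi
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(dev, [alpha, 1.0 - alpha])
    return mean, float(0.5 * (hi - lo))


def count_modes(values, bins: int = 36, min_prominence: float = 0.05) -> int:
    """Number of peaks of the circular histogram density (wrap-aware).

    ``min_prominence`` is on the normalized density scale (uniform
    density is 1/2pi ~ 0.159); peaks are found on a tripled copy of the
    histogram and counted in the central copy.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    hist, _ = np.histogram(np.mod(values + np.pi, 2 * np.pi) - np.pi,
                           bins=bins, range=(-np.pi, np.pi), density=True)
    tiled = np.concatenate([hist, hist, hist])
    peaks, _ = find_peaks(tiled, prominence=min_prominence)
    return int(np.count_nonzero((peaks >= bins) & (peaks < 2 * bins)))
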