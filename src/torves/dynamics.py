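"""Overdamped Langevin dynamics on the torus.

Euler-Maruyama update with wrap-to-domain:

    z <- wrap(z - beta D grad(U + V) dt + sqrt(2 D dt) xi)

with xi standard normal per coordinate.  The stationary law of the
unbiased chain is the Boltzmann distribution of U, which makes the
propagator directly testable against analytic basin occupancies.
Time is measured in arbitrary step units; the scheme deliberately
carries none of the physical timescales of an atomistic engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import DEFAULT_TEMPERATURE, beta as beta_of
from .potentials import ModelPotential
from .trajectory import CVTrajectory

__all__ = ["LangevinParams", "run_langevin", "StabilityError"]

_CHUNK = 1 << 16
_EMPTY_MATRIX = np.zeros((1, 1))


class StabilityError(ValueError):
    """Single-step drift would exceed the half-domain width."""


@dataclass(frozen=True)
class LangevinParams:
    """Parameters of the overdamped propagator.

    diffusion is in rad^2 per time unit; time_step in time units.
    """

    temperature: float = DEFAULT_TEMPERATURE
    diffusion: float = 0.1
    time_step: float = 0.01
    n_steps: int = 100_000
    record_stride: int = 10
    seed: int = 0
    start: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.temperature <= 0 or self.diffusion <= 0 or self.time_step <= 0:
            raise ValueError("temperature, diffusion and time_step must be positive")
        if self.n_steps < 1 or self.record_stride < 1:
            raise ValueError("n_steps and record_stride must be >= 1")

    @property
    def beta(self) -> float:
        return beta_of(self.temperature)


def check_stability(potential: ModelPotential, params: LangevinParams, bias=None) -> None:
    """Refuse parameter sets whose deterministic drift can exceed pi per step."""
    max_grad = potential.max_gradient_norm()
    if bias is not None:
        max_grad += bias.max_gradient_norm()
    drift = params.time_step * params.diffusion * params.beta * max_grad
    if drift >= np.pi:
        max_dt = np.pi / (params.diffusion * params.beta * max_grad)
        raise StabilityError(
            f"single-step drift {drift:.3g} rad >= pi; "
            f"largest usable time_step is {max_dt:.3g} time units"
        )


def _bias_matrix(bias) -> np.ndarray:
    if bias is None:
        return _EMPTY_MATRIX
    return np.ascontiguousarray(bias.coeffs, dtype=float)


def _potential_matrix(potential: ModelPotential) -> np.ndarray:
    if potential.fourier:
        return np.ascontiguousarray(potential.fourier_coeff_matrix())
    return _EMPTY_MATRIX


def run_langevin(
    potential: ModelPotential,
    bias,
    params: LangevinParams,
) -> CVTrajectory:
    """Propagate and record (time, phi, psi, bias) every record_stride steps.

    ``bias`` is a :class:`torves.ves.BiasModel` or None.  Identical
    seeds give bitwise-identical trajectories.
    """
    check_stability(potential, params, bias)
    rng = np.random.default_rng(params.seed)
    n_rec = params.n_steps // params.record_stride
    rec_t = np.empty(n_rec)
    rec_phi = np.empty(n_rec)
    rec_psi = np.empty(n_rec)
    rec_bias = np.empty(n_rec)
    fsum = np.zeros((1, 1))
    wells = np.ascontiguousarray(potential.wells)
    pot_c = _potential_matrix(potential)
    bias_c = _bias_matrix(bias)
    sigma = np.sqrt(2.0 * params.diffusion * params.time_step)
    phi, psi = float(params.start[0]), float(params.start[1])
    done = 0
    written = 0
    while done < params.n_steps:
        n = min(_CHUNK, params.n_steps - done)
        noise = rng.standard_normal((n, 2)) * sigma
        phi, psi, nrec = _kernels.propagate(
            phi, psi, wells, pot_c, bias_c,
            params.beta, params.diffusion, params.time_step,
            noise, done, params.record_stride,
            rec_t, rec_phi, rec_psi, rec_bias, written,
            fsum, False,
        )
        written += nrec
        done += n
    return CVTrajectory(rec_t[:written], {"phi": rec_phi[:written], "psi": rec_psi[:written]}, rec_bias[:written])
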