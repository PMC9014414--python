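"""Variationally enhanced sampling over two periodic collective variables.

A Fourier-series bias V_a(z) acting on (Phi, Psi) is optimized so that
the biased marginal approaches a chosen target distribution (uniform
here).  The convex functional

    Omega[V] = (1/beta) ln ( int e^{-beta(F+V)} / int e^{-beta F} )
               + int p_T(z) V(z) dz

has the gradient, for basis coefficients a_k of V = sum_k a_k f_k,

    dOmega/da_k = -<f_k>_{biased} + <f_k>_{p_T},

estimated per update from the samples collected during the preceding
stride.  Coefficients are updated by stochastic gradient descent.
Three iterate-averaging modes are available:

* ``"suffix"`` (default): the instantaneous iterates define the acting
  bias; the reported bias is the running mean of the iterates from
  ``averaging_start`` (default: mid-run) onward.  Suffix averaging
  discards the optimisation ramp, whose pollution otherwise decays
  only like 1/t, and averages the stationary SGD fluctuations away.
* ``"full"``: classic iterate averaging -- the running mean over all
  iterations both acts on the dynamics and is reported.
* ``"none"``: plain SGD; the final instantaneous iterate is reported.

For a uniform target, a converged bias satisfies V = -U + const on
the span of the basis, which is the recovery property the tests score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .basis import (
    axis_design_matrix,
    basis_functions,
    describe_axis_function,
    flat_index,
    n_axis_functions,
)
from .dynamics import LangevinParams, check_stability, _potential_matrix
from .potentials import ModelPotential
from .trajectory import CVTrajectory

__all__ = [
    "basis_functions",
    "BiasModel",
    "TargetDistribution",
    "OptimizerState",
    "omega_gradient",
    "sgd_update",
    "run_ves",
    "VESResult",
    "save_bias",
    "load_bias",
]


@dataclass(frozen=True)
class BiasModel:
    """Fourier bias V(z) with real cos/sin product coefficients (kJ/mol).

    ``coeffs`` has shape (2N+1, 2N+1) in the ordering of
    :mod:`torves.basis`; zero coefficients mean V = 0.
    """

    order: int
    coeffs: np.ndarray = None

    def __post_init__(self):
        m = n_axis_functions(self.order)
        coeffs = self.coeffs
        if coeffs is None:
            coeffs = np.zeros((m, m))
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape != (m, m):
            raise ValueError(f"coefficient matrix must be {(m, m)}, got {coeffs.shape}")
        object.__setattr__(self, "coeffs", coeffs)

    @property
    def n_basis(self) -> int:
        return n_axis_functions(self.order) ** 2

    def coefficient(self, k1: int, kind1: str, k2: int, kind2: str) -> float:
        m = n_axis_functions(self.order)
        idx = flat_index(k1, kind1, k2, kind2, self.order)
        return float(self.coeffs[idx // m, idx % m])

    def evaluate(self, phi, psi) -> np.ndarray:
        """V at (arrays of) torus points, kJ/mol."""
        scalar = np.isscalar(phi) and np.isscalar(psi)
        phi = np.atleast_1d(np.asarray(phi, dtype=float))
        psi = np.atleast_1d(np.asarray(psi, dtype=float))
        fp = axis_design_matrix(phi.ravel(), self.order)
        fq = axis_design_matrix(psi.ravel(), self.order)
        out = np.einsum("ni,ij,nj->n", fp, self.coeffs, fq).reshape(phi.shape)
        return out.item() if scalar else out

    def gradient(self, phi, psi) -> tuple[np.ndarray, np.ndarray]:
        phi = np.atleast_1d(np.asarray(phi, dtype=float))
        psi = np.atleast_1d(np.asarray(psi, dtype=float))
        fp = axis_design_matrix(phi.ravel(), self.order)
        fq = axis_design_matrix(psi.ravel(), self.order)
        dfp = axis_design_matrix(phi.ravel(), self.order, derivative=True)
        dfq = axis_design_matrix(psi.ravel(), self.order, derivative=True)
        gp = np.einsum("ni,ij,nj->n", dfp, self.coeffs, fq).reshape(phi.shape)
        gq = np.einsum("ni,ij,nj->n", fp, self.coeffs, dfq).reshape(phi.shape)
        return gp, gq

    def max_gradient_norm(self, n_grid: int = 129) -> float:
        x = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
        pp, qq = np.meshgrid(x, x, indexing="ij")
        gp, gq = self.gradient(pp, qq)
        return float(np.max(np.hypot(gp, gq)))


def evaluate_bias(b: BiasModel, z) -> float:
    """V at a single torus point (dot product with the basis vector)."""
    return float(b.evaluate(z[0], z[1]))


@dataclass(frozen=True)
class TargetDistribution:
    """Target marginal of the biased sampling; only 'uniform' is implemented."""

    kind: str = "uniform"

    def __post_init__(self):
        if self.kind != "uniform":
            raise NotImplementedError("only the uniform target distribution is implemented")

    def basis_expectations(self, order: int) -> np.ndarray:
        """<f_k>_{p_T} in matrix layout: 1 on the constant, 0 elsewhere."""
        m = n_axis_functions(order)
        out = np.zeros((m, m))
        out[0, 0] = 1.0
        return out


@dataclass(frozen=True)
class OptimizerState:
    """SGD state: instantaneous iterate plus the running mean of the
    iterates over the completed averaged iterations."""

    order: int
    learning_rate: float = 0.1
    stride: int = 1000
    iteration: int = 0
    n_averaged: int = 0
    alpha_inst: np.ndarray = None
    alpha_avg: np.ndarray = None

    def __post_init__(self):
        m = n_axis_functions(self.order)
        for name in ("alpha_inst", "alpha_avg"):
            a = getattr(self, name)
            a = np.zeros((m, m)) if a is None else np.asarray(a, dtype=float)
            if a.shape != (m, m):
                raise ValueError(f"{name} must have shape {(m, m)}")
            object.__setattr__(self, name, a)


def omega_gradient(
    batch_phi,
    batch_psi,
    order: int,
    target: TargetDistribution = TargetDistribution(),
) -> np.ndarray:
    """Stochastic gradient of Omega w.r.t. the coefficient matrix.

    ``batch_phi/psi`` are CV samples from the biased run; the biased
    expectation of each basis function is estimated by the batch mean.
    """
    batch_phi = np.asarray(batch_phi, dtype=float)
    batch_psi = np.asarray(batch_psi, dtype=float)
    if batch_phi.size == 0:
        raise ValueError("gradient batch is empty")
    fp = axis_design_matrix(batch_phi, order)
    fq = axis_design_matrix(batch_psi, order)
    mean_f = fp.T @ fq / batch_phi.size
    return -mean_f + target.basis_expectations(order)


def sgd_update(state: OptimizerState, grad: np.ndarray, update_average: bool = True) -> OptimizerState:
    """One SGD step: inst <- inst - mu*grad; optionally fold the new
    iterate into the running mean (suffix averaging skips the ramp)."""
    grad = np.asarray(grad, dtype=float)
    if grad.shape != state.alpha_inst.shape:
        raise ValueError("gradient dimensions do not match the coefficient matrix")
    inst = state.alpha_inst - state.learning_rate * grad
    it = state.iteration + 1
    if update_average:
        n_avg = state.n_averaged + 1
        avg = state.alpha_avg + (inst - state.alpha_avg) / n_avg
    else:
        n_avg = state.n_averaged
        avg = state.alpha_avg
    return replace(state, iteration=it, n_averaged=n_avg, alpha_inst=inst, alpha_avg=avg)


@dataclass
class VESResult:
    trajectory: CVTrajectory
    bias: BiasModel
    optimizer: OptimizerState
    #: (iteration, alpha_avg copy) snapshots, every ``history_stride`` updates.
    history: list = field(default_factory=list)


def run_ves(
    potential: ModelPotential,
    params: LangevinParams,
    order: int = 10,
    learning_rate: float = 0.1,
    stride: int = 1000,
    n_iterations: int = 500,
    target: TargetDistribution = TargetDistribution(),
    averaging: str = "suffix",
    averaging_start: int | None = None,
    production_iterations: int | None = None,
    history_stride: int = 50,
) -> VESResult:
    """Alternate ``stride`` Langevin steps under the acting bias with one
    gradient/update cycle; ``params.n_steps`` is ignored (the run length
    is stride * n_iterations).

    ``averaging`` selects the iterate-averaging mode (module docstring);
    ``averaging_start`` (suffix mode) is the first averaged iteration,
    default ``n_iterations // 2``.  After the optimisation phase the
    final bias is frozen and ``production_iterations`` further strides
    are sampled under it (default: as many as the optimisation phase);
    a static production bias keeps the reweighting weights' effective
    sample size high, whereas weights recorded under a still-moving
    bias fluctuate exponentially.  The recorded bias column holds the
    acting bias evaluated at each stored sample at its sampling time,
    which is what reweighting needs; discarding the optimisation phase
    as burn-in (a fraction of 0.5 with the default lengths) mirrors the
    usual discard of the weight-equilibration period.
    """
    if averaging not in ("suffix", "full", "none"):
        raise ValueError(f"unknown averaging mode {averaging!r}")
    if averaging_start is None:
        averaging_start = n_iterations // 2 if averaging == "suffix" else 0
    if production_iterations is None:
        production_iterations = n_iterations
    state = OptimizerState(order, learning_rate, stride)
    check_stability(potential, params)
    rng = np.random.default_rng(params.seed)
    m = n_axis_functions(order)
    total_steps = stride * (n_iterations + production_iterations)
    n_rec = total_steps // params.record_stride
    rec_t = np.empty(n_rec)
    rec_phi = np.empty(n_rec)
    rec_psi = np.empty(n_rec)
    rec_bias = np.empty(n_rec)
    wells = np.ascontiguousarray(potential.wells)
    pot_c = _potential_matrix(potential)
    sigma = np.sqrt(2.0 * params.diffusion * params.time_step)
    target_f = target.basis_expectations(order)
    phi, psi = float(params.start[0]), float(params.start[1])
    written = 0
    history = []
    for it in range(n_iterations):
        acting = state.alpha_avg if averaging == "full" else state.alpha_inst
        bias_c = np.ascontiguousarray(acting)
        fsum = np.zeros((m, m))
        noise = rng.standard_normal((stride, 2)) * sigma
        phi, psi, nrec = _kernels.propagate(
            phi, psi, wells, pot_c, bias_c,
            params.beta, params.diffusion, params.time_step,
            noise, it * stride, params.record_stride,
            rec_t, rec_phi, rec_psi, rec_bias, written,
            fsum, True,
        )
        written += nrec
        grad = -fsum / stride + target_f
        state = sgd_update(state, grad, update_average=(it >= averaging_start))
        if (it + 1) % history_stride == 0 or it == n_iterations - 1:
            history.append((state.iteration, state.alpha_avg.copy()))
    final = state.alpha_inst if averaging == "none" else state.alpha_avg
    bias_c = np.ascontiguousarray(final)
    fsum = np.zeros((m, m))
    for it in range(n_iterations, n_iterations + production_iterations):
        noise = rng.standard_normal((stride, 2)) * sigma
        phi, psi, nrec = _kernels.propagate(
            phi, psi, wells, pot_c, bias_c,
            params.beta, params.diffusion, params.time_step,
            noise, it * stride, params.record_stride,
            rec_t, rec_phi, rec_psi, rec_bias, written,
            fsum, False,
        )
        written += nrec
    traj = CVTrajectory(
        rec_t[:written], {"phi": rec_phi[:written], "psi": rec_psi[:written]}, rec_bias[:written]
    )
    return VESResult(traj, BiasModel(order, final), state, history)


def save_bias(bias: BiasModel, path) -> None:
    """Serialize a bias as text: header, then one 'k1 k2 type coeff' row
    per basis function (type in {cc, cs, sc, ss}); round-trips bit-exactly."""
    m = n_axis_functions(bias.order)
    lines = [f"# torves bias checkpoint order={bias.order} domain=[-pi,pi)^2"]
    for u in range(m):
        k1, t1 = describe_axis_function(u)
        for v in range(m):
            k2, t2 = describe_axis_function(v)
            lines.append(f"{k1} {k2} {t1}{t2} {bias.coeffs[u, v].item()!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_bias(path) -> BiasModel:
    with open(path) as fh:
        header = fh.readline()
        if "torves bias checkpoint" not in header:
            raise ValueError(f"{path}: not a torves bias checkpoint")
        order = int(header.split("order=")[1].split()[0])
        m = n_axis_functions(order)
        coeffs = np.zeros((m, m))
        for line in fh:
            if not line.strip():
                continue
            k1, k2, types, value = line.split()
            idx = flat_index(int(k1), types[0], int(k2), types[1], order)
            coeffs[idx // m, idx % m] = float(value)
    return BiasModel(order, coeffs)
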