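import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from torves import ModelPotential, FourierTerm, run_ves, four_state_test_preset
from torves.dynamics import LangevinParams


@pytest.fixture(scope="session")
def separable_cos_potential():
    """U = 10 cos(phi) + 6 cos(psi): inside the span of an order-2 basis."""
    return ModelPotential(
        fourier=(FourierTerm(1, "c", 0, "c", 10.0), FourierTerm(0, "c", 1, "c", 6.0))
    )


@pytest.fixture(scope="session")
def cos_ves_result(separable_cos_potential):
    """Converged VES run on the separable cosine surface (order 2)."""
    return run_ves(
        separable_cos_potential,
        LangevinParams(seed=1, record_stride=10),
        order=2,
        learning_rate=0.1,
        stride=1000,
        n_iterations=4000,
        production_iterations=0,
    )


@pytest.fixture(scope="session")
def four_state_ves():
    """Converged VES run on the low-barrier four-state surface (order 10)."""
    potential = four_state_test_preset()
    result = run_ves(
        potential,
        LangevinParams(seed=1, record_stride=1),
        order=10,
        learning_rate=0.1,
        stride=1000,
        n_iterations=2000,
    )
    return potential, result


def barrier_by_level_sweep(values, start, end):
    """Independent minimax-barrier oracle: exhaustive sweep over occupation
    levels with BFS connectivity on the periodic 4-neighbour graph."""
    from collections import deque

    ni, nj = values.shape
    levels = np.unique(values[np.isfinite(values)])
    for level in levels:
        allowed = np.isfinite(values) & (values <= level)
        if not (allowed[start] and allowed[end]):
            continue
        seen = {start}
        queue = deque([start])
        while queue:
            i, j = queue.popleft()
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = ((i + di) % ni, (j + dj) % nj)
                if allowed[nb] and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        if end in seen:
            return level - values[start]
    raise ValueError("unreachable")


def bin_averaged_reference(potential, nbins, beta, sub=8):
    """Analytic FES reference on the estimator's own grid: log-mean-exp of
    the Boltzmann factor over each bin (what a histogram estimates)."""
    edges = np.linspace(-np.pi, np.pi, nbins + 1)
    width = edges[1] - edges[0]
    offsets = (np.arange(sub) + 0.5) / sub * width
    x = (edges[:-1][:, None] + offsets[None, :]).ravel()
    pp, qq = np.meshgrid(x, x, indexing="ij")
    u = potential.energy(pp, qq).reshape(nbins, sub, nbins, sub)
    f = -np.log(np.exp(-beta * (u - u.min())).mean(axis=(1, 3))) / beta
    return f - f.min()
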