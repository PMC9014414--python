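"""Time-ordered collective-variable samples with recorded bias energies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CVTrajectory"]


@dataclass
class CVTrajectory:
    """Columnar CV time series: time, named CV columns, bias energy.

    The canonical columns for the dihedral workflow are ``phi`` and
    ``psi`` (radians); ``bias`` is the instantaneous bias energy
    (kJ/mol) recorded at sampling time, zero for unbiased data.
    """

    times: np.ndarray
    columns: dict[str, np.ndarray] = field(default_factory=dict)
    bias: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.columns = {k: np.asarray(v, dtype=float) for k, v in self.columns.items()}
        for name, col in self.columns.items():
            if col.shape != self.times.shape:
                raise ValueError(f"column {name!r} length mismatch")
        if self.bias is None:
            self.bias = np.zeros_like(self.times)
        else:
            self.bias = np.asarray(self.bias, dtype=float)
            if self.bias.shape != self.times.shape:
                raise ValueError("bias column length mismatch")

    @property
    def phi(self) -> np.ndarray:
        return self.columns["phi"]

    @property
    def psi(self) -> np.ndarray:
        return self.columns["psi"]

    def __len__(self) -> int:
        return self.times.size

    def slice(self, mask_or_index) -> "CVTrajectory":
        return CVTrajectory(
            self.times[mask_or_index],
            {k: v[mask_or_index] for k, v in self.columns.items()},
            self.bias[mask_or_index],
        )
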