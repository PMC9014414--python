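"""PLUMED-COLVAR-style columnar text I/O for CV time series.

Format: a header line ``#! FIELDS time phi psi bias ...`` followed by
whitespace-separated numeric rows.  Restarted runs concatenate blocks,
each with its own header; the reader appends later blocks and resolves
duplicate times by keeping the last occurrence.
"""

from __future__ import annotations

import numpy as np

from .trajectory import CVTrajectory

__all__ = ["read_colvar", "write_colvar"]

MANDATORY = ("time", "phi", "psi", "bias")


def write_colvar(traj: CVTrajectory, path) -> None:
    """Deterministic fixed-precision (17 significant digits) output."""
    names = ["time"] + list(traj.columns) + ["bias"]
    cols = [traj.times] + list(traj.columns.values()) + [traj.bias]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_colvar(path) -> CVTrajectory:
    fields: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#!"):
                tokens = stripped.split()
                if len(tokens) < 2 or tokens[1] != "FIELDS":
                    raise ValueError(f"{path}:{lineno}: malformed header")
                new_fields = tokens[2:]
                if fields is not None and new_fields != fields:
                    raise ValueError(f"{path}:{lineno}: restart block changes the column set")
                fields = new_fields
                continue
            if stripped.startswith("#"):
                continue
            if fields is None:
                raise ValueError(f"{path}:{lineno}: data before any FIELDS header")
            try:
                values = [float(tok) for tok in stripped.split()]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row: {stripped!r}") from exc
            if len(values) != len(fields):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(fields)} columns, got {len(values)}"
                )
            rows.append(values)
    if fields is None:
        raise ValueError(f"{path}: no FIELDS header found")
    for name in ("time", "bias"):
        if name not in fields:
            raise ValueError(f"{path}: mandatory column {name!r} missing")
    data = np.array(rows) if rows else np.zeros((0, len(fields)))
    t = data[:, fields.index("time")]
    # duplicate times (restarts): keep the last occurrence, then sort by time
    _, last_idx = np.unique(t[::-1], return_index=True)
    keep = np.sort(t.size - 1 - last_idx)
    data = data[keep]
    t = data[:, fields.index("time")]
    columns = {
        name: data[:, i]
        for i, name in enumerate(fields)
        if name not in ("time", "bias")
    }
    return CVTrajectory(t, columns, data[:, fields.index("bias")])
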