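"""End-to-end workflow: simulate -> ves -> fes -> states -> compare ->
converge -> struct -> report, on two landscapes (A: resting-form-like,
B: illuminated-form-like).

Every numeric output is a pure function of the configuration (all
randomness flows from ``config.seed``), so re-running an identical
config reproduces all output files bitwise.  Each output file carries
the config hash in its header.
"""

from __future__ import annotations

import os

import numpy as np

from .config import RunConfig
from .constants import kt
from .convergence import convergence_series, fes_checkpoints, fes_variability
from .colvar import write_colvar
from .dynamics import LangevinParams
from .energetics import RateModel, arrhenius_time
from .fes import (
    compute_weights,
    estimate_fes_2d,
    global_barrier,
    marginal_profile,
    minimax_path_barrier,
    write_fes,
)
from .potentials import (
    ModelPotential,
    four_state_test_preset,
    pfr_like_preset,
    pr_like_preset,
)
from .states import (
    MetastableState,
    cluster_states,
    label_states,
    merge_superstates,
    select_high_weight,
    state_fe_difference,
    state_free_energies,
)
from .structural import contact_frequency, hbond_counts, rmsd_series, rmsf_per_residue
from .toyprotein import PlantedContact, PlantedHBond, ToyProteinSpec, make_toy_protein_trajectory
from .ves import run_ves, save_bias

__all__ = ["run_pipeline", "PipelineStageError", "build_potential", "write_states_table", "read_states_table"]

_PRESETS = {
    "four_state_test": four_state_test_preset,
    "pr_like": pr_like_preset,
    "pfr_like": pfr_like_preset,
}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def build_potential(pconf) -> ModelPotential:
    if pconf.preset in _PRESETS:
        return _PRESETS[pconf.preset]()
    if pconf.preset == "custom":
        return ModelPotential(np.asarray(pconf.wells, dtype=float)).shifted_to_zero_min()
    raise ValueError(f"unknown potential preset {pconf.preset!r}")


def write_states_table(states: list[MetastableState], path, header_extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# torves states {header_extra}\n")
        fh.write("# label centroid_phi centroid_psi members free_energy_kj_mol\n")
        for s in states:
            fh.write(
                f"{s.label} {s.centroid[0]!r} {s.centroid[1]!r} {s.member_count} {s.free_energy!r}\n"
            )


def read_states_table(path) -> list[MetastableState]:
    states = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            lab, cp, cq, n, f = line.split()
            states.append(
                MetastableState(lab, np.arange(int(n)), (float(cp), float(cq)), float(f))
            )
    return states


def _analyze_landscape(
    potential: ModelPotential,
    config: RunConfig,
    seed: int,
    outdir: str,
    tag: str,
) -> dict:
    lv = config.langevin
    an = config.analysis
    params = LangevinParams(
        temperature=lv.temperature,
        diffusion=lv.diffusion,
        time_step=lv.time_step,
        n_steps=lv.n_steps,
        record_stride=lv.record_stride,
        seed=seed,
    )
    try:
        result = run_ves(
            potential,
            params,
            order=config.ves.order,
            learning_rate=config.ves.learning_rate,
            stride=config.ves.stride,
            n_iterations=config.ves.n_iterations,
            production_iterations=config.ves.production_iterations,
            averaging=config.ves.averaging,
        )
        save_bias(result.bias, os.path.join(outdir, f"bias_{tag}.dat"))
        traj = result.trajectory
        thin = max(1, len(traj) // 50_000)
        write_colvar(traj.slice(slice(None, None, thin)), os.path.join(outdir, f"colvar_{tag}.dat"))
    except Exception as exc:
        raise PipelineStageError(f"ves_{tag}", exc) from exc

    try:
        ws = compute_weights(traj, burn_in_fraction=an.burn_in_fraction, temperature=lv.temperature)
        fes = estimate_fes_2d(ws, nbins=an.grid_bins)
        write_fes(fes, os.path.join(outdir, f"fes_{tag}.dat"))
        for axis, name in ((0, "phi"), (1, "psi")):
            centers, prof = marginal_profile(fes, axis)
            with open(os.path.join(outdir, f"profile_{name}_{tag}.dat"), "w") as fh:
                fh.write(f"# torves profile axis={name}\n")
                for x, f in zip(centers, prof):
                    fh.write(f"{float(x)!r} {float(f)!r}\n")
    except Exception as exc:
        raise PipelineStageError(f"fes_{tag}", exc) from exc

    try:
        idx = select_high_weight(ws, an.fe_cutoff)
        clusters = cluster_states(ws, idx, an.cluster_eps, an.cluster_min_members)
        clusters = merge_superstates(clusters, ws, fes, an.merge_barrier)
        states = state_free_energies(ws, label_states(clusters))
        write_states_table(states, os.path.join(outdir, f"states_{tag}.dat"))
    except Exception as exc:
        raise PipelineStageError(f"states_{tag}", exc) from exc

    try:
        kept = ws.times[ws.mask]
        cp_times = np.linspace(kept.min(), kept.max(), an.n_checkpoints + 1)[1:]
        checkpoints = fes_checkpoints(ws, cp_times, nbins=an.grid_bins)
        series = convergence_series(
            checkpoints, cp_times, window=an.convergence_window, slope_tol=an.slope_tol
        )
        variability = fes_variability(checkpoints, window=an.variability_window)
        with open(os.path.join(outdir, f"convergence_{tag}.dat"), "w") as fh:
            fh.write("# torves convergence time distance\n")
            for t, d in zip(series.checkpoint_times[1:], series.distances):
                fh.write(f"{float(t)!r} {float(d)!r}\n")
            verdict = (
                f"plateau at t={series.plateau_time!r}" if series.converged else "no plateau detected"
            )
            fh.write(f"# {verdict}; last-window FES variability {variability!r} kJ/mol\n")
    except Exception as exc:
        raise PipelineStageError(f"converge_{tag}", exc) from exc

    by_label = {s.label: s for s in states}
    barriers = {}
    if "S_h" in by_label and "S_m" in by_label:
        b_h = fes.bin_of(*by_label["S_h"].centroid)
        b_m = fes.bin_of(*by_label["S_m"].centroid)
        barriers["S_h_to_S_m"] = minimax_path_barrier(fes, b_h, b_m)
        barriers["S_m_to_S_h"] = minimax_path_barrier(fes, b_m, b_h)
    return {
        "tag": tag,
        "weighted_samples": ws,
        "fes": fes,
        "states": states,
        "global_barrier": global_barrier(fes),
        "path_barriers": barriers,
        "convergence": series,
        "variability": variability,
    }


def _default_toy_spec() -> ToyProteinSpec:
    # tongue-like mobile region, one planted chromophore-protein H-bond,
    # one frequent and one intermittent contact
    return ToyProteinSpec(
        n_residues=20,
        n_frames=200,
        mobile_residues=(14, 15, 16),
        jitter_sigma=0.03,
        driven_dihedral_series=np.linspace(-np.pi, np.pi, 200, endpoint=False),
        hbonds=(PlantedHBond(donor=4 * 10, hydrogen=4 * 10 + 1, acceptor=4 * 12 + 3, fraction=0.8),),
        contacts=(PlantedContact(2, 8, fraction=1.0), PlantedContact(3, 12, fraction=0.6)),
    )


def _structural_stage(config: RunConfig, outdir: str) -> dict:
    spec = _default_toy_spec()
    traj = make_toy_protein_trajectory(spec, seed=config.seed + 7)
    # fit on the rigid leading residues (all their atoms: non-collinear set)
    rigid = np.flatnonzero(traj.residue_ids < 10)
    rmsd = rmsd_series(traj, traj.coords[0], fit_indices=rigid)
    rmsf = rmsf_per_residue(traj, fit_indices=rigid)
    contacts = contact_frequency(traj)
    hb = spec.hbonds[0]
    counts, hist = hbond_counts(traj, [(hb.donor, hb.hydrogen, hb.acceptor)])
    with open(os.path.join(outdir, "rmsf.dat"), "w") as fh:
        fh.write("# torves rmsf residue rmsf_nm\n")
        for resid, value in sorted(rmsf.items()):
            fh.write(f"{resid} {value!r}\n")
    with open(os.path.join(outdir, "contacts.dat"), "w") as fh:
        fh.write(f"# torves contacts cutoff={contacts.cutoff} n_frames={contacts.n_frames}\n")
        n = contacts.residues.size
        for i in range(n):
            for j in range(i + 1, n):
                if contacts.frequencies[i, j] > 0:
                    fh.write(
                        f"{contacts.residues[i]} {contacts.residues[j]} {contacts.frequencies[i, j].item()!r}\n"
                    )
    return {
        "rmsd_mean": float(rmsd.mean()),
        "rmsf": rmsf,
        "hbond_fraction": 1.0 - hist.get(0, 0.0),
        "contact_2_8": contacts.frequency(2, 8),
        "contact_3_12": contacts.frequency(3, 12),
    }


def run_pipeline(config: RunConfig, output_dir: str | None = None) -> dict:
    """Execute all stages; returns the summary dict and writes reports.

    Stage failures raise :class:`PipelineStageError` naming the stage.
    """
    outdir = output_dir or config.output_dir
    os.makedirs(outdir, exist_ok=True)
    digest = config.digest()
    config.to_yaml(os.path.join(outdir, "config_used.yaml"))
    summary: dict = {"config_digest": digest, "seed": config.seed}

    results = {}
    for tag, pconf, seed in (
        ("a", config.potential_a, config.seed),
        ("b", config.potential_b, config.seed + 1),
    ):
        try:
            potential = build_potential(pconf)
        except Exception as exc:
            raise PipelineStageError("potential", exc) from exc
        try:
            results[tag] = _analyze_landscape(potential, config, seed, outdir, tag)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(f"landscape_{tag}", exc) from exc

    try:
        deltas = state_fe_difference(results["a"]["states"], results["b"]["states"])
    except Exception as exc:
        raise PipelineStageError("compare", exc) from exc

    try:
        structural = _structural_stage(config, outdir)
    except Exception as exc:
        raise PipelineStageError("struct", exc) from exc

    rate = RateModel(temperature=config.langevin.temperature)
    timescales = {}
    for tag in ("a", "b"):
        for name, barrier in results[tag]["path_barriers"].items():
            timescales[f"{tag}_{name}"] = arrhenius_time(barrier, rate)

    summary.update(
        {
            "global_barrier_a": results["a"]["global_barrier"],
            "global_barrier_b": results["b"]["global_barrier"],
            "path_barriers_a": results["a"]["path_barriers"],
            "path_barriers_b": results["b"]["path_barriers"],
            "state_fe_a": {s.label: s.free_energy for s in results["a"]["states"]},
            "state_fe_b": {s.label: s.free_energy for s in results["b"]["states"]},
            "state_fe_differences": deltas,
            "plateau_a": results["a"]["convergence"].plateau_time,
            "plateau_b": results["b"]["convergence"].plateau_time,
            "variability_a": results["a"]["variability"],
            "variability_b": results["b"]["variability"],
            "timescales_s": timescales,
            "structural": structural,
            "kt": kt(config.langevin.temperature),
        }
    )

    try:
        with open(os.path.join(outdir, "summary.txt"), "w") as fh:
            fh.write(f"# torves summary config={digest} seed={config.seed}\n")
            for key in (
                "global_barrier_a",
                "global_barrier_b",
                "variability_a",
                "variability_b",
                "plateau_a",
                "plateau_b",
            ):
                fh.write(f"{key} = {summary[key]!r}\n")
            for tag in ("a", "b"):
                for s in results[tag]["states"]:
                    fh.write(
                        f"state_{tag} {s.label} F={s.free_energy!r} members={s.member_count}\n"
                    )
            for lab, d in deltas.items():
                fh.write(f"delta_F {lab} = {d!r}\n")
            for name, tau in timescales.items():
                fh.write(f"timescale_{name} = {tau!r} s\n")
    except Exception as exc:
        raise PipelineStageError("report", exc) from exc
    return summary
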