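"""Steered-association force expressions and unfolding-trace analysis.

Two distance-dependent biasing forces act between mass-weighted group
centres of mass (COM):

- a pulling force of magnitude ``0.5 * d`` (kJ/mol/A at separation d A)
  drawing the target-lysine sidechain amine group (NZ, HZ1, HZ2) towards
  the cofactor methyl group (SD, CE, H10); energy ``+1/2 * k * d^2``;
- a repulsive force of magnitude ``0.3 * d`` pushing the peptide's
  terminal groups (A29 N/CA/C and P43 CG/CD/OXT) apart to suppress
  hairpin formation; energy ``-1/2 * k * d^2`` (an inverted harmonic:
  the stated force law grows with separation).

Forces are distributed over group atoms by their COM mass weights and
obey action-reaction exactly.  The unfolding analysis tracks, per
docking trajectory, the backbone RMSD to an extended reference and the
N-C distance (backbone N of A29 to backbone N of P43) up to the frame of
minimum RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ATOMIC_MASS, kabsch_superpose, rmsd
from .trajectory import Frame, Topology, Trajectory, select

__all__ = [
    "SteeringForceSpec",
    "UnfoldingTrace",
    "steering_energy_forces",
    "rmsd_to_reference_trace",
    "nc_distance_trace",
    "unfolding_trace",
    "classify_unfolding",
    "ensemble_unfolding_fractions",
    "trace_correlation",
]


@dataclass(frozen=True)
class SteeringForceSpec:
    """Group definitions and force constants of the steering protocol."""

    pull_k: float = 0.5    # kJ mol^-1 A^-2
    repulse_k: float = 0.3  # kJ mol^-1 A^-2, applied with negative sign
    pull_group_a: str = "residue_seq 36 and name NZ,HZ1,HZ2"
    pull_group_b: str = "chain S and name SD,CE,H10"
    repulse_group_a: str = "residue_seq 29 and name N,CA,C"
    repulse_group_b: str = "residue_seq 43 and name CG,CD,OXT"
    repulse_distance_cap: float | None = None  # short-range-only variant

    def __post_init__(self):
        if self.pull_k < 0 or self.repulse_k < 0:
            raise ValueError("force constants must be non-negative")


def _group(topology: Topology, frame: Frame, selection: str):
    idx = select(topology, selection)
    if not idx:
        raise ValueError(f"selection {selection!r} resolves to no atoms")
    masses = np.array([ATOMIC_MASS[topology.atoms[i].element] for i in idx])
    weights = masses / masses.sum()
    com = (frame.coordinates[idx] * weights[:, None]).sum(axis=0)
    return idx, weights, com


def _pair_term(frame, topology, sel_a, sel_b, k, sign, forces, cap=None):
    """Harmonic COM-COM term; sign +1 attracts, -1 repels.  Returns energy."""
    idx_a, w_a, com_a = _group(topology, frame, sel_a)
    idx_b, w_b, com_b = _group(topology, frame, sel_b)
    delta = com_b - com_a
    d = float(np.linalg.norm(delta))
    if cap is not None and d > cap:
        return 0.0
    if d < 1e-12:
        return 0.0
    axis = delta / d
    # force on group a along +axis (towards b) when attracting
    f_mag = k * d
    f_a = sign * f_mag * axis
    for i, w in zip(idx_a, w_a):
        forces[i] += w * f_a
    for i, w in zip(idx_b, w_b):
        forces[i] -= w * f_a
    return sign * 0.5 * k * d * d


def steering_energy_forces(
    frame: Frame, topology: Topology, spec: SteeringForceSpec = SteeringForceSpec()
) -> tuple[float, np.ndarray]:
    """Total steering energy (kJ/mol) and per-atom forces (kJ/mol/A).

    The pulling term is an ordinary harmonic spring between the group
    COMs; the repulsive term uses the same distance-proportional
    magnitude with inverted sign.  With ``repulse_distance_cap`` set, the
    repulsive term only acts below that separation.
    """
    forces = np.zeros_like(frame.coordinates)
    energy = _pair_term(
        frame, topology, spec.pull_group_a, spec.pull_group_b,
        spec.pull_k, +1.0, forces,
    )
    if spec.repulse_k > 0:
        energy += _pair_term(
            frame, topology, spec.repulse_group_a, spec.repulse_group_b,
            spec.repulse_k, -1.0, forces, cap=spec.repulse_distance_cap,
        )
    return energy, forces


def rmsd_to_reference_trace(
    trajectory: Trajectory,
    reference: Frame,
    fit_selection: str = "name N,CA,C",
    reference_topology: Topology | None = None,
) -> tuple[np.ndarray, int]:
    """Per-frame Kabsch-fit backbone RMSD to a reference conformation.

    Returns the trace and the argmin frame (first occurrence on ties).
    The reference must share the backbone layout of the trajectory.
    """
    traj_idx = select(trajectory.topology, fit_selection)
    ref_top = reference_topology or trajectory.topology
    ref_idx = select(ref_top, fit_selection)
    if len(traj_idx) != len(ref_idx) or len(traj_idx) < 3:
        raise ValueError("reference does not share the fit-atom layout")
    ref_coords = reference.coordinates[ref_idx]
    trace = np.empty(trajectory.n_frames)
    for t, frame in enumerate(trajectory.frames):
        mobile = frame.coordinates[traj_idx]
        _, moved = kabsch_superpose(mobile, ref_coords)
        trace[t] = rmsd(moved, ref_coords)
    return trace, int(np.argmin(trace))


def nc_distance_trace(trajectory: Trajectory) -> np.ndarray:
    """Per-frame N-C distance: backbone N of residue 29 to backbone N of 43."""
    top = trajectory.topology
    i = top.index_of(29, "N")
    j = top.index_of(43, "N")
    stack = trajectory.coordinate_stack()
    return np.linalg.norm(stack[:, i] - stack[:, j], axis=1)


@dataclass
class UnfoldingTrace:
    """RMSD and N-C traces truncated at the minimum-RMSD frame (inclusive)."""

    rmsd_to_reference: np.ndarray
    nc_distance: np.ndarray
    argmin_frame: int

    def __post_init__(self):
        if len(self.rmsd_to_reference) != len(self.nc_distance):
            raise ValueError("trace length mismatch")
        if self.argmin_frame != len(self.rmsd_to_reference) - 1:
            raise ValueError("traces must end at the argmin frame")


def unfolding_trace(
    trajectory: Trajectory,
    reference: Frame,
    fit_selection: str = "name N,CA,C",
    reference_topology: Topology | None = None,
) -> UnfoldingTrace:
    """Track RMSD-to-reference and N-C distance until the minimum RMSD."""
    trace, argmin = rmsd_to_reference_trace(
        trajectory, reference, fit_selection, reference_topology
    )
    nc = nc_distance_trace(trajectory)
    return UnfoldingTrace(
        rmsd_to_reference=trace[: argmin + 1],
        nc_distance=nc[: argmin + 1],
        argmin_frame=argmin,
    )


def classify_unfolding(trace: UnfoldingTrace) -> tuple[bool, bool]:
    """(rmsd_decreased, nc_increased) between frame 0 and the argmin frame."""
    if len(trace.rmsd_to_reference) < 2:
        return False, False
    rmsd_decreased = bool(
        trace.rmsd_to_reference[trace.argmin_frame] < trace.rmsd_to_reference[0]
    )
    nc_increased = bool(trace.nc_distance[trace.argmin_frame] > trace.nc_distance[0])
    return rmsd_decreased, nc_increased


def ensemble_unfolding_fractions(
    trajectories: list[Trajectory],
    reference: Frame,
    fit_selection: str = "name N,CA,C",
    reference_topology: Topology | None = None,
) -> tuple[float, float]:
    """Fractions of replicates with decreasing RMSD / increasing N-C distance."""
    flags = [
        classify_unfolding(
            unfolding_trace(t, reference, fit_selection, reference_topology)
        )
        for t in trajectories
    ]
    rmsd_frac = float(np.mean([f[0] for f in flags]))
    nc_frac = float(np.mean([f[1] for f in flags]))
    return rmsd_frac, nc_frac


def trace_correlation(rmsd_series, nc_series) -> float:
    """Pearson correlation between the RMSD and N-C traces."""
    a = np.asarray(rmsd_series, dtype=float)
    b = np.asarray(nc_series, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("series must have equal length >= 3")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(np.corrcoef(a, b)[0, 1])
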