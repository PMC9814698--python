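"""Synthetic labelled trajectories, melt curves and sequence utilities.

Every analysis stage in this package is exercised on data produced here,
so the generators emit ground-truth labels alongside coordinates:

- 15-residue peptide backbones (N, CA, C) flipping between an extended
  and a hairpin template under a two-state Markov chain, emulating
  solution simulations written every 20 ps;
- enzyme-peptide-cofactor complex trajectories with a lysine NZ/CD probe,
  cofactor S/methyl-C pseudo-atoms and plantable transition-state-like
  occupancy, dwell times and residue contacts;
- temperature-series fluorescence melt curves from the two-state FRET
  forward model.

The hairpin template places the target lysine (residue 36) at the loop
apex and satisfies both hairpin criteria (stem-loop G33CA-P38CA < 7 A,
end-to-end A29CA-P43CA < 15 A); the extended template violates both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from biotite.sequence import ProteinSequence

from .fret import TwoStateParams, predicted_intensity, MeltCurve
from .trajectory import Atom, Frame, Topology, Trajectory

__all__ = [
    "H3K36_SEQUENCE",
    "SSK36_SEQUENCE",
    "PeptideSequence",
    "EnsembleSpec",
    "ComplexSpec",
    "MeltCurveSpec",
    "SpecError",
    "build_template",
    "build_peptide_topology",
    "build_complex_topology",
    "generate_two_state_ensemble",
    "generate_complex_ensemble",
    "generate_unfolding_ensemble",
    "generate_melt_curve",
    "peptide_diff",
    "sequence_length",
]

FIRST_RESIDUE = 29  # author numbering of the 15-mer substrate peptides
CA_SPACING = 3.8    # consecutive CA-CA distance, angstrom


class SpecError(ValueError):
    """Invalid generator specification."""


@dataclass(frozen=True)
class PeptideSequence:
    """15-mer peptide in 1-letter code, author-numbered 29-43."""

    name: str
    residues: str

    def __post_init__(self):
        if len(self.residues) != 15:
            raise SpecError(f"{self.name}: expected 15 residues, got {len(self.residues)}")
        if self.residues[36 - FIRST_RESIDUE] != "K":
            raise SpecError(f"{self.name}: target position 36 must be lysine")

    def __len__(self) -> int:
        return len(self.residues)

    def author_position(self, i: int) -> int:
        return FIRST_RESIDUE + i


H3K36_SEQUENCE = PeptideSequence(name="H3K36", residues="APATGGVKKPHRYRP")
SSK36_SEQUENCE = PeptideSequence(name="ssK36", residues="APRFGGVKRPNRYRP")


def sequence_length(seq) -> int:
    """Residue count of a peptide sequence (string or PeptideSequence)."""
    residues = seq.residues if isinstance(seq, PeptideSequence) else seq
    return len(residues)


def peptide_diff(seq_a, seq_b) -> list[tuple[int, str, str]]:
    """Positions (author numbering) where two equal-length peptides differ."""
    a = seq_a.residues if isinstance(seq_a, PeptideSequence) else seq_a
    b = seq_b.residues if isinstance(seq_b, PeptideSequence) else seq_b
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    return [
        (FIRST_RESIDUE + i, x, y)
        for i, (x, y) in enumerate(zip(a, b))
        if x != y
    ]


# --- backbone templates ------------------------------------------------------

def _ca_positions(conformation: str) -> np.ndarray:
    n = 15
    if conformation == "extended":
        ca = np.zeros((n, 3))
        ca[:, 0] = CA_SPACING * np.arange(n)
        return ca
    if conformation == "hairpin":
        # two antiparallel strands 5 A apart joined at the apex (residue 36)
        strand_sep = 5.0
        ca = np.zeros((n, 3))
        apex = 36 - FIRST_RESIDUE  # index 7
        for i in range(apex):
            ca[i] = (CA_SPACING * i, 0.0, 0.0)
        for i in range(apex + 1, n):
            ca[i] = (CA_SPACING * (n - 1 - i), strand_sep, 0.0)
        # apex equidistant (one CA step) from both strand ends
        last_in = ca[apex - 1]
        first_out = ca[apex + 1]
        mid = 0.5 * (last_in + first_out)
        half_gap = 0.5 * np.linalg.norm(first_out - last_in)
        reach = np.sqrt(CA_SPACING**2 - half_gap**2)
        ca[apex] = mid + np.array([reach, 0.0, 0.0])
        return ca
    raise ValueError(f"unknown conformation {conformation!r}")


def _backbone_from_ca(ca: np.ndarray) -> np.ndarray:
    """Place N and C flanking each CA along the local chain tangent."""
    n = len(ca)
    tangents = np.zeros_like(ca)
    tangents[1:-1] = ca[2:] - ca[:-2]
    tangents[0] = ca[1] - ca[0]
    tangents[-1] = ca[-1] - ca[-2]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    up = np.array([0.0, 0.0, 1.0])
    coords = np.zeros((3 * n, 3))
    for i in range(n):
        coords[3 * i] = ca[i] - 1.0 * tangents[i] + 1.06 * up      # N, ~1.46 A
        coords[3 * i + 1] = ca[i]                                  # CA
        coords[3 * i + 2] = ca[i] + 1.1 * tangents[i] + 1.05 * up  # C, ~1.52 A
    return coords


def build_peptide_topology(
    sequence: PeptideSequence = SSK36_SEQUENCE, chain_id: str = "P"
) -> Topology:
    """Backbone-only (N, CA, C) topology with author numbering 29-43."""
    atoms = []
    serial = 1
    for i, letter in enumerate(sequence.residues):
        res_name = ProteinSequence.convert_letter_1to3(letter)
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C")):
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_index=i,
                    residue_name=res_name,
                    residue_seq=FIRST_RESIDUE + i,
                    chain_id=chain_id,
                )
            )
            serial += 1
    return Topology(atoms=atoms)


def build_template(
    conformation: str, sequence: PeptideSequence = SSK36_SEQUENCE
) -> tuple[Topology, Frame]:
    """Ideal extended or hairpin backbone template.

    Consecutive CA-CA spacing is 3.8 A; the hairpin places residue 36 at
    the loop apex and satisfies both hairpin distance criteria, the
    extended template violates both.
    """
    topology = build_peptide_topology(sequence)
    coords = _backbone_from_ca(_ca_positions(conformation))
    return topology, Frame(coordinates=coords, frame_index=0, time_ps=0.0)


# --- two-state solution ensembles -------------------------------------------

@dataclass(frozen=True)
class EnsembleSpec:
    """Two-state (extended/hairpin) Markov-chain solution ensemble.

    Defaults emulate the study's solution design: 50 replicates of 70 ns
    written every 20 ps (3500 frames per replicate).
    """

    n_replicates: int = 50
    n_frames_per_replicate: int = 3500
    p_stay_hairpin: float = 0.98
    p_stay_extended: float = 0.98
    coordinate_noise_sd: float = 0.3
    seed: int = 0
    condition_label: str = "ssK36"
    sequence: PeptideSequence = SSK36_SEQUENCE

    def __post_init__(self):
        for p in (self.p_stay_hairpin, self.p_stay_extended):
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"stay probability {p} outside [0, 1]")
        if self.n_frames_per_replicate < 1:
            raise SpecError("need at least one frame per replicate")
        if self.n_replicates < 1:
            raise SpecError("need at least one replicate")
        if self.coordinate_noise_sd < 0:
            raise SpecError("noise sd must be non-negative")

    @property
    def stationary_hairpin_fraction(self) -> float:
        leave_h = 1.0 - self.p_stay_hairpin
        leave_e = 1.0 - self.p_stay_extended
        if leave_h + leave_e == 0.0:
            return 0.5  # degenerate frozen chain; start state decides
        return leave_e / (leave_h + leave_e)

    @staticmethod
    def from_stationary(
        hairpin_fraction: float, mean_dwell_frames: float = 50.0, **kwargs
    ) -> "EnsembleSpec":
        """Spec with a prescribed stationary hairpin fraction.

        The hairpin dwell is geometric with the given mean; the extended
        stay probability follows from detailed balance of the 2-state chain.
        """
        if not 0.0 < hairpin_fraction < 1.0:
            raise SpecError("stationary fraction must lie in (0, 1)")
        leave_h = 1.0 / mean_dwell_frames
        leave_e = leave_h * hairpin_fraction / (1.0 - hairpin_fraction)
        if leave_e > 1.0:
            raise SpecError("dwell/fraction combination needs leave probability > 1")
        return EnsembleSpec(
            p_stay_hairpin=1.0 - leave_h, p_stay_extended=1.0 - leave_e, **kwargs
        )


def _simulate_chain(rng, n, p_stay_a, p_stay_b, start_a_prob):
    """Boolean chain; True = state A (hairpin)."""
    states = np.empty(n, dtype=bool)
    u = rng.random(n)
    states[0] = u[0] < start_a_prob
    for t in range(1, n):
        stay = p_stay_a if states[t - 1] else p_stay_b
        states[t] = states[t - 1] if u[t] < stay else not states[t - 1]
    return states


def generate_two_state_ensemble(
    spec: EnsembleSpec,
) -> tuple[list[Trajectory], list[np.ndarray]]:
    """Solution-trajectory ensemble plus true per-frame hairpin labels."""
    rng = np.random.default_rng(spec.seed)
    topology, hairpin = build_template("hairpin", spec.sequence)
    _, extended = build_template("extended", spec.sequence)
    templates = {True: hairpin.coordinates, False: extended.coordinates}
    trajectories, labels = [], []
    for rep in range(spec.n_replicates):
        states = _simulate_chain(
            rng,
            spec.n_frames_per_replicate,
            spec.p_stay_hairpin,
            spec.p_stay_extended,
            spec.stationary_hairpin_fraction,
        )
        base = np.where(
            states[:, None, None], templates[True][None], templates[False][None]
        )
        noise = rng.normal(0.0, spec.coordinate_noise_sd, size=base.shape)
        coords = base + noise
        frames = [
            Frame(coordinates=coords[t], frame_index=t, time_ps=20.0 * t)
            for t in range(spec.n_frames_per_replicate)
        ]
        trajectories.append(
            Trajectory(
                topology=topology,
                frames=frames,
                frame_interval_ps=20.0,
                condition_label=spec.condition_label,
                replicate_id=rep,
            )
        )
        labels.append(states)
    return trajectories, labels


# --- complex ensembles -------------------------------------------------------

# enzyme stand-in: 12 pseudo-residues named after peptide-contacting residues
ENZYME_RESIDUES = (
    1602, 1609, 1625, 1636, 1638, 1665, 1666, 1674, 1676, 1695, 1699, 1700
)

# cofactor methyl carbon sits 6 A outward from the apex lysine CA
_CE_BASE = np.array([31.7, 2.5, 0.0])
_SD_BASE = _CE_BASE + np.array([-1.8, 0.0, 0.0])
# attack direction of the lysine sidechain nitrogen: +x from the methyl C
_NZ_TS = _CE_BASE + np.array([3.5, 0.0, 0.0])
_NZ_FAR = _CE_BASE + np.array([6.0, 0.0, 0.0])


@dataclass(frozen=True)
class ComplexSpec:
    """Complex-trajectory ensemble with plantable TS-like dynamics.

    Defaults emulate the study's complex design: 15 replicates of 100 ns
    written every 20 ps (5000 frames per replicate).  ``contact_plan``
    maps ``(peptide_residue, enzyme_residue)`` to a target contact
    frequency; ``ts_contact_pairs`` are in contact exactly in TS frames.
    """

    n_replicates: int = 15
    n_frames: int = 5000
    ts_occupancy: float = 0.2
    mean_dwell_frames: float = 4.0
    seed: int = 0
    condition_label: str = "ssK36"
    sequence: PeptideSequence = SSK36_SEQUENCE
    backbone_noise_sd: float = 0.2
    contact_plan: tuple = ()
    ts_contact_pairs: tuple = ()

    def __post_init__(self):
        if not 0.0 <= self.ts_occupancy <= 1.0:
            raise SpecError("ts_occupancy must lie in [0, 1]")
        if self.mean_dwell_frames < 1.0:
            raise SpecError("mean dwell must be >= 1 frame")
        if self.n_frames < 1 or self.n_replicates < 1:
            raise SpecError("need at least one frame and one replicate")
        planned = [enz for (_, enz), _ in self.contact_plan]
        ts_planned = [enz for _, enz in self.ts_contact_pairs]
        if len(set(planned + ts_planned)) != len(planned + ts_planned):
            raise SpecError("each enzyme residue may appear in one contact rule only")


def build_complex_topology(sequence: PeptideSequence = SSK36_SEQUENCE) -> Topology:
    """Peptide backbone + lysine probe + cofactor + enzyme pseudo-residues.

    Chains: P peptide (29-43; residue 36 carries CD/NZ/HZ1/HZ2, residue 43
    carries CG/CD/OXT), S cofactor (SD, CE, H10), E enzyme stand-in
    (12 pseudo-residues of 3 heavy atoms each).
    """
    atoms = list(build_peptide_topology(sequence).atoms)
    serial = len(atoms) + 1

    def add(name, element, residue_index, residue_name, residue_seq, chain_id):
        nonlocal serial
        atoms.append(
            Atom(serial=serial, name=name, element=element,
                 residue_index=residue_index, residue_name=residue_name,
                 residue_seq=residue_seq, chain_id=chain_id)
        )
        serial += 1

    lys_idx = 36 - FIRST_RESIDUE
    for name, element in (("CD", "C"), ("NZ", "N"), ("HZ1", "H"), ("HZ2", "H")):
        add(name, element, lys_idx, "LYS", 36, "P")
    for name, element in (("CG", "C"), ("CD", "C"), ("OXT", "O")):
        add(name, element, 14, ProteinSequence.convert_letter_1to3(
            sequence.residues[14]), 43, "P")
    for name, element in (("SD", "S"), ("CE", "C"), ("H10", "H")):
        add(name, element, 15, "SAM", 1, "S")
    for k, res_seq in enumerate(ENZYME_RESIDUES):
        for name, element in (("CA", "C"), ("CB", "C"), ("CG", "C")):
            add(name, element, 16 + k, "ENZ", res_seq, "E")
    return Topology(atoms=atoms)


def _complex_base_coords(topology: Topology, sequence: PeptideSequence) -> np.ndarray:
    """Static base geometry: hairpin peptide docked at the cofactor."""
    backbone = _backbone_from_ca(_ca_positions("hairpin"))
    coords = np.zeros((len(topology), 3))
    coords[: len(backbone)] = backbone
    pos = {(a.chain_id, a.residue_seq, a.name): i for i, a in enumerate(topology.atoms)}
    ca36 = backbone[3 * (36 - FIRST_RESIDUE) + 1]
    coords[pos[("P", 36, "NZ")]] = _NZ_FAR
    coords[pos[("P", 36, "CD")]] = 0.5 * (ca36 + _NZ_FAR)
    coords[pos[("P", 36, "HZ1")]] = _NZ_FAR + np.array([0.4, 0.9, 0.0])
    coords[pos[("P", 36, "HZ2")]] = _NZ_FAR + np.array([0.4, -0.9, 0.0])
    ca43 = backbone[3 * 14 + 1]
    coords[pos[("P", 43, "CG")]] = ca43 + np.array([0.0, -1.5, 0.0])
    coords[pos[("P", 43, "CD")]] = ca43 + np.array([1.0, -1.5, 0.0])
    coords[pos[("P", 43, "OXT")]] = ca43 + np.array([0.5, -2.3, 0.0])
    coords[pos[("S", 1, "SD")]] = _SD_BASE
    coords[pos[("S", 1, "CE")]] = _CE_BASE
    coords[pos[("S", 1, "H10")]] = _CE_BASE + np.array([0.0, 1.1, 0.0])
    for k, res_seq in enumerate(ENZYME_RESIDUES):
        base = np.array([4.0 * k, -20.0, 0.0])
        coords[pos[("E", res_seq, "CA")]] = base
        coords[pos[("E", res_seq, "CB")]] = base + np.array([1.5, 0.0, 0.0])
        coords[pos[("E", res_seq, "CG")]] = base + np.array([0.0, 1.5, 0.0])
    return coords


# lysine CD placed so the attack angle CD-NZ...CE is exactly 109 deg
_ATTACK_DEG = 109.0


def _probe_coords(ts: bool) -> dict[str, np.ndarray]:
    nz = _NZ_TS if ts else _NZ_FAR
    theta = np.radians(_ATTACK_DEG)
    # unit vector from NZ towards CE is (-1, 0, 0); CD at 109 deg from it
    v = np.array([-np.cos(theta), np.sin(theta), 0.0])
    return {
        "NZ": nz,
        "CD": nz + 1.5 * v,
        "HZ1": nz + np.array([0.4, 0.9, 0.0]),
        "HZ2": nz + np.array([0.4, -0.9, 0.0]),
    }


def generate_complex_ensemble(
    spec: ComplexSpec,
) -> tuple[list[Trajectory], list[np.ndarray]]:
    """Complex-trajectory ensemble plus true per-frame TS-like labels.

    TS dwell lengths are geometric with mean ``mean_dwell_frames``; the
    entry probability is set so the stationary TS fraction equals
    ``ts_occupancy``.  In TS frames the probe satisfies all three
    geometric criteria exactly; in non-TS frames the NZ-CE distance
    criterion is violated.
    """
    rng = np.random.default_rng(spec.seed)
    topology = build_complex_topology(spec.sequence)
    base = _complex_base_coords(topology, spec.sequence)
    pos = {(a.chain_id, a.residue_seq, a.name): i for i, a in enumerate(topology.atoms)}
    n_backbone = 45

    leave_ts = 1.0 / spec.mean_dwell_frames
    if spec.ts_occupancy in (0.0, 1.0):
        p_stay_ts, p_stay_non = (1.0, 1.0) if spec.ts_occupancy == 1.0 else (0.0, 1.0)
        if spec.ts_occupancy == 0.0:
            p_stay_ts = 1.0 - leave_ts
    else:
        enter = leave_ts * spec.ts_occupancy / (1.0 - spec.ts_occupancy)
        if enter > 1.0:
            raise SpecError("occupancy/dwell combination is infeasible")
        p_stay_ts, p_stay_non = 1.0 - leave_ts, 1.0 - enter

    probe_names = ("NZ", "CD", "HZ1", "HZ2")
    trajectories, labels = [], []
    for rep in range(spec.n_replicates):
        states = _simulate_chain(
            rng, spec.n_frames, p_stay_ts, p_stay_non, spec.ts_occupancy
        )
        coords = np.repeat(base[None], spec.n_frames, axis=0)
        coords[:, :n_backbone] += rng.normal(
            0.0, spec.backbone_noise_sd, size=(spec.n_frames, n_backbone, 3)
        )
        for ts in (True, False):
            mask = states == ts
            probe = _probe_coords(ts)
            for name in probe_names:
                coords[mask, pos[("P", 36, name)]] = probe[name]
        # planted residue-residue contacts: enzyme CG moved next to peptide CA
        for (pep_seq, enz_seq), freq in spec.contact_plan:
            on = rng.random(spec.n_frames) < freq
            target = coords[:, pos[("P", pep_seq, "CA")]] + np.array([0.0, 3.0, 0.0])
            coords[on, pos[("E", enz_seq, "CG")]] = target[on]
        for pep_seq, enz_seq in spec.ts_contact_pairs:
            target = coords[:, pos[("P", pep_seq, "CA")]] + np.array([0.0, 3.0, 0.0])
            coords[states, pos[("E", enz_seq, "CG")]] = target[states]
        frames = [
            Frame(coordinates=coords[t], frame_index=t, time_ps=20.0 * t)
            for t in range(spec.n_frames)
        ]
        trajectories.append(
            Trajectory(
                topology=topology,
                frames=frames,
                frame_interval_ps=20.0,
                condition_label=spec.condition_label,
                replicate_id=rep,
            )
        )
        labels.append(states)
    return trajectories, labels


def plant_ts_runs(
    spec: ComplexSpec, runs: list[tuple[int, int]]
) -> tuple[Trajectory, np.ndarray]:
    """Single replicate with TS-true frames exactly at the given runs.

    ``runs`` are (start_frame, length) pairs; everything else is non-TS.
    Used to test event detection with known dwell structure.
    """
    states = np.zeros(spec.n_frames, dtype=bool)
    for start, length in runs:
        states[start : start + length] = True
    base_spec = ComplexSpec(
        n_replicates=1, n_frames=spec.n_frames, ts_occupancy=0.0,
        mean_dwell_frames=spec.mean_dwell_frames, seed=spec.seed,
        condition_label=spec.condition_label, sequence=spec.sequence,
        backbone_noise_sd=spec.backbone_noise_sd,
    )
    [traj], _ = generate_complex_ensemble(base_spec)
    pos = {(a.chain_id, a.residue_seq, a.name): i
           for i, a in enumerate(traj.topology.atoms)}
    probe = _probe_coords(True)
    for t in np.flatnonzero(states):
        for name in ("NZ", "CD", "HZ1", "HZ2"):
            traj.frames[t].coordinates[pos[("P", 36, name)]] = probe[name]
    return traj, states


# --- unfolding (association) ensembles --------------------------------------

def generate_unfolding_ensemble(
    n_replicates: int,
    morph_fraction: float,
    n_frames: int = 50,
    noise_sd: float = 0.05,
    seed: int = 0,
    sequence: PeptideSequence = SSK36_SEQUENCE,
) -> tuple[list[Trajectory], np.ndarray]:
    """Docking-style ensembles: a fraction of replicates morph hairpin->extended.

    Morphing replicates interpolate linearly from the hairpin to the
    extended template over the trajectory (the unfolding signature: RMSD
    to the extended reference falls, the N-C distance grows).  The
    remaining replicates stay folded and tighten slightly - they drift
    away from the extended reference, so neither signature appears.
    Returns trajectories and the boolean morph flags (the planted truth
    for unfolding classification).
    """
    if not 0.0 <= morph_fraction <= 1.0:
        raise SpecError("morph fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    topology, hairpin = build_template("hairpin", sequence)
    _, extended = build_template("extended", sequence)
    n_morph = int(round(morph_fraction * n_replicates))
    flags = np.zeros(n_replicates, dtype=bool)
    flags[rng.choice(n_replicates, size=n_morph, replace=False)] = True
    trajectories = []
    alphas = np.linspace(0.0, 1.0, n_frames)
    for rep in range(n_replicates):
        if flags[rep]:
            base = (
                (1 - alphas)[:, None, None] * hairpin.coordinates[None]
                + alphas[:, None, None] * extended.coordinates[None]
            )
        else:
            # refolding replicate: relax from a slight hairpin/extended blend
            # back to the pure hairpin, drifting away from the extended
            # reference so neither unfolding signature appears
            blend = 0.9 * hairpin.coordinates + 0.1 * extended.coordinates
            base = (
                (1 - alphas)[:, None, None] * blend[None]
                + alphas[:, None, None] * hairpin.coordinates[None]
            )
        coords = base + rng.normal(0.0, noise_sd, size=base.shape)
        frames = [
            Frame(coordinates=coords[t], frame_index=t, time_ps=20.0 * t)
            for t in range(n_frames)
        ]
        trajectories.append(
            Trajectory(topology=topology, frames=frames, frame_interval_ps=20.0,
                       condition_label=sequence.name, replicate_id=rep)
        )
    return trajectories, flags


# --- melt curves -------------------------------------------------------------

@dataclass(frozen=True)
class MeltCurveSpec:
    """Temperature series for the two-state FRET forward model.

    Default temperatures follow the melt protocol: 5 to 95 degC in 10 degC
    steps.  ``noise_sd`` is relative (fraction of the model intensity).
    """

    params: TwoStateParams
    temperatures: tuple = tuple(float(t) for t in range(5, 96, 10))
    noise_sd: float = 0.0
    seed: int = 0
    condition_label: str = ""

    def __post_init__(self):
        temps = np.asarray(self.temperatures, dtype=float)
        if temps.size < 2 or np.any(np.diff(temps) <= 0):
            raise SpecError("temperatures must be strictly increasing")
        if self.noise_sd < 0:
            raise SpecError("noise sd must be non-negative")


def generate_melt_curve(spec: MeltCurveSpec) -> MeltCurve:
    """Noisy realization of the two-state melt forward model."""
    rng = np.random.default_rng(spec.seed)
    temps = np.asarray(spec.temperatures, dtype=float)
    model = predicted_intensity(temps, spec.params)
    noise = rng.normal(0.0, 1.0, size=model.shape) * spec.noise_sd * model
    return MeltCurve(
        temperature=temps,
        intensity=model + noise,
        condition_label=spec.condition_label,
    )
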