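"""Heavy-atom residue-contact maps and contact-frequency profiles.

A contact between two residues exists in a frame when any pair of their
heavy atoms is closer than the cutoff (4.5 A by default, strict).
Within one chain the two sequence neighbours on either side are ignored;
pairs across chains (peptide-enzyme) are never excluded.  Contact
frequencies are the fraction of frames in contact; difference profiles
between two conditions keep pairs whose absolute frequency change
exceeds the reporting threshold (over 35% by default, strict).

Residues are keyed as ``(chain_id, residue_seq)`` with author numbering,
so profiles from the two peptide conditions align positionally
(A/R31 merge onto residue 31, and so on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import centroid
from .trajectory import Frame, Topology, Trajectory, select

__all__ = [
    "ContactCriteria",
    "ContactFrequencyProfile",
    "DifferenceProfile",
    "frame_contacts",
    "contact_frequency",
    "conditional_frequency",
    "difference_profile",
    "distance_to_reference",
]

ResidueKey = tuple[str, int]  # (chain_id, author residue number)


@dataclass(frozen=True)
class ContactCriteria:
    cutoff: float = 4.5
    neighbor_exclusion: int = 2  # intra-chain sequence neighbours ignored
    heavy_only: bool = True

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.neighbor_exclusion < 0:
            raise ValueError("neighbor exclusion must be >= 0")


def _residue_layout(topology: Topology, criteria: ContactCriteria):
    """Atom indices grouped per residue key, heavy atoms only if requested."""
    keys: list[ResidueKey] = []
    groups: dict[ResidueKey, list[int]] = {}
    for i, atom in enumerate(topology.atoms):
        if criteria.heavy_only and not atom.is_heavy:
            continue
        key = (atom.chain_id, atom.residue_seq)
        if key not in groups:
            groups[key] = []
            keys.append(key)
        groups[key].append(i)
    return keys, groups


def _excluded(a: ResidueKey, b: ResidueKey, exclusion: int) -> bool:
    return a[0] == b[0] and abs(a[1] - b[1]) <= exclusion


def frame_contacts(
    frame: Frame, topology: Topology, criteria: ContactCriteria = ContactCriteria()
) -> set[frozenset]:
    """Unordered residue pairs in contact in one frame."""
    keys, groups = _residue_layout(topology, criteria)
    atom_idx = [i for key in keys for i in groups[key]]
    atom_res = [key for key in keys for _ in groups[key]]
    coords = frame.coordinates[atom_idx]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(criteria.cutoff)
    out: set[frozenset] = set()
    for i, j in pairs:
        ri, rj = atom_res[i], atom_res[j]
        if ri == rj or _excluded(ri, rj, criteria.neighbor_exclusion):
            continue
        # KD-tree pairs satisfy d <= cutoff; the criterion is strict
        if np.linalg.norm(coords[i] - coords[j]) < criteria.cutoff:
            out.add(frozenset((ri, rj)))
    return out


@dataclass
class ContactFrequencyProfile:
    """Fraction of frames each residue pair spends in contact."""

    frequencies: dict[frozenset, float]
    n_frames: int

    def frequency(self, res_a: ResidueKey, res_b: ResidueKey) -> float:
        return self.frequencies.get(frozenset((res_a, res_b)), 0.0)


def _frequency_over_frames(
    trajectory: Trajectory, frame_ids, criteria: ContactCriteria
) -> ContactFrequencyProfile:
    counts: dict[frozenset, int] = {}
    n = 0
    for t in frame_ids:
        n += 1
        for pair in frame_contacts(trajectory.frames[t], trajectory.topology, criteria):
            counts[pair] = counts.get(pair, 0) + 1
    return ContactFrequencyProfile(
        frequencies={p: c / n for p, c in counts.items()}, n_frames=n
    )


def contact_frequency(
    trajectory: Trajectory, criteria: ContactCriteria = ContactCriteria()
) -> ContactFrequencyProfile:
    """Per-pair contact fraction over all frames of a trajectory."""
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    return _frequency_over_frames(trajectory, range(trajectory.n_frames), criteria)


def conditional_frequency(
    trajectory: Trajectory,
    frame_mask,
    criteria: ContactCriteria = ContactCriteria(),
) -> ContactFrequencyProfile:
    """Contact fractions over a boolean frame mask (e.g. TS-like frames)."""
    mask = np.asarray(frame_mask, dtype=bool)
    if mask.size != trajectory.n_frames:
        raise ValueError("mask length does not match frame count")
    selected = np.flatnonzero(mask)
    if selected.size == 0:
        raise ValueError("mask selects no frames")
    return _frequency_over_frames(trajectory, selected, criteria)


def pooled_frequency(
    trajectories: list[Trajectory],
    criteria: ContactCriteria = ContactCriteria(),
    masks=None,
) -> ContactFrequencyProfile:
    """Frame-weighted contact fractions over an ensemble of replicates."""
    counts: dict[frozenset, float] = {}
    n = 0
    for r, traj in enumerate(trajectories):
        prof = (
            contact_frequency(traj, criteria)
            if masks is None
            else conditional_frequency(traj, masks[r], criteria)
        )
        for pair, freq in prof.frequencies.items():
            counts[pair] = counts.get(pair, 0.0) + freq * prof.n_frames
        n += prof.n_frames
    return ContactFrequencyProfile(
        frequencies={p: c / n for p, c in counts.items()}, n_frames=n
    )


@dataclass
class DifferenceProfile:
    """Signed frequency differences (condition A minus condition B).

    Only pairs with |difference| strictly above ``report_threshold`` are
    kept; positive values mean the contact is more frequent in A.
    """

    differences: dict[frozenset, float]
    report_threshold: float = 0.35

    def __len__(self) -> int:
        return len(self.differences)


def difference_profile(
    profile_a: ContactFrequencyProfile,
    profile_b: ContactFrequencyProfile,
    threshold: float = 0.35,
) -> DifferenceProfile:
    """Pairs whose contact frequency changes by more than the threshold."""
    pairs = set(profile_a.frequencies) | set(profile_b.frequencies)
    diffs = {}
    for pair in pairs:
        delta = profile_a.frequencies.get(pair, 0.0) - profile_b.frequencies.get(
            pair, 0.0
        )
        if abs(delta) > threshold:
            diffs[pair] = delta
    return DifferenceProfile(differences=diffs, report_threshold=threshold)


def distance_to_reference(
    trajectory: Trajectory,
    peptide_selection: str = "chain P and name N,CA,C",
    reference_selection: str = "chain E and residue_seq 1625 and name CA",
) -> dict[int, float]:
    """Mean residue-backbone-centroid to reference-point distance, per residue.

    The reference point defaults to the CA of enzyme residue 1625, a
    marker in the middle of the catalytic domain; distances are averaged
    over frames.
    """
    top = trajectory.topology
    pep_idx = select(top, peptide_selection)
    ref_idx = select(top, reference_selection)
    if not pep_idx or not ref_idx:
        raise ValueError("empty peptide or reference selection")
    by_residue: dict[int, list[int]] = {}
    for i in pep_idx:
        by_residue.setdefault(top.atoms[i].residue_seq, []).append(i)
    stack = trajectory.coordinate_stack()
    ref_point = stack[:, ref_idx, :].mean(axis=1)  # (n_frames, 3)
    out = {}
    for res_seq, idx in sorted(by_residue.items()):
        cent = stack[:, idx, :].mean(axis=1)
        out[res_seq] = float(np.linalg.norm(cent - ref_point, axis=1).mean())
    return out
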