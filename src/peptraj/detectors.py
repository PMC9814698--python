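"""Per-frame state detectors and dwell/event statistics.

Two geometric classifiers drive the analysis:

- the hairpin classifier: a frame is a hairpin iff the stem-loop distance
  (G33 CA - P38 CA) is under 7 A *and* the end-to-end distance
  (A29 CA - P43 CA) is under 15 A (both strict);
- the SN2 transition-state-like detector: target-lysine NZ within 4 A of
  the cofactor methyl carbon (strict), attack angle CD-NZ...C(methyl) in
  109 +/- 30 deg, and NZ...C(methyl)-S near-linear within 180 +/- 30 deg
  (angle windows closed).

Events are maximal runs of detector-true frames; long-lived events use a
minimum run length of 8 frames (160 ps at the 20 ps write interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import bond_angle, interatomic_distance, run_lengths
from .stats import sem
from .trajectory import Frame, Topology, Trajectory, select

logger = logging.getLogger(__name__)

__all__ = [
    "HairpinCriteria",
    "TSCriteria",
    "EventTable",
    "classify_hairpin",
    "hairpin_series",
    "is_ts_like",
    "ts_series",
    "ts_counts",
    "event_table",
    "docking_success",
    "fold_enrichment",
]


@dataclass(frozen=True)
class HairpinCriteria:
    stem_loop_max: float = 7.0
    end_to_end_max: float = 15.0
    stem_atoms: tuple = ((33, "CA"), (38, "CA"))
    end_atoms: tuple = ((29, "CA"), (43, "CA"))

    def __post_init__(self):
        if self.stem_loop_max <= 0 or self.end_to_end_max <= 0:
            raise ValueError("hairpin thresholds must be positive")


@dataclass(frozen=True)
class TSCriteria:
    """Geometric windows approximating the SN2 transition state."""

    d_max: float = 4.0
    attack_angle_center: float = 109.0
    attack_angle_width: float = 30.0
    linearity_center: float = 180.0
    linearity_width: float = 30.0
    nucleophile: tuple = (36, "NZ")   # lysine sidechain nitrogen
    nucleophile_anchor: tuple = (36, "CD")
    methyl_carbon: tuple = (1, "CE")  # cofactor methyl C (SAM)
    sulfur: tuple = (1, "SD")

    def __post_init__(self):
        if self.attack_angle_width <= 0 or self.linearity_width <= 0:
            raise ValueError("angle windows must have positive width")
        for center in (self.attack_angle_center, self.linearity_center):
            if not 0.0 < center <= 180.0:
                raise ValueError("angle centers must lie in (0, 180]")


@dataclass
class EventTable:
    """Dwell events (replicate, start frame, length) at a minimum length."""

    events: list[tuple[int, int, int]]
    min_len: int = 8

    def __post_init__(self):
        if any(length < self.min_len for _, _, length in self.events):
            raise ValueError("event shorter than min_len")
        self.events = sorted(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def lengths(self) -> list[int]:
        return [length for _, _, length in self.events]


def _resolve(topology: Topology, residue_seq: int, name: str) -> int:
    return topology.index_of(residue_seq, name)


def _hairpin_indices(topology: Topology, criteria: HairpinCriteria):
    (r1, a1), (r2, a2) = criteria.stem_atoms
    (r3, a3), (r4, a4) = criteria.end_atoms
    return (
        _resolve(topology, r1, a1), _resolve(topology, r2, a2),
        _resolve(topology, r3, a3), _resolve(topology, r4, a4),
    )


def classify_hairpin(
    frame: Frame, topology: Topology, criteria: HairpinCriteria = HairpinCriteria()
) -> bool:
    """True iff both hairpin distance criteria hold (strict inequalities)."""
    i1, i2, i3, i4 = _hairpin_indices(topology, criteria)
    c = frame.coordinates
    stem = interatomic_distance(c, i1, i2)
    ends = interatomic_distance(c, i3, i4)
    return stem < criteria.stem_loop_max and ends < criteria.end_to_end_max


def hairpin_series(
    trajectory: Trajectory, criteria: HairpinCriteria = HairpinCriteria()
) -> np.ndarray:
    """Vectorized per-frame hairpin flags for one trajectory."""
    i1, i2, i3, i4 = _hairpin_indices(trajectory.topology, criteria)
    stack = trajectory.coordinate_stack()
    stem = np.linalg.norm(stack[:, i1] - stack[:, i2], axis=1)
    ends = np.linalg.norm(stack[:, i3] - stack[:, i4], axis=1)
    return (stem < criteria.stem_loop_max) & (ends < criteria.end_to_end_max)


def _ts_indices(topology: Topology, criteria: TSCriteria):
    return (
        _resolve(topology, *criteria.nucleophile),
        _resolve(topology, *criteria.nucleophile_anchor),
        _resolve(topology, *criteria.methyl_carbon),
        _resolve(topology, *criteria.sulfur),
    )


def is_ts_like(
    frame: Frame, topology: Topology, criteria: TSCriteria = TSCriteria()
) -> bool:
    """True iff the frame satisfies all three SN2 geometric criteria."""
    nz, cd, cme, s = _ts_indices(topology, criteria)
    c = frame.coordinates
    if interatomic_distance(c, nz, cme) >= criteria.d_max:
        return False
    attack = bond_angle(c, cd, nz, cme)
    if abs(attack - criteria.attack_angle_center) > criteria.attack_angle_width:
        return False
    linear = bond_angle(c, nz, cme, s)
    return abs(linear - criteria.linearity_center) <= criteria.linearity_width


def ts_series(
    trajectory: Trajectory, criteria: TSCriteria = TSCriteria()
) -> np.ndarray:
    """Vectorized per-frame TS-like flags for one trajectory."""
    nz, cd, cme, s = _ts_indices(trajectory.topology, criteria)
    stack = trajectory.coordinate_stack()
    d = np.linalg.norm(stack[:, nz] - stack[:, cme], axis=1)

    def angles(a, b, c_):
        v1 = stack[:, a] - stack[:, b]
        v2 = stack[:, c_] - stack[:, b]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    attack = angles(cd, nz, cme)
    linear = angles(nz, cme, s)
    return (
        (d < criteria.d_max)
        & (np.abs(attack - criteria.attack_angle_center) <= criteria.attack_angle_width)
        & (np.abs(linear - criteria.linearity_center) <= criteria.linearity_width)
    )


@dataclass
class TSCountSummary:
    counts: list[int]
    mean: float
    sem: float | None


def ts_counts(
    trajectories: list[Trajectory], criteria: TSCriteria = TSCriteria()
) -> TSCountSummary:
    """Per-replicate TS-like frame counts with mean and SEM.

    With a single replicate the SEM is undefined and reported as None.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    counts = [int(np.count_nonzero(ts_series(t, criteria))) for t in trajectories]
    mean = float(np.mean(counts))
    if len(counts) >= 2:
        err = sem(counts)
    else:
        logger.warning("SEM undefined for a single replicate")
        err = None
    return TSCountSummary(counts=counts, mean=mean, sem=err)


_DETECTORS = {"hairpin": hairpin_series, "ts_like": ts_series}


def event_table(
    trajectories: list[Trajectory],
    detector: str = "ts_like",
    min_len: int = 8,
    criteria=None,
) -> EventTable:
    """Maximal detector-true runs of length >= ``min_len`` across replicates."""
    if detector not in _DETECTORS:
        raise ValueError(f"unknown detector {detector!r}")
    fn = _DETECTORS[detector]
    events = []
    for traj in trajectories:
        series = fn(traj, criteria) if criteria is not None else fn(traj)
        for start, length in run_lengths(series).filtered(min_len):
            events.append((traj.replicate_id, start, length))
    return EventTable(events=events, min_len=min_len)


def docking_success(
    trajectory: Trajectory, ts_criteria: TSCriteria = TSCriteria()
) -> bool:
    """True iff any frame of the trajectory is TS-like."""
    return bool(np.any(ts_series(trajectory, ts_criteria)))


def fold_enrichment(count_a: float, count_b: float) -> float:
    """count_a / count_b, reported to one decimal."""
    if count_b == 0:
        raise ZeroDivisionError(
            f"fold enrichment undefined: counts ({count_a}, {count_b})"
        )
    return round(count_a / count_b, 1)
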