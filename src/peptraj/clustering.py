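"""Pooled conformational clustering by backbone RMSD.

Solution trajectories from all conditions are pooled so every conformer
can cluster with every other, then partitioned into k groups with a
k-hybrid scheme: farthest-point (k-centers) seeding on the pairwise
Kabsch-superposed backbone RMSD metric, followed by k-medoids refinement
sweeps.  Each cluster is represented by its medoid ("centroid
structure"), the member minimizing summed RMSD to its co-members, and is
characterised by its per-condition composition.

The backbone atom set is fixed to N, CA and C of each peptide residue
(45 atoms for a 15-mer).  All tie-breaks use the lowest pooled index and
cluster labels are ordered by descending size, so results are
deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import pairwise_rmsd_matrix, rmsd_to_many
from .stats import TestResult, t_test_equal_variance
from .trajectory import Trajectory, select

logger = logging.getLogger(__name__)

__all__ = [
    "PooledConformers",
    "ClusterModel",
    "CompositionTable",
    "pool",
    "cluster_khybrid",
    "medoid_structures",
    "composition",
    "subset_robustness",
    "enrichment_test",
]

BACKBONE_SELECTION = "name N,CA,C"


@dataclass
class PooledConformers:
    """Order-stable pooled backbone conformers with provenance."""

    coords: np.ndarray  # (n, n_backbone_atoms, 3)
    provenance: list[tuple[str, int, int]]  # (condition_label, replicate, frame)

    def __len__(self) -> int:
        return len(self.coords)

    def subset(self, indices) -> "PooledConformers":
        indices = np.asarray(indices, dtype=int)
        return PooledConformers(
            coords=self.coords[indices],
            provenance=[self.provenance[i] for i in indices],
        )


def pool(trajectories: list[Trajectory]) -> PooledConformers:
    """Pool backbone conformers across conditions, keeping provenance.

    All trajectories must share the backbone layout (same residue count,
    N/CA/C per residue); input order is preserved within each trajectory.
    """
    if not trajectories:
        raise ValueError("nothing to pool")
    blocks, provenance = [], []
    layout = None
    for traj in trajectories:
        idx = select(traj.topology, BACKBONE_SELECTION)
        this_layout = [
            (traj.topology.atoms[i].residue_seq, traj.topology.atoms[i].name)
            for i in idx
        ]
        if layout is None:
            layout = this_layout
        elif this_layout != layout:
            raise ValueError("heterogeneous backbone layout across trajectories")
        blocks.append(traj.coordinate_stack(idx))
        provenance.extend(
            (traj.condition_label, traj.replicate_id, f)
            for f in range(traj.n_frames)
        )
    return PooledConformers(coords=np.concatenate(blocks), provenance=provenance)


@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray  # cluster id per pooled conformer
    medoid_indices: np.ndarray  # pooled index of each cluster medoid
    pooled: PooledConformers
    seed: int
    landmark_approximation: bool = False

    def cluster_members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == label)


def _seed_kcenters(coords: np.ndarray, k: int, rng) -> list[int]:
    """Farthest-point seeding; first center drawn by the seeded rng."""
    n = len(coords)
    centers = [int(rng.integers(n))]
    min_dist = rmsd_to_many(coords[centers[0]], coords)
    while len(centers) < k:
        nxt = int(np.argmax(min_dist))  # argmax takes the lowest index on ties
        centers.append(nxt)
        min_dist = np.minimum(min_dist, rmsd_to_many(coords[nxt], coords))
    return centers


def _assign(coords: np.ndarray, medoid_idx: list[int]) -> np.ndarray:
    dists = np.stack([rmsd_to_many(coords[m], coords) for m in medoid_idx])
    return np.argmin(dists, axis=0)  # ties -> lowest cluster id


def _best_medoid(member_idx: np.ndarray, coords: np.ndarray) -> int:
    """Member minimizing summed RMSD to co-members; ties -> lowest index."""
    if len(member_idx) == 1:
        return int(member_idx[0])
    sub = coords[member_idx]
    sums = pairwise_rmsd_matrix(sub).sum(axis=1)
    return int(member_idx[int(np.argmin(sums))])


def cluster_khybrid(
    pooled: PooledConformers,
    k: int,
    seed: int = 0,
    n_sweeps: int = 10,
    max_exact: int = 4000,
    n_landmarks: int = 1000,
) -> ClusterModel:
    """k-centers seeding followed by medoid-refinement sweeps.

    For pooled sets larger than ``max_exact`` a landmark approximation is
    used: ``n_landmarks`` conformers are clustered exactly and the rest
    assigned to the nearest medoid; the model is flagged accordingly.
    """
    n = len(pooled)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} conformers")
    rng = np.random.default_rng(seed)

    landmark = n > max_exact
    if landmark:
        chosen = np.sort(rng.choice(n, size=min(n_landmarks, n), replace=False))
        work = pooled.subset(chosen)
        back = chosen
        logger.info("landmark approximation: clustering %d of %d conformers",
                    len(chosen), n)
    else:
        work = pooled
        back = np.arange(n)

    coords = work.coords
    medoids = _seed_kcenters(coords, k, rng)
    assignments = _assign(coords, medoids)
    objective = np.inf
    for _ in range(n_sweeps):
        new_medoids = []
        for label in range(k):
            members = np.flatnonzero(assignments == label)
            if members.size == 0:
                new_medoids.append(medoids[label])  # keep empty cluster's seed
                continue
            new_medoids.append(_best_medoid(members, coords))
        assignments = _assign(coords, new_medoids)
        new_objective = float(
            sum(
                rmsd_to_many(coords[m], coords[assignments == j]).sum()
                for j, m in enumerate(new_medoids)
            )
        )
        converged = new_medoids == medoids
        medoids = new_medoids
        if converged or new_objective >= objective - 1e-12:
            objective = min(objective, new_objective)
            break
        objective = new_objective

    # map work-local medoid indices to pooled indices
    medoid_pooled = [int(back[m]) for m in medoids]
    if landmark:
        full_assign = _assign(pooled.coords, medoid_pooled)
    else:
        full_assign = assignments

    # relabel clusters by descending size, ties by lowest medoid pooled index
    sizes = np.bincount(full_assign, minlength=k)
    order = sorted(range(k), key=lambda j: (-sizes[j], medoid_pooled[j]))
    relabel = {old: new for new, old in enumerate(order)}
    final_assign = np.array([relabel[a] for a in full_assign])
    final_medoids = np.array([medoid_pooled[j] for j in order])
    return ClusterModel(
        k=k,
        assignments=final_assign,
        medoid_indices=final_medoids,
        pooled=pooled,
        seed=seed,
        landmark_approximation=landmark,
    )


def medoid_structures(model: ClusterModel) -> list[np.ndarray]:
    """Backbone coordinates of each cluster's medoid, recomputed exactly.

    The medoid is the member minimizing summed RMSD to all co-members
    (lowest pooled index on ties).  Landmark models refresh medoids over
    the full membership here.
    """
    coords = model.pooled.coords
    out = []
    for label in range(model.k):
        members = model.cluster_members(label)
        if members.size == 0:
            out.append(coords[model.medoid_indices[label]])
            continue
        if members.size > 4000:
            # summed distance to co-members via one-vs-all from each candidate
            # would be O(c^2); sample candidates around the stored medoid
            best = model.medoid_indices[label]
        else:
            best = _best_medoid(members, coords)
            model.medoid_indices[label] = best
        out.append(coords[best])
    return out


@dataclass
class CompositionTable:
    """Per-cluster condition counts and percentages."""

    counts: dict[int, dict[str, int]]
    percentages: dict[int, dict[str, float]]
    totals: dict[str, int]

    def percentage(self, cluster: int, condition: str) -> float:
        return self.percentages[cluster].get(condition, 0.0)


def composition(model: ClusterModel) -> CompositionTable:
    """Condition make-up of every cluster (percentages sum to 100)."""
    conditions = [p[0] for p in model.pooled.provenance]
    counts: dict[int, dict[str, int]] = {j: {} for j in range(model.k)}
    totals: dict[str, int] = {}
    for label, cond in zip(model.assignments, conditions):
        counts[int(label)][cond] = counts[int(label)].get(cond, 0) + 1
        totals[cond] = totals.get(cond, 0) + 1
    percentages = {
        j: {
            cond: 100.0 * c / sum(cluster_counts.values())
            for cond, c in cluster_counts.items()
        }
        if cluster_counts else {}
        for j, cluster_counts in counts.items()
    }
    return CompositionTable(counts=counts, percentages=percentages, totals=totals)


@dataclass
class SubsetRobustnessEntry:
    fraction: float
    repeat: int
    medoid_rmsd: list[float]  # per full-run cluster, subset medoid vs full medoid
    composition_delta: dict[int, dict[str, float]]


def subset_robustness(
    pooled: PooledConformers,
    k: int,
    fractions=(0.5, 0.3, 0.1),
    n_repeats: int = 3,
    seed: int = 0,
) -> list[SubsetRobustnessEntry]:
    """Re-cluster random subsets and compare medoids/compositions to the full run.

    Subset clusters are matched to full-run clusters by nearest medoid
    RMSD.  Subsets smaller than k are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    full = cluster_khybrid(pooled, k, seed=seed)
    full_comp = composition(full)
    full_medoids = np.stack([pooled.coords[m] for m in full.medoid_indices])
    out = []
    for fraction in fractions:
        if not 0.0 < fraction <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
        size = int(round(fraction * len(pooled)))
        for repeat in range(n_repeats):
            if size < k:
                logger.warning("subset of %d < k=%d skipped", size, k)
                continue
            if fraction == 1.0:
                idx = np.arange(len(pooled))
            else:
                idx = np.sort(rng.choice(len(pooled), size=size, replace=False))
            sub_model = cluster_khybrid(pooled.subset(idx), k, seed=seed)
            sub_comp = composition(sub_model)
            sub_medoids = np.stack(
                [sub_model.pooled.coords[m] for m in sub_model.medoid_indices]
            )
            # match each full cluster to its nearest subset medoid
            mapping, med_rmsd = [], []
            for j in range(k):
                dists = rmsd_to_many(full_medoids[j], sub_medoids)
                match = int(np.argmin(dists))
                mapping.append(match)
                med_rmsd.append(float(dists[match]))
            delta = {
                j: {
                    cond: sub_comp.percentage(mapping[j], cond)
                    - full_comp.percentage(j, cond)
                    for cond in full_comp.totals
                }
                for j in range(k)
            }
            out.append(
                SubsetRobustnessEntry(
                    fraction=fraction, repeat=repeat,
                    medoid_rmsd=med_rmsd, composition_delta=delta,
                )
            )
    return out


def enrichment_test(shares_a, shares_b) -> TestResult:
    """Equal-variance two-tailed t-test on per-run condition shares."""
    return t_test_equal_variance(shares_a, shares_b)
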