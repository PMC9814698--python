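"""Geometric primitives shared by every trajectory analysis stage.

Superposition follows the Kabsch algorithm (SVD with reflection
correction), RMSD is the plain root-mean-square deviation over a chosen
atom set, and run-length encoding turns per-frame boolean state series
into dwell events.  Distances are in angstroms, angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "RunLengthSeries",
    "kabsch_superpose",
    "rmsd",
    "pairwise_rmsd_matrix",
    "rmsd_to_many",
    "interatomic_distance",
    "bond_angle",
    "centroid",
    "run_lengths",
    "DegenerateGeometryError",
]

# average atomic masses for the elements that occur in backbone + probe sets
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}


class DegenerateGeometryError(ValueError):
    """Raised when a geometric operation has no well-defined answer."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform: ``y = x @ rotation.T + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class RunLengthSeries:
    """Boolean per-frame series with its maximal true-runs.

    ``runs`` holds ``(start_frame, length)`` pairs, ordered, non-overlapping;
    run lengths sum to the number of true frames.
    """

    values: np.ndarray
    runs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_true(self) -> int:
        return int(np.count_nonzero(self.values))

    def lengths(self) -> list[int]:
        return [length for _, length in self.runs]

    def filtered(self, min_len: int) -> list[tuple[int, int]]:
        return [(s, n) for s, n in self.runs if n >= min_len]


def _as_coords(x: np.ndarray) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected (n, 3) coordinates, got shape {a.shape}")
    return a


def kabsch_superpose(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[RigidTransform, np.ndarray]:
    """Least-squares superpose ``mobile`` onto ``reference``.

    The optimal proper rotation is found over ``fit_indices`` (all atoms if
    omitted) and applied to *all* mobile atoms.  Requires at least three
    non-collinear fit atoms.
    """
    mobile = _as_coords(mobile_coords)
    reference = _as_coords(reference_coords)
    if fit_indices is None:
        fit_indices = np.arange(len(mobile))
    fit_indices = np.asarray(fit_indices, dtype=int)
    if len(fit_indices) < 3:
        raise DegenerateGeometryError("superposition needs >= 3 fit atoms")
    m = mobile[fit_indices]
    r = reference[fit_indices]
    if m.shape != r.shape:
        raise ValueError("mobile/reference fit sets differ in size")

    m_center = m.mean(axis=0)
    r_center = r.mean(axis=0)
    mc = m - m_center
    rc = r - r_center
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(mc, tol=1e-8) < 2:
        raise DegenerateGeometryError("fit atoms are collinear")

    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = r_center - rotation @ m_center
    transform = RigidTransform(rotation=rotation, translation=translation)
    return transform, transform.apply(mobile)


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray, indices=None) -> float:
    """Root-mean-square deviation over ``indices`` (no superposition here)."""
    a = _as_coords(coords_a)
    b = _as_coords(coords_b)
    if indices is not None:
        indices = np.asarray(indices, dtype=int)
        if indices.size == 0:
            raise ValueError("empty index set for RMSD")
        a = a[indices]
        b = b[indices]
    if a.shape != b.shape:
        raise ValueError("coordinate sets differ in shape")
    if len(a) == 0:
        raise ValueError("empty index set for RMSD")
    diff = a - b
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Kabsch-fit RMSD between two equally-sized coordinate sets."""
    _, moved = kabsch_superpose(mobile, reference)
    return rmsd(moved, reference)


def _batched_kabsch_rmsd(stack_a: np.ndarray, stack_b: np.ndarray) -> np.ndarray:
    """Minimum (post-superposition) RMSD for paired coordinate stacks.

    ``stack_a``/``stack_b`` have shape (m, n_atoms, 3); returns (m,).
    Uses the covariance-SVD identity: min RMSD**2 = (Ga + Gb - 2*sum(d*s)) / n
    where s are singular values of the covariance and d corrects reflection.
    """
    a = stack_a - stack_a.mean(axis=1, keepdims=True)
    b = stack_b - stack_b.mean(axis=1, keepdims=True)
    n = a.shape[1]
    ga = np.sum(a * a, axis=(1, 2))
    gb = np.sum(b * b, axis=(1, 2))
    cov = np.einsum("mni,mnj->mij", a, b)
    u, s, vt = np.linalg.svd(cov)
    det = np.linalg.det(u) * np.linalg.det(vt)
    corrected = s[:, 0] + s[:, 1] + np.sign(det) * s[:, 2]
    msd = np.maximum((ga + gb - 2.0 * corrected) / n, 0.0)
    return np.sqrt(msd)


def rmsd_to_many(reference: np.ndarray, stack: np.ndarray) -> np.ndarray:
    """Kabsch-fit RMSD of one structure against a stack of structures."""
    reference = np.asarray(reference, dtype=float)
    stack = np.asarray(stack, dtype=float)
    ref = np.broadcast_to(reference, stack.shape)
    return _batched_kabsch_rmsd(np.ascontiguousarray(ref), stack)


def pairwise_rmsd_matrix(stack: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Full symmetric matrix of pairwise Kabsch-fit RMSDs.

    Chunked over rows to bound the size of the batched SVD.
    """
    stack = np.asarray(stack, dtype=float)
    m = len(stack)
    out = np.zeros((m, m))
    for i in range(m):
        js = np.arange(i + 1, m)
        for lo in range(0, len(js), chunk):
            sel = js[lo : lo + chunk]
            vals = _batched_kabsch_rmsd(
                np.broadcast_to(stack[i], (len(sel),) + stack.shape[1:]).copy(),
                stack[sel],
            )
            out[i, sel] = vals
            out[sel, i] = vals
    return out


def interatomic_distance(coords: np.ndarray, i: int, j: int) -> float:
    c = _as_coords(coords)
    return float(np.linalg.norm(c[i] - c[j]))


def bond_angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k in degrees, vertex at j; in [0, 180]."""
    c = _as_coords(coords)
    v1 = c[i] - c[j]
    v2 = c[k] - c[j]
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise DegenerateGeometryError("coincident points at the angle vertex")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def centroid(
    coords: np.ndarray,
    indices,
    weights: str = "geometric",
    elements=None,
) -> np.ndarray:
    """Weighted mean position of the selected atoms.

    ``weights="mass"`` uses average atomic masses and requires ``elements``
    (one symbol per selected atom, or per all atoms to be indexed).
    """
    c = _as_coords(coords)
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("empty index set for centroid")
    pts = c[indices]
    if weights == "geometric":
        return pts.mean(axis=0)
    if weights == "mass":
        if elements is None:
            raise ValueError("mass-weighted centroid needs element symbols")
        elements = list(elements)
        if len(elements) == len(c):
            elements = [elements[i] for i in indices]
        if len(elements) != len(indices):
            raise ValueError("element list does not match selection")
        w = np.array([ATOMIC_MASS[e] for e in elements])
        return (pts * w[:, None]).sum(axis=0) / w.sum()
    raise ValueError(f"unknown weighting {weights!r}")


def run_lengths(series) -> RunLengthSeries:
    """Maximal true-runs of a boolean series.

    A run that is still open at the final frame is closed there.
    """
    values = np.asarray(series, dtype=bool)
    runs: list[tuple[int, int]] = []
    if values.size:
        padded = np.concatenate(([False], values, [False])).astype(int)
        edges = np.diff(padded)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        runs = [(int(s), int(e - s)) for s, e in zip(starts, ends)]
    return RunLengthSeries(values=values, runs=runs)
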