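"""Coordinate representations and metrics for conformational ensembles.

Transforms here serve two consumers: the membership-function learner,
which needs rotation/translation-invariant inputs for molecular systems
(pairwise interatomic distances, backbone internal coordinates), and the
clustering stage, which needs a metric between conformations (optimal
superposition RMSD, or plain Euclidean distance for non-molecular
systems) and a notion of cluster average structure.

All operations accept plain NumPy arrays; optional readers for standard
trajectory formats are provided behind a guarded import of mdtraj.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

__all__ = [
    "ConformationSet",
    "FeatureMatrix",
    "DegenerateGeometryError",
    "pairwise_distances",
    "internal_coordinates",
    "kabsch_rmsd",
    "kabsch_align",
    "pairwise_rmsd_matrix",
    "mean_structure",
    "load_conformations",
]


class DegenerateGeometryError(ValueError):
    """Raised when three consecutive chain atoms are collinear."""


@dataclass(frozen=True)
class ConformationSet:
    """A set of N conformations: molecular ``(N, A, 3)`` or flat ``(N, d)``."""

    coordinates: np.ndarray
    labels: Optional[Sequence] = None

    def __post_init__(self) -> None:
        if self.coordinates.ndim not in (2, 3):
            raise ValueError("coordinates must be (N, d) or (N, A, 3)")
        if self.coordinates.ndim == 3 and self.coordinates.shape[2] != 3:
            raise ValueError("molecular coordinates must be (N, A, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_states(self) -> int:
        return self.coordinates.shape[0]

    @property
    def is_molecular(self) -> bool:
        return self.coordinates.ndim == 3

    @property
    def atom_count(self) -> int:
        if not self.is_molecular:
            raise ValueError("flat conformation sets have no atom count")
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class FeatureMatrix:
    values: np.ndarray  # (N, F)
    feature_kind: str  # cartesian | pairwise_distance | internal
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be an (N, F) matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    def save(self, path) -> None:
        np.savez(path, values=self.values,
                 feature_kind=self.feature_kind, provenance=self.provenance)

    @classmethod
    def load(cls, path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as data:
            return cls(values=data["values"],
                       feature_kind=str(data["feature_kind"]),
                       provenance=str(data["provenance"]))


def pairwise_distances(conformation: np.ndarray) -> np.ndarray:
    """Upper-triangle Euclidean distances between all atom pairs.

    Row-major (i<j) order; length A(A-1)/2.  Invariant under rigid
    motions of the conformation, which is why it is the default input
    representation for molecular membership functions.
    """
    conformation = np.asarray(conformation, dtype=float)
    if conformation.ndim != 2 or conformation.shape[0] < 2:
        raise ValueError("conformation must be (A, 3) with A >= 2")
    return pdist(conformation)


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral, IUPAC convention: positive for a right-handed
    (clockwise, viewed from p1 towards p2) rotation of p3 out of the
    p0-p1-p2 plane; range (-pi, pi]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1))
    angle = np.arctan2(y, x)
    # fold -pi onto +pi so the planar trans case is reported as +pi
    if angle <= -np.pi + 1e-12:
        angle = np.pi
    return float(angle)


def internal_coordinates(chain: np.ndarray) -> np.ndarray:
    """Bond lengths, bond angles and dihedrals along a declared atom chain.

    Returns the concatenation of A-1 bond lengths (nm), A-2 angles
    (rad, in (0, pi)) and A-3 dihedrals (rad, in (-pi, pi]).  Atoms are
    taken in the order given; for topologies that are not a simple
    chain, pass an explicitly ordered index selection.
    """
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 2 or chain.shape[1] != 3 or chain.shape[0] < 4:
        raise ValueError("chain must be (A, 3) with A >= 4")
    bonds = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    if np.any(bonds == 0):
        raise DegenerateGeometryError("coincident consecutive atoms in chain")
    angles = np.empty(len(chain) - 2)
    for i in range(len(chain) - 2):
        u = chain[i] - chain[i + 1]
        v = chain[i + 2] - chain[i + 1]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if abs(cosang) >= 1.0 - 1e-10:
            raise DegenerateGeometryError(
                f"atoms {i}, {i + 1}, {i + 2} are collinear; bond angle undefined"
            )
        angles[i] = np.arccos(np.clip(cosang, -1.0, 1.0))
    dihedrals = np.array(
        [_dihedral(*chain[i : i + 4]) for i in range(len(chain) - 3)]
    )
    return np.concatenate([bonds, angles, dihedrals])


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def kabsch_align(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigidly superpose ``mobile`` onto ``reference`` (proper rotations
    only) and return the transformed coordinates."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("conformations must share the same shape")
    mc, rc = _center(mobile), _center(reference)
    rot, _ = Rotation.align_vectors(rc, mc)
    return rot.apply(mc) + reference.mean(axis=0)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two conformations over rigid motions.

    Uses the standard quaternion/SVD superposition (reflections
    excluded).  Symmetric in its arguments and zero iff the two
    conformations are congruent.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("conformations must share the same (A, 3) shape")
    ac, bc = _center(a), _center(b)
    _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(a.shape[0]))


def pairwise_rmsd_matrix(conformations: ConformationSet | np.ndarray,
                         metric: str = "rmsd") -> np.ndarray:
    """Symmetric N x N distance matrix between conformations.

    ``metric='rmsd'`` (optimal superposition, molecular sets) or
    ``metric='euclidean'`` (flat coordinate distance, used for
    non-molecular systems such as the 2D toy landscape).
    """
    coords = conformations.coordinates if isinstance(conformations, ConformationSet) \
        else np.asarray(conformations, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two conformations")
    if metric == "euclidean":
        flat = coords.reshape(n, -1)
        return squareform(pdist(flat))
    if metric == "rmsd":
        if coords.ndim != 3:
            raise ValueError("rmsd metric requires (N, A, 3) coordinates")
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = kabsch_rmsd(coords[i], coords[j])
        return out
    raise ValueError(f"unknown metric {metric!r}; expected 'rmsd' or 'euclidean'")


def mean_structure(members: ConformationSet | np.ndarray,
                   metric: str = "rmsd",
                   tol: float = 1e-6,
                   max_iter: int = 50) -> np.ndarray:
    """Average structure of a set of conformations.

    For the Euclidean metric this is the plain coordinate mean.  For the
    RMSD metric the members are iteratively aligned to the running mean
    (align all, re-average, repeat) until the mean moves by less than
    ``tol`` or ``max_iter`` rounds have run — the standard procedure for
    a Karcher-type mean under rigid-motion equivalence.
    """
    coords = members.coordinates if isinstance(members, ConformationSet) \
        else np.asarray(members, dtype=float)
    if coords.shape[0] < 1:
        raise ValueError("mean_structure requires at least one member")
    if metric == "euclidean" or coords.ndim == 2:
        return coords.mean(axis=0)
    if metric != "rmsd":
        raise ValueError(f"unknown metric {metric!r}")
    ref = coords[0]
    for _ in range(max_iter):
        aligned = np.array([kabsch_align(c, ref) for c in coords])
        new_ref = aligned.mean(axis=0)
        shift = np.max(np.abs(new_ref - ref))
        ref = new_ref
        if shift < tol:
            break
    return ref


def save_xyz(path, coordinates: np.ndarray, elements: Optional[Sequence[str]] = None,
             comment: str = "") -> None:
    """Write one or more conformations to a plain XYZ file (coordinates
    in nm are converted to Angstrom, the format's conventional unit)."""
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coordinates must be (A, 3) or (N, A, 3)")
    n_atoms = coords.shape[1]
    elements = list(elements) if elements is not None else ["C"] * n_atoms
    if len(elements) != n_atoms:
        raise ValueError("one element symbol per atom required")
    with open(path, "w") as fh:
        for frame in coords:
            fh.write(f"{n_atoms}\n{comment}\n")
            for el, (x, y, z) in zip(elements, frame * 10.0):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def load_conformations(path, topology=None, atom_indices=None) -> ConformationSet:
    """Read conformations from PDB/XYZ/DCD/XTC via mdtraj (optional).

    Returns coordinates in nm as a :class:`ConformationSet`.
    """
    try:
        import mdtraj as md
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading trajectory formats requires the optional dependency mdtraj"
        ) from exc
    traj = md.load(str(path), top=topology) if topology else md.load(str(path))
    xyz = traj.xyz
    if atom_indices is not None:
        xyz = xyz[:, atom_indices, :]
    return ConformationSet(coordinates=np.asarray(xyz, dtype=float))
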