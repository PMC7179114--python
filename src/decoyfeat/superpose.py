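"""Rigid-body superposition, lRMSD, centralization, and dataset splitting.

The data-preparation stage turns an ensemble of CA traces into the matrix a
featurization model consumes: every structure is optimally superposed onto a
reference structure (removing translation and rotation), and the reference is
then subtracted to obtain per-atom deviation vectors dS.  A reconstructed
structure is simply S^ = dS^ + S_reference, so reconstruction error computed
on deviations equals reconstruction error computed on coordinates.

RMSD convention: sqrt of the mean over atoms of the squared per-atom
distance.  lRMSD is this RMSD after optimal (Kabsch) superposition, the
standard measure of dissimilarity between two conformations of the same
chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError, ShapeError
from .structure_io import Conformation, DecoyEnsemble

__all__ = [
    "RigidTransform",
    "DeviationDataset",
    "kabsch_superpose",
    "lrmsd",
    "centralize",
    "reconstruct",
    "split_dataset",
]


@dataclass
class RigidTransform:
    """A proper rotation plus translation: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ShapeError("rigid transform requires a 3x3 rotation and 3-vector")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class DeviationDataset:
    """Centralized deviations of an ensemble from its reference structure.

    ``deviations`` is an ``m x 3n`` matrix; row i is structure i superposed
    onto the reference with the reference subtracted.  ``split`` maps
    'train'/'validation'/'test' to disjoint row-index arrays covering all
    rows (empty until :func:`split_dataset` is applied).
    """

    reference: Conformation
    deviations: np.ndarray
    labels: np.ndarray | None = None
    split: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.deviations = np.asarray(self.deviations, dtype=float)
        if self.deviations.ndim != 2:
            raise ShapeError("deviations must be a 2-D matrix")
        if self.deviations.shape[1] != 3 * self.reference.n_atoms:
            raise ShapeError(
                f"deviation width {self.deviations.shape[1]} does not match "
                f"reference dimension {3 * self.reference.n_atoms}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=float)
            if self.labels.shape != (self.deviations.shape[0],):
                raise ShapeError("labels length must match number of deviations")

    @property
    def n_structures(self) -> int:
        return self.deviations.shape[0]

    @property
    def input_dim(self) -> int:
        return self.deviations.shape[1]

    def rows(self, part: str) -> np.ndarray:
        """Deviation rows of one split part ('train'/'validation'/'test')."""
        return self.deviations[self.split[part]]

    def part_labels(self, part: str) -> np.ndarray:
        if self.labels is None:
            raise InvalidSpecError("dataset carries no lRMSD labels")
        return self.labels[self.split[part]]

    def save_split(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: v.tolist() for k, v in self.split.items()}, fh)

    def load_split(self, path) -> None:
        with open(path) as fh:
            self.split = {k: np.asarray(v, dtype=int) for k, v in json.load(fh).items()}


def _as_coords(obj) -> np.ndarray:
    return obj.coords if isinstance(obj, Conformation) else np.asarray(obj, dtype=float)


def kabsch_superpose(mobile, target) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``target`` (Kabsch).

    Returns the proper-rotation transform minimizing the RMSD between the
    transformed mobile coordinates and the target, and that minimal RMSD.
    Reflections are excluded.  For degenerate (e.g. collinear) inputs the
    SVD solution is still returned, but the rotation may not be unique.
    """
    P = _as_coords(mobile)
    Q = _as_coords(target)
    if P.shape[0] == 0:
        raise ShapeError("cannot superpose empty conformations")
    if P.shape != Q.shape:
        raise ShapeError(f"atom-count mismatch: {P.shape} vs {Q.shape}")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transform = RigidTransform(R, t)
    diff = transform.apply(P) - Q
    rmsd = float(np.sqrt((diff**2).sum() / P.shape[0]))
    return transform, rmsd


def lrmsd(a, b) -> float:
    """Least RMSD: RMSD after optimal rigid-body superposition (Å).

    Symmetric and invariant to rigid motions of either argument.
    """
    _, value = kabsch_superpose(a, b)
    return value


def centralize(
    ensemble: DecoyEnsemble,
    reference_index: int = 0,
    reference: Conformation | None = None,
) -> DeviationDataset:
    """Superpose every member onto the reference and subtract the reference.

    The reference anchoring the feature-space frame is, by convention, the
    first structure of the ensemble; ``reference_index`` overrides that, and
    passing an explicit ``reference`` conformation (for instance the native
    structure, so several targets share one frame) overrides both.  When the
    reference is a member its own deviation row is exactly zero.  The
    *label* anchor is separate: if the ensemble carries a native structure,
    lRMSD labels are (re)computed against it; otherwise existing member
    labels are kept.
    """
    m = len(ensemble)
    if reference is not None:
        ref_member = None
        if reference.n_atoms != ensemble.n_residues:
            raise ShapeError("reference atom count differs from ensemble")
    else:
        if not (-m <= reference_index < m):
            raise IndexError(
                f"reference index {reference_index} out of range for {m} members"
            )
        ref_member = reference_index % m
        reference = ensemble[ref_member]
    ref_coords = reference.coords
    n = reference.n_atoms

    deviations = np.empty((m, 3 * n))
    for i, conf in enumerate(ensemble):
        if i == ref_member:
            deviations[i] = 0.0
            continue
        transform, _ = kabsch_superpose(conf, reference)
        deviations[i] = (transform.apply(conf.coords) - ref_coords).reshape(-1)

    if ensemble.native is not None:
        labels = np.asarray([lrmsd(c, ensemble.native) for c in ensemble])
    else:
        labels = ensemble.labels()
    return DeviationDataset(reference=reference, deviations=deviations, labels=labels)


def reconstruct(deviation: np.ndarray, reference: Conformation) -> Conformation:
    """Recover a structure from its deviation vector: S^ = dS^ + S_reference."""
    deviation = np.asarray(deviation, dtype=float).reshape(-1)
    if deviation.size != 3 * reference.n_atoms:
        raise ShapeError(
            f"deviation length {deviation.size} does not match reference "
            f"dimension {3 * reference.n_atoms}"
        )
    coords = reference.coords + deviation.reshape(-1, 3)
    return Conformation(coords=coords, id="reconstructed")


def split_dataset(
    dataset: DeviationDataset,
    fractions: tuple[float, float, float] = (0.5, 0.1, 0.4),
    seed: int = 0,
) -> DeviationDataset:
    """Randomly split rows into train/validation/test index sets.

    Validation and test receive ``floor(m * fraction)`` rows each; the
    remainder goes to train.  The default 0.5:0.1:0.4 split is the
    convention used throughout the pipeline.  The split is a uniform random
    shuffle, reproducible under ``seed``; indices are stored on the returned
    dataset (the same object, mutated).
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise InvalidSpecError(
            f"fractions must be three positive numbers summing to 1, got {fractions}"
        )
    m = dataset.n_structures
    n_val = int(np.floor(m * fr[1]))
    n_test = int(np.floor(m * fr[2]))
    n_train = m - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise InvalidSpecError(
            f"split of {m} rows at {fractions} leaves an empty part"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    dataset.split = {
        "train": np.sort(perm[:n_train]),
        "validation": np.sort(perm[n_train : n_train + n_val]),
        "test": np.sort(perm[n_train + n_val :]),
    }
    return dataset
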