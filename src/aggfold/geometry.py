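"""Rigid superposition, fluctuation, compactness and periodic-distance primitives.

All coordinates are in nm.  Superposition uses the Kabsch SVD construction,
which minimises the RMSD over proper rotations and translations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import PeptideSequence
from .trajectory import ATOM_NAMES, Conformation, Trajectory, atom_masses, atom_selection_indices

__all__ = [
    "RigidTransform",
    "kabsch_superpose",
    "superpose_coords",
    "rmsd",
    "rmsf_per_residue",
    "radius_of_gyration",
    "min_image_distance",
    "min_image_displacement",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation, ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-10
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ np.asarray(self.rotation).T + self.translation

    def inverse(self) -> "RigidTransform":
        R = np.asarray(self.rotation)
        return RigidTransform(R.T, -(R.T @ np.asarray(self.translation)))


def _kabsch_rotation(mobile_c: np.ndarray, ref_c: np.ndarray) -> np.ndarray:
    """Optimal proper rotation for centred point sets (Kabsch via SVD)."""
    H = mobile_c.T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the transform and the minimal RMSD (nm).  Requires at least 3
    non-collinear points in each set and equal point counts.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point count mismatch: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need an (n>=3, 3) coordinate array")
    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    mob_c = mobile - mob_mean
    ref_c = reference - ref_mean
    # degeneracy: collinear point sets leave a rotation axis undetermined
    if np.linalg.matrix_rank(mob_c, tol=1e-9) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    R = _kabsch_rotation(mob_c, ref_c)
    t = ref_mean - R @ mob_mean
    fitted = mob_c @ R.T + ref_mean
    val = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return RigidTransform(R, t), val


def superpose_coords(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """``mobile`` after optimal superposition onto ``reference``."""
    tf, _ = kabsch_superpose(mobile, reference)
    return tf.apply(mobile)


def rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = True) -> float:
    """RMSD between two conformers, optionally after optimal superposition."""
    if superpose:
        return kabsch_superpose(a, b)[1]
    a = np.asarray(a)
    b = np.asarray(b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsf_per_residue(
    traj: Trajectory,
    chain_id: str,
    selection: Sequence[str] = ("CA",),
    fit_selection: Sequence[str] = ATOM_NAMES,
    reference: str = "first",
) -> np.ndarray:
    """Per-residue RMSF (nm) of the selected atoms for one chain.

    Every frame is first superposed onto the reference (the first frame by
    default, or the time-average structure with ``reference="mean"``) on
    ``fit_selection``; the RMSF of residue *i* is the RMS deviation of its
    selected atoms from their time-average positions.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    fit = traj.chain_coords(chain_id, fit_selection)
    if reference == "mean":
        ref = fit.mean(axis=0)
        # one round of iterative refit onto the running mean
        fitted = np.array([superpose_coords(x, ref) for x in fit])
        ref = fitted.mean(axis=0)
    elif reference == "first":
        ref = fit[0]
    else:
        raise ValueError("reference must be 'first' or 'mean'")

    c = traj.chain_index(chain_id)
    idx = atom_selection_indices(selection)
    sel = traj.coords_nm[:, c][:, :, idx, :]  # (F, R, S, 3)
    out_shape = sel.shape[1:]
    fitted_sel = np.empty_like(sel)
    for f in range(traj.n_frames):
        tf, _ = kabsch_superpose(fit[f], ref)
        fitted_sel[f] = tf.apply(sel[f].reshape(-1, 3)).reshape(out_shape)
    mean_pos = fitted_sel.mean(axis=0)
    sq = np.sum((fitted_sel - mean_pos) ** 2, axis=-1)  # (F, R, S)
    return np.sqrt(sq.mean(axis=(0, 2)))


def radius_of_gyration(
    conf: Conformation | np.ndarray,
    masses: np.ndarray | None = None,
    sequence: PeptideSequence | None = None,
) -> float:
    """Mass-weighted radius of gyration (nm).

    Accepts a :class:`Conformation` (masses derived from its sequence) or a
    raw ``(n, 3)`` coordinate array with optional per-point masses.
    """
    if isinstance(conf, Conformation):
        coords = conf.coords_nm.reshape(-1, 3)
        masses = atom_masses(conf.sequence).reshape(-1)
    else:
        coords = np.asarray(conf, dtype=float).reshape(-1, 3)
        if masses is None:
            if sequence is not None:
                masses = atom_masses(sequence).reshape(-1)
            else:
                masses = np.ones(len(coords))
        masses = np.asarray(masses, dtype=float)
    if len(coords) == 0:
        raise ValueError("radius of gyration of an empty point set")
    w = masses / masses.sum()
    com = w @ coords
    return float(np.sqrt(np.sum(w * np.sum((coords - com) ** 2, axis=1))))


def min_image_displacement(delta: np.ndarray, box_nm: np.ndarray) -> np.ndarray:
    """Displacement vector(s) wrapped to the minimum image of an orthorhombic box."""
    box = np.asarray(box_nm, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edge lengths must be positive")
    return delta - box * np.round(np.asarray(delta, dtype=float) / box)


def min_image_distance(p: np.ndarray, q: np.ndarray, box_nm: np.ndarray) -> float:
    """Distance between two points under the minimum-image convention."""
    d = min_image_displacement(np.asarray(p, dtype=float) - np.asarray(q, dtype=float), box_nm)
    return float(np.linalg.norm(d))
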