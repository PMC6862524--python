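"""Conformational clustering and Cartesian backbone PCA (essential dynamics).

Clustering follows the greedy neighbour-count algorithm popularised by the
GROMOS analysis tools: the structure with the most RMSD-neighbours within
the cutoff becomes a cluster centroid, it and its neighbours are removed,
and the step repeats.  Ties on neighbour count are broken toward the
earlier frame index so the partition is deterministic.  Pairwise RMSDs use
per-pair optimal superposition.

PCA is carried out on Cartesian coordinates of the N/CA/C backbone
selection (60 atoms for a 20-residue chain) after least-square fitting of
every observation to the starting conformation; the covariance is
mass-unweighted and centred on the trajectory mean.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import kabsch_superpose
from .trajectory import BACKBONE_PCA_ATOMS, Trajectory

__all__ = [
    "Cluster",
    "ClusterSet",
    "PcaModel",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "cartesian_pca",
    "eigen_rmsf",
    "project",
]

GROMOS_CUTOFF_NM = 0.3


@dataclass
class Cluster:
    centroid: int
    members: np.ndarray

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """Clusters ordered by size (descending); they partition the frame set."""

    clusters: list[Cluster]
    n_frames: int

    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def labels(self) -> np.ndarray:
        lab = np.full(self.n_frames, -1, dtype=int)
        for k, c in enumerate(self.clusters):
            lab[c.members] = k
        return lab


def _as_obs(traj_or_coords, chain_ids, selection) -> np.ndarray:
    if isinstance(traj_or_coords, Trajectory):
        traj = traj_or_coords
        ids = chain_ids if chain_ids is not None else traj.chain_ids
        if isinstance(ids, str):
            ids = (ids,)
        per_chain = [traj.chain_coords(cid, selection) for cid in ids]
        return np.concatenate(per_chain, axis=0)  # chain-frames stacked
    coords = np.asarray(traj_or_coords, dtype=float)
    if coords.ndim != 3 or coords.shape[-1] != 3:
        raise ValueError("expected coordinates shaped (n_obs, n_atoms, 3)")
    return coords


def pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """Symmetric matrix of per-pair optimally-superposed RMSDs (nm)."""
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, v = kabsch_superpose(coords[i], coords[j])
            out[i, j] = out[j, i] = v
    return out


def gromos_cluster(
    traj_or_coords,
    chain_ids: str | Sequence[str] | None = None,
    selection: Sequence[str] = BACKBONE_PCA_ATOMS,
    cutoff_nm: float = GROMOS_CUTOFF_NM,
) -> ClusterSet:
    """Greedy neighbour-count clustering of conformations.

    Accepts a :class:`Trajectory` (frames of one or more chains become the
    observations) or a raw ``(n_obs, n_atoms, 3)`` stack.
    """
    coords = _as_obs(traj_or_coords, chain_ids, selection)
    n = len(coords)
    if n == 0:
        raise ValueError("empty frame set")
    dist = pairwise_rmsd_matrix(coords)
    neighbour = dist < cutoff_nm
    np.fill_diagonal(neighbour, True)

    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        counts = (neighbour & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        centroid = int(np.argmax(counts))  # argmax takes the earliest on ties
        members = np.where(neighbour[centroid] & remaining)[0]
        clusters.append(Cluster(centroid=centroid, members=members))
        remaining[members] = False
    clusters.sort(key=lambda c: (-c.size, c.centroid))
    return ClusterSet(clusters=clusters, n_frames=n)


@dataclass
class PcaModel:
    """Cartesian PCA of superposed backbone coordinates.

    ``eigenvectors`` columns are orthonormal 3N-dimensional modes sorted by
    descending eigenvalue (nm^2); ``projections`` are the per-observation
    scores (nm) of the fitting data.
    """

    reference: np.ndarray
    mean_flat: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    projections: np.ndarray
    selection: tuple[str, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.reference)

    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Project observations ``(n_obs, n_atoms, 3)`` onto all modes."""
        coords = np.asarray(coords, dtype=float)
        fitted = np.empty_like(coords)
        for i, x in enumerate(coords):
            tf, _ = kabsch_superpose(x, self.reference)
            fitted[i] = tf.apply(x)
        centred = fitted.reshape(len(coords), -1) - self.mean_flat
        return centred @ self.eigenvectors


def cartesian_pca(
    traj_or_coords,
    chain_ids: str | Sequence[str] | None = None,
    selection: Sequence[str] = BACKBONE_PCA_ATOMS,
) -> PcaModel:
    """Backbone PCA after least-square fitting to the starting conformation.

    For a multi-chain trajectory every chain-frame is one observation of
    the monomer structure, all fitted to the same reference (the first
    chain's first frame).
    """
    coords = _as_obs(traj_or_coords, chain_ids, selection)
    if len(coords) < 2:
        raise ValueError("PCA requires at least 2 observations")
    reference = coords[0]
    fitted = np.empty_like(coords)
    for i, x in enumerate(coords):
        tf, _ = kabsch_superpose(x, reference)
        fitted[i] = tf.apply(x)
    flat = fitted.reshape(len(coords), -1)
    mean_flat = flat.mean(axis=0)
    centred = flat - mean_flat
    cov = centred.T @ centred / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    projections = centred @ evecs
    sel = tuple(selection) if not isinstance(traj_or_coords, Trajectory) else tuple(selection)
    return PcaModel(
        reference=reference,
        mean_flat=mean_flat,
        eigenvalues=evals,
        eigenvectors=evecs,
        projections=projections,
        selection=sel,
    )


def eigen_rmsf(model: PcaModel, component: int = 0) -> np.ndarray:
    """Per-atom RMS fluctuation (nm) generated by one eigenmode.

    The mode's displacement amplitude at atom *a* is the norm of its
    3-vector block of the eigenvector, scaled by the mode's RMS score
    ``sqrt(eigenvalue)``.
    """
    if not 0 <= component < len(model.eigenvalues):
        raise IndexError(f"component {component} out of range")
    vec = model.eigenvectors[:, component].reshape(-1, 3)
    return np.sqrt(model.eigenvalues[component]) * np.linalg.norm(vec, axis=1)


def project(
    traj_or_coords,
    model: PcaModel,
    component: int = 0,
    chain_ids: str | Sequence[str] | None = None,
) -> np.ndarray:
    """Per-observation projection (nm) onto one principal component."""
    if not 0 <= component < len(model.eigenvalues):
        raise IndexError(f"component {component} out of range")
    coords = _as_obs(traj_or_coords, chain_ids, model.selection)
    if coords.shape[1] != model.n_atoms:
        raise ValueError(
            f"selection mismatch: {coords.shape[1]} atoms vs model {model.n_atoms}"
        )
    return model.transform(coords)[:, component]
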