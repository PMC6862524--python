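"""Aggregate detection and intermolecular-contact statistics.

Two chains are neighbours when any inter-chain atom pair is closer than a
cutoff (0.5 nm by default, the 5 A neighbour criterion) under the
minimum-image convention; aggregates are the connected components of that
contact graph.  The same machinery provides neighbour attribution at event
times (who was next to a chain when it straightened) and per-residue
intermolecular contact counts grouped by the chain's conformational state.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .secstruct import ConformationState, StateSeries
from .trajectory import Trajectory

__all__ = [
    "CONTACT_CUTOFF_NM",
    "AggregateSeries",
    "chain_contact_graph",
    "aggregate_series",
    "intermolecular_contacts",
    "neighbors_at_time",
    "oligomer_name",
]

#: Chain-neighbour distance cutoff (nm); the 5 A criterion.
CONTACT_CUTOFF_NM = 0.5

_OLIGOMER_NAMES = {
    1: "Monomer", 2: "Dimer", 3: "Trimer", 4: "Tetramer", 5: "Pentamer",
    6: "Hexamer", 7: "Heptamer", 8: "Octamer", 9: "Nonamer", 10: "Decamer",
}


def oligomer_name(size: int) -> str:
    """Conventional oligomer name for an aggregate size (``"27-mer"`` style
    beyond the named ones)."""
    if size < 1:
        raise ValueError("aggregate size must be >= 1")
    return _OLIGOMER_NAMES.get(size, f"{size}-mer")


def _inter_chain_pairs(
    frame_coords: np.ndarray, box_nm: np.ndarray, cutoff_nm: float
) -> np.ndarray:
    """Inter-chain atom pairs within the cutoff under minimum image.

    Returns an array of atom-pair rows ``(ci, ri, cj, rj)`` with ci < cj.
    """
    n_chains, n_res, n_at, _ = frame_coords.shape
    flat = frame_coords.reshape(-1, 3)
    box = np.asarray(box_nm, dtype=float)
    wrapped = np.mod(flat, box)
    # fp rounding in mod can land exactly on the upper box edge
    wrapped[wrapped >= box] = 0.0
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(cutoff_nm, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 4), dtype=int)
    per_chain = n_res * n_at
    ci = pairs[:, 0] // per_chain
    cj = pairs[:, 1] // per_chain
    inter = ci != cj
    pairs = pairs[inter]
    ci, cj = ci[inter], cj[inter]
    ri = (pairs[:, 0] % per_chain) // n_at
    rj = (pairs[:, 1] % per_chain) // n_at
    swap = ci > cj
    ci[swap], cj[swap] = cj[swap], ci[swap].copy()
    ri[swap], rj[swap] = rj[swap], ri[swap].copy()
    return np.column_stack([ci, ri, cj, rj])


def chain_contact_graph(
    frame_coords: np.ndarray,
    box_nm: np.ndarray,
    cutoff_nm: float = CONTACT_CUTOFF_NM,
) -> np.ndarray:
    """Boolean chain adjacency for one frame ``(n_chains, n_res, n_atoms, 3)``.

    Chains are adjacent iff any inter-chain atom pair is within the cutoff
    under the minimum-image convention.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    n_chains = frame_coords.shape[0]
    adj = np.zeros((n_chains, n_chains), dtype=bool)
    rows = _inter_chain_pairs(frame_coords, box_nm, cutoff_nm)
    if len(rows):
        adj[rows[:, 0], rows[:, 2]] = True
        adj[rows[:, 2], rows[:, 0]] = True
    return adj


def _components(adj: np.ndarray) -> np.ndarray:
    n = len(adj)
    graph = coo_matrix(adj.astype(np.int8))
    _, labels = connected_components(graph, directed=False)
    return labels


@dataclass
class AggregateSeries:
    """Per-frame partition of chains into contact components.

    ``labels`` has shape ``(n_frames, n_chains)``: chains sharing a label in
    a frame belong to one aggregate.
    """

    chain_ids: tuple[str, ...]
    times_ns: np.ndarray
    labels: np.ndarray

    @property
    def n_aggregates(self) -> np.ndarray:
        return np.array([len(np.unique(row)) for row in self.labels])

    @property
    def max_size(self) -> np.ndarray:
        return np.array([np.bincount(row).max() for row in self.labels])

    def partition(self, frame: int) -> list[set[str]]:
        row = self.labels[frame]
        return [
            {self.chain_ids[i] for i in np.where(row == lab)[0]}
            for lab in np.unique(row)
        ]

    def aggregate_of(self, frame: int, chain_id: str) -> set[str]:
        c = self.chain_ids.index(chain_id)
        row = self.labels[frame]
        return {self.chain_ids[i] for i in np.where(row == row[c])[0]}

    def to_frame(self) -> pd.DataFrame:
        membership = [
            "|".join(",".join(sorted(part)) for part in self.partition(f))
            for f in range(len(self.times_ns))
        ]
        return pd.DataFrame(
            {
                "time_ns": self.times_ns,
                "n_aggregates": self.n_aggregates,
                "max_size": self.max_size,
                "components": membership,
            }
        )


def aggregate_series(
    traj: Trajectory, cutoff_nm: float = CONTACT_CUTOFF_NM
) -> AggregateSeries:
    """Connected-component aggregates for every frame of a trajectory."""
    labels = np.empty((traj.n_frames, traj.n_chains), dtype=int)
    for f in range(traj.n_frames):
        adj = chain_contact_graph(traj.frame_coords(f), traj.box_nm, cutoff_nm)
        labels[f] = _components(adj)
    return AggregateSeries(traj.chain_ids, traj.times_ns.copy(), labels)


def neighbors_at_time(
    traj: Trajectory,
    chain_id: str,
    time_ns: float,
    cutoff_nm: float = CONTACT_CUTOFF_NM,
) -> set[str]:
    """Chain ids adjacent to ``chain_id`` in the frame nearest ``time_ns``."""
    c = traj.chain_index(chain_id)
    f = traj.nearest_frame(time_ns)
    adj = chain_contact_graph(traj.frame_coords(f), traj.box_nm, cutoff_nm)
    return {traj.chain_ids[j] for j in np.where(adj[c])[0]}


def intermolecular_contacts(
    traj: Trajectory,
    states: StateSeries,
    cutoff_nm: float = CONTACT_CUTOFF_NM,
    deduplicate: bool = False,
) -> pd.DataFrame:
    """Mean intermolecular contacts per frame per residue, grouped by state.

    A contact is an inter-chain atom pair within the cutoff, attributed to
    both residues involved; a residue pair touching through *k* atom pairs
    contributes *k* (or 1 with ``deduplicate=True``).  Means are taken over
    all chain-frames whose chain carries the given state in that frame.

    Returns a DataFrame with columns ``residue`` (1-based), ``state`` and
    ``mean_contacts_per_frame``.
    """
    if states.codes.shape != (traj.n_frames, traj.n_chains):
        raise ValueError("state series is not aligned to the trajectory")
    n_res = len(traj.sequence)
    state_list = list(ConformationState)
    sums = {s: np.zeros(n_res) for s in state_list}
    n_obs = {s: 0 for s in state_list}

    for f in range(traj.n_frames):
        rows = _inter_chain_pairs(traj.frame_coords(f), traj.box_nm, cutoff_nm)
        if deduplicate and len(rows):
            rows = np.unique(rows, axis=0)
        counts = np.zeros((traj.n_chains, n_res))
        for ci, ri, cj, rj in rows:
            counts[ci, ri] += 1
            counts[cj, rj] += 1
        for c, cid in enumerate(traj.chain_ids):
            st = states.label(f, cid)
            sums[st] += counts[c]
            n_obs[st] += 1

    recs = []
    for st in state_list:
        mean = sums[st] / n_obs[st] if n_obs[st] else np.zeros(n_res)
        for r in range(n_res):
            recs.append(
                {
                    "residue": r + 1,
                    "state": st.value,
                    "mean_contacts_per_frame": mean[r],
                }
            )
    return pd.DataFrame(recs)
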