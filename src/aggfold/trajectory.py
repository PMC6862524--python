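"""Trajectory containers and multi-model PDB input/output.

A reduced per-residue representation is used throughout: the four backbone
atoms (N, CA, C, O) plus a single side-chain pseudo-atom placed at the CB
position.  Coordinates are stored in nm internally; PDB files are written
and read in Angstrom as the format requires.

Trajectories are multi-model PDB files: one MODEL per frame, chains
distinguished by chain identifier, the cubic box on a CRYST1 record and the
per-frame time stamps on ``REMARK 250 FRAME`` header lines.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import ONE_LETTER, SIDECHAIN_MASS, THREE_LETTER, PeptideSequence, parse_sequence

__all__ = [
    "ATOM_NAMES",
    "BACKBONE_PCA_ATOMS",
    "Conformation",
    "Trajectory",
    "TrajectoryFormatError",
    "write_trajectory",
    "read_trajectory",
    "atom_masses",
]

#: Atom layout per residue: backbone N, CA, C, O and the CB side-chain
#: pseudo-atom (side-chain centroid).
ATOM_NAMES: tuple[str, ...] = ("N", "CA", "C", "O", "CB")
N_ATOMS_PER_RESIDUE = len(ATOM_NAMES)

#: Selection used for backbone PCA and clustering (no carbonyl O, no CB).
BACKBONE_PCA_ATOMS: tuple[str, ...] = ("N", "CA", "C")

_ATOM_INDEX = {name: i for i, name in enumerate(ATOM_NAMES)}

# Atomic masses (Da) of the explicit backbone atoms; the CB pseudo-atom
# carries the whole side-chain mass of its residue.
_BACKBONE_MASS = {"N": 15.01, "CA": 13.02, "C": 12.01, "O": 16.00}


class TrajectoryFormatError(ValueError):
    """Raised for malformed multi-model PDB trajectory files."""


def atom_selection_indices(names: Sequence[str]) -> np.ndarray:
    """Indices into the per-residue atom axis for the named atoms."""
    try:
        return np.array([_ATOM_INDEX[n] for n in names], dtype=int)
    except KeyError as exc:  # pragma: no cover - defensive
        raise KeyError(f"unknown atom name {exc}; layout is {ATOM_NAMES}") from exc


def atom_masses(seq: PeptideSequence) -> np.ndarray:
    """Per-atom masses, shape ``(n_residues, 5)``; CB holds the side chain."""
    out = np.empty((len(seq), N_ATOMS_PER_RESIDUE))
    for j, name in enumerate(ATOM_NAMES):
        if name == "CB":
            out[:, j] = [SIDECHAIN_MASS[aa] for aa in seq]
        else:
            out[:, j] = _BACKBONE_MASS[name]
    return out


@dataclass
class Conformation:
    """A single chain's reduced-representation structure.

    ``coords_nm`` has shape ``(n_residues, 5, 3)`` following
    :data:`ATOM_NAMES`.
    """

    sequence: PeptideSequence
    coords_nm: np.ndarray
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coords_nm = np.asarray(self.coords_nm, dtype=float)
        expected = (len(self.sequence), N_ATOMS_PER_RESIDUE, 3)
        if self.coords_nm.shape != expected:
            raise ValueError(
                f"coordinate array has shape {self.coords_nm.shape}, expected {expected}"
            )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def atoms(self, *names: str) -> np.ndarray:
        """Coordinates of the named atoms, shape ``(n_residues, len(names), 3)``.

        With a single name the atom axis is squeezed away.
        """
        idx = atom_selection_indices(names)
        sel = self.coords_nm[:, idx, :]
        return sel[:, 0, :] if len(names) == 1 else sel

    def flat(self, names: Sequence[str] = ATOM_NAMES) -> np.ndarray:
        """Selected coordinates flattened to ``(n_residues*len(names), 3)``."""
        idx = atom_selection_indices(names)
        return self.coords_nm[:, idx, :].reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        coords = self.coords_nm @ rotation.T + translation
        return Conformation(self.sequence, coords, self.chain_id)


@dataclass
class Trajectory:
    """A multi-chain trajectory on the reduced representation.

    ``coords_nm`` has shape ``(n_frames, n_chains, n_residues, 5, 3)``;
    ``times_ns`` is strictly increasing; ``box_nm`` is the orthorhombic box
    edge length triple, constant over the trajectory.
    """

    sequence: PeptideSequence
    chain_ids: tuple[str, ...]
    times_ns: np.ndarray
    box_nm: np.ndarray
    coords_nm: np.ndarray

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.box_nm = np.asarray(self.box_nm, dtype=float)
        self.coords_nm = np.asarray(self.coords_nm, dtype=float)
        self.chain_ids = tuple(self.chain_ids)
        f, c, r, a, _ = self.coords_nm.shape
        if c != len(self.chain_ids):
            raise ValueError("chain_ids length does not match coordinate array")
        if r != len(self.sequence) or a != N_ATOMS_PER_RESIDUE:
            raise ValueError("coordinate array does not match sequence/atom layout")
        if f != len(self.times_ns):
            raise ValueError("times_ns length does not match frame count")
        if f > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise ValueError("frame time stamps must be strictly increasing")
        if np.any(self.box_nm <= 0):
            raise ValueError("box edge lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords_nm.shape[0]

    @property
    def n_chains(self) -> int:
        return self.coords_nm.shape[1]

    def chain_index(self, chain_id: str) -> int:
        try:
            return self.chain_ids.index(chain_id)
        except ValueError:
            raise KeyError(f"unknown chain id {chain_id!r}") from None

    def conformation(self, frame: int, chain_id: str) -> Conformation:
        c = self.chain_index(chain_id)
        return Conformation(self.sequence, self.coords_nm[frame, c], chain_id)

    def frame_coords(self, frame: int) -> np.ndarray:
        """All chains of one frame, shape ``(n_chains, n_residues, 5, 3)``."""
        return self.coords_nm[frame]

    def chain_coords(self, chain_id: str, names: Sequence[str] = ATOM_NAMES) -> np.ndarray:
        """One chain across frames, shape ``(n_frames, n_res*len(names), 3)``."""
        c = self.chain_index(chain_id)
        idx = atom_selection_indices(names)
        sel = self.coords_nm[:, c][:, :, idx, :]
        return sel.reshape(self.n_frames, -1, 3)

    def nearest_frame(self, time_ns: float) -> int:
        return int(np.argmin(np.abs(self.times_ns - time_ns)))


_NM_PER_ANGSTROM = 0.1


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file.

    One MODEL per frame; CRYST1 carries the box; a ``REMARK 250 FRAME``
    header line per frame carries the time stamp.  Output is deterministic
    (no wall-clock time stamps).
    """
    path = Path(path)
    seq = traj.sequence
    n_res = len(seq)
    lines: list[str] = []
    lines.append("REMARK 250 AGGFOLD REDUCED-REPRESENTATION TRAJECTORY")
    for i, t in enumerate(traj.times_ns):
        lines.append(f"REMARK 250 FRAME {i:6d} TIME_NS {t:.6f}")
    bx, by, bz = traj.box_nm / _NM_PER_ANGSTROM
    lines.append(
        f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
    )
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        for c, chain_id in enumerate(traj.chain_ids):
            for r in range(n_res):
                resname = THREE_LETTER[seq[r]]
                for a, name in enumerate(ATOM_NAMES):
                    x, y, z = traj.coords_nm[f, c, r, a] / _NM_PER_ANGSTROM
                    lines.append(
                        f"ATOM  {serial % 100000:5d}  {name:<3s}{resname:>4s} "
                        f"{chain_id:1s}{r + 1:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {elements[name]:>2s}"
                    )
                    serial += 1
            lines.append(f"TER   {serial % 100000:5d}      {THREE_LETTER[seq[-1]]:>3s} {chain_id:1s}{n_res:4d}")
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a multi-model PDB trajectory written by :func:`write_trajectory`.

    Raises :class:`TrajectoryFormatError` on empty files, malformed MODEL
    nesting or inconsistent atom counts between models.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise TrajectoryFormatError(f"{path} is empty")

    times: list[float] = []
    box = None
    models: list[list[str]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "REMARK" and "TIME_NS" in line:
            times.append(float(line.rsplit("TIME_NS", 1)[1]))
        elif rec == "CRYST1":
            box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
            box *= _NM_PER_ANGSTROM
        elif rec == "MODEL":
            if current is not None:
                raise TrajectoryFormatError("nested MODEL record without ENDMDL")
            current = []
        elif rec == "ENDMDL":
            if current is None:
                raise TrajectoryFormatError("ENDMDL without matching MODEL")
            models.append(current)
            current = None
        elif rec == "ATOM":
            if current is None:
                # single-model file without MODEL records
                current = []
                models.append(current)
            current.append(line)
    if current is not None and current not in models:
        raise TrajectoryFormatError("unterminated MODEL record")
    if not models or not models[0]:
        raise TrajectoryFormatError(f"{path} contains no ATOM records")

    n_atoms = len(models[0])
    for i, m in enumerate(models):
        if len(m) != n_atoms:
            raise TrajectoryFormatError(
                f"model {i + 1} has {len(m)} atoms, expected {n_atoms}"
            )

    # chain / residue layout from the first model
    chain_ids: list[str] = []
    seq_codes: list[str] = []
    first_chain: str | None = None
    for line in models[0]:
        chain = line[21]
        name = line[12:16].strip()
        if chain not in chain_ids:
            chain_ids.append(chain)
            if first_chain is None:
                first_chain = chain
        if chain == first_chain and name == "CA":
            resname = line[17:20].strip()
            if resname not in ONE_LETTER:
                raise TrajectoryFormatError(f"unknown residue name {resname!r}")
            seq_codes.append(ONE_LETTER[resname])
    if not seq_codes:
        raise TrajectoryFormatError("no CA atoms found in first chain")
    seq = parse_sequence("".join(seq_codes))

    n_res = len(seq)
    n_chains = len(chain_ids)
    if n_atoms != n_chains * n_res * N_ATOMS_PER_RESIDUE:
        raise TrajectoryFormatError(
            f"atom count {n_atoms} does not match {n_chains} chains x {n_res} "
            f"residues x {N_ATOMS_PER_RESIDUE} atoms"
        )

    coords = np.empty((len(models), n_chains, n_res, N_ATOMS_PER_RESIDUE, 3))
    for f, m in enumerate(models):
        arr = np.array(
            [[float(l[30:38]), float(l[38:46]), float(l[46:54])] for l in m]
        )
        coords[f] = arr.reshape(n_chains, n_res, N_ATOMS_PER_RESIDUE, 3)
    coords *= _NM_PER_ANGSTROM

    if len(times) != len(models):
        # fall back to unit spacing if time remarks are absent
        times = list(range(len(models)))
    if box is None:
        raise TrajectoryFormatError("missing CRYST1 box record")

    return Trajectory(
        sequence=seq,
        chain_ids=tuple(chain_ids),
        times_ns=np.array(times, dtype=float),
        box_nm=box,
        coords_nm=coords,
    )
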