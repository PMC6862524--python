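"""Helix assignment and conformational-state classification.

A residue is called helical when its backbone dihedrals fall in the
alpha-helical window (phi in [-100, -30] deg, psi in [-80, -5] deg) and it
belongs to a run of at least four consecutive such residues; chain termini,
whose phi or psi is undefined, are never helical.  This dihedral-window
criterion replaces hydrogen-bond-based assigners: for the state question
asked here — "is the Val5-Lys17 span continuously helical?" — the dihedral
test is sufficient and has no external dependencies.  A different assigner
can be plugged in by supplying a custom helix mask to the state logic.

States:

* ``single-helix`` — the whole classification span (residues 5-17 by
  default, the experimentally well-structured core) is helical;
* ``helix-loop-helix`` — the span holds two or more helical segments (each
  at least 3 residues within the span) separated by a break;
* ``disordered`` — anything else.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .trajectory import Conformation, Trajectory

__all__ = [
    "ConformationState",
    "StateSeries",
    "PHI_WINDOW_DEG",
    "PSI_WINDOW_DEG",
    "MIN_HELIX_RUN",
    "MIN_SEGMENT_RUN",
    "CLASSIFICATION_SPAN",
    "backbone_dihedrals",
    "assign_helix",
    "helix_mask",
    "classify_state",
    "state_series",
    "occupancy_windows",
]

PHI_WINDOW_DEG = (-100.0, -30.0)
PSI_WINDOW_DEG = (-80.0, -5.0)
#: Minimum consecutive helical residues for the helix call.
MIN_HELIX_RUN = 4
#: Minimum helical-segment length (within the span) for the two-segment test.
MIN_SEGMENT_RUN = 3
#: 1-based residue span used for state classification (Val5-Lys17 core).
CLASSIFICATION_SPAN = (5, 17)


class ConformationState(str, Enum):
    SINGLE_HELIX = "single-helix"
    HELIX_LOOP_HELIX = "helix-loop-helix"
    DISORDERED = "disordered"


_STATE_CODES = {
    ConformationState.DISORDERED: 0,
    ConformationState.HELIX_LOOP_HELIX: 1,
    ConformationState.SINGLE_HELIX: 2,
}
_CODE_STATES = {v: k for k, v in _STATE_CODES.items()}


def _dihedral_array(p0, p1, p2, p3) -> np.ndarray:
    """Torsion angles in degrees for stacked point quadruples (..., 3)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def backbone_dihedrals(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Phi and psi (degrees) for coordinates shaped ``(..., n_res, 5, 3)``.

    Output arrays have shape ``(..., n_res)`` with NaN where the dihedral is
    undefined (phi of the first residue, psi of the last).
    """
    coords = np.asarray(coords, dtype=float)
    n_res = coords.shape[-3]
    lead = coords.shape[:-3]
    phi = np.full(lead + (n_res,), np.nan)
    psi = np.full(lead + (n_res,), np.nan)
    N = coords[..., 0, :]
    CA = coords[..., 1, :]
    C = coords[..., 2, :]
    phi[..., 1:] = _dihedral_array(
        C[..., :-1, :], N[..., 1:, :], CA[..., 1:, :], C[..., 1:, :]
    )
    psi[..., :-1] = _dihedral_array(
        N[..., :-1, :], CA[..., :-1, :], C[..., :-1, :], N[..., 1:, :]
    )
    return phi, psi


def _run_filtered(raw: np.ndarray, min_run: int = MIN_HELIX_RUN) -> np.ndarray:
    """Keep only True positions that belong to a run of >= min_run along the
    last axis."""
    n = raw.shape[-1]
    if n < min_run:
        return np.zeros_like(raw)
    windows = np.lib.stride_tricks.sliding_window_view(raw, min_run, axis=-1)
    full = windows.all(axis=-1)  # (..., n - min_run + 1)
    out = np.zeros_like(raw)
    for start in range(full.shape[-1]):
        sl = out[..., start : start + min_run]
        sl |= full[..., start][..., None]
    return out


def helix_mask(coords: np.ndarray) -> np.ndarray:
    """Per-residue helicity for coordinates shaped ``(..., n_res, 5, 3)``."""
    phi, psi = backbone_dihedrals(coords)
    with np.errstate(invalid="ignore"):
        raw = (
            (phi >= PHI_WINDOW_DEG[0])
            & (phi <= PHI_WINDOW_DEG[1])
            & (psi >= PSI_WINDOW_DEG[0])
            & (psi <= PSI_WINDOW_DEG[1])
        )
    return _run_filtered(raw, MIN_HELIX_RUN)


def assign_helix(conf: Conformation) -> np.ndarray:
    """Boolean helix assignment per residue for a single conformation."""
    if not np.all(np.isfinite(conf.coords_nm[:, :3])):
        raise ValueError("missing backbone atoms: non-finite coordinates")
    return helix_mask(conf.coords_nm)


def _count_segments(span_mask: np.ndarray, min_len: int = MIN_SEGMENT_RUN) -> np.ndarray:
    """Number of helical segments of >= min_len within the span (last axis)."""
    padded = np.concatenate(
        [np.zeros(span_mask.shape[:-1] + (1,), dtype=bool), span_mask], axis=-1
    )
    starts = span_mask & ~padded[..., :-1]
    n = span_mask.shape[-1]
    long_enough = np.zeros_like(span_mask)
    for i in range(n):
        end = i + min_len
        if end <= n:
            long_enough[..., i] = span_mask[..., i:end].all(axis=-1)
    return (starts & long_enough).sum(axis=-1)


def _states_from_mask(
    mask: np.ndarray, span: tuple[int, int] = CLASSIFICATION_SPAN
) -> np.ndarray:
    lo, hi = span
    if mask.shape[-1] < hi:
        raise ValueError(
            f"chain has {mask.shape[-1]} residues; classification span needs {hi}"
        )
    sub = mask[..., lo - 1 : hi]
    single = sub.all(axis=-1)
    n_seg = _count_segments(sub, MIN_SEGMENT_RUN)
    codes = np.zeros(mask.shape[:-1], dtype=np.int8)
    codes[n_seg >= 2] = _STATE_CODES[ConformationState.HELIX_LOOP_HELIX]
    codes[single] = _STATE_CODES[ConformationState.SINGLE_HELIX]
    return codes


def classify_state(
    conf: Conformation, span: tuple[int, int] = CLASSIFICATION_SPAN
) -> ConformationState:
    """Classify one conformation as single-helix / helix-loop-helix / disordered."""
    mask = assign_helix(conf)
    code = _states_from_mask(mask[None, :], span)[0]
    return _CODE_STATES[int(code)]


@dataclass
class StateSeries:
    """Per-chain, per-frame conformational labels.

    ``codes`` has shape ``(n_frames, n_chains)`` with 0 = disordered,
    1 = helix-loop-helix, 2 = single-helix.
    """

    chain_ids: tuple[str, ...]
    times_ns: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != (len(self.times_ns), len(self.chain_ids)):
            raise ValueError("codes shape must be (n_frames, n_chains)")

    def label(self, frame: int, chain_id: str) -> ConformationState:
        c = self.chain_ids.index(chain_id)
        return _CODE_STATES[int(self.codes[frame, c])]

    def chain_codes(self, chain_id: str) -> np.ndarray:
        return self.codes[:, self.chain_ids.index(chain_id)]

    def is_state(self, state: ConformationState) -> np.ndarray:
        return self.codes == _STATE_CODES[state]

    def to_frame(self) -> pd.DataFrame:
        recs = {
            cid: [str(_CODE_STATES[int(c)].value) for c in self.codes[:, i]]
            for i, cid in enumerate(self.chain_ids)
        }
        out = pd.DataFrame(recs)
        out.insert(0, "time_ns", self.times_ns)
        return out


def state_series(
    traj: Trajectory, span: tuple[int, int] = CLASSIFICATION_SPAN
) -> StateSeries:
    """Classify every chain in every frame of a trajectory."""
    mask = helix_mask(traj.coords_nm)  # (F, C, R)
    codes = _states_from_mask(mask, span)
    return StateSeries(traj.chain_ids, traj.times_ns, codes)


def occupancy_windows(
    series: StateSeries,
    state: ConformationState = ConformationState.SINGLE_HELIX,
    window_ns: float = 10.0,
    chain_id: str | None = None,
) -> pd.DataFrame:
    """Windowed occupancy of a state.

    The series is cut into consecutive ``[k*w, (k+1)*w)`` windows; each row
    reports the fraction of frames (pooled over chains unless ``chain_id``
    is given) carrying the state, plus that window's frame count — the
    final window may be partial.
    """
    if series.codes.size == 0:
        raise ValueError("empty state series")
    if window_ns <= 0:
        raise ValueError("window length must be positive")
    flags = series.is_state(state)
    if chain_id is not None:
        flags = flags[:, [series.chain_ids.index(chain_id)]]
    t = series.times_ns
    bins = np.floor(t / window_ns).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        rows.append(
            {
                "window_start_ns": b * window_ns,
                "window_end_ns": (b + 1) * window_ns,
                "n_frames": int(sel.sum()),
                "occupancy": float(flags[sel].mean()),
            }
        )
    return pd.DataFrame(rows)
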