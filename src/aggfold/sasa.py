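"""Solvent-accessible surface area by the Shrake-Rupley method.

Each atom is inflated by the probe radius and covered with a deterministic
golden-spiral quadrature; the exposed fraction of quadrature points gives
the atom's accessible area.  Areas are decomposed by the physicochemical
class (hydrophobic / polar / charged) of the residue each atom belongs to,
which is the decomposition that makes the hydrophobic driving force of
peptide self-association visible: on aggregation the hydrophobic class
total collapses while the charged (lysine) total stays at the isolated-
monomer level.

The reduced representation carries one side-chain pseudo-atom (CB) per
residue, so atomic radii are a published van-der-Waals set for the backbone
plus a class-dependent pseudo-atom radius (see ``CLASS_CB_RADII_NM``).
Absolute areas therefore differ from full-atom values; class fractions and
time-series shapes are the meaningful output.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import PeptideSequence, ResidueClassScheme, default_class_scheme
from .trajectory import ATOM_NAMES, Conformation, Trajectory

__all__ = [
    "PROBE_RADIUS_NM",
    "DEFAULT_N_POINTS",
    "BACKBONE_RADII_NM",
    "CLASS_CB_RADII_NM",
    "GLY_CB_RADIUS_NM",
    "SasaResult",
    "golden_spiral_points",
    "shrake_rupley",
    "atom_radii",
    "conformation_sasa",
    "frame_sasa",
    "sasa_by_class",
    "polar_hydrophobic_ratio",
]

#: Water-probe radius (nm), the conventional 1.4 A.
PROBE_RADIUS_NM = 0.14
#: Default quadrature points per atom.
DEFAULT_N_POINTS = 960

#: Van-der-Waals radii (nm) of the explicit backbone atoms.
BACKBONE_RADII_NM: dict[str, float] = {"N": 0.155, "CA": 0.170, "C": 0.170, "O": 0.152}
#: Side-chain pseudo-atom radius (nm) by residue class.
CLASS_CB_RADII_NM: dict[str, float] = {
    "hydrophobic": 0.20,
    "polar": 0.19,
    "charged": 0.20,
}
#: Glycine's "side chain" is a single hydrogen.
GLY_CB_RADIUS_NM = 0.11


@dataclass
class SasaResult:
    """Class-decomposed SASA of one frame (areas in nm^2)."""

    per_atom_nm2: np.ndarray
    per_residue_nm2: np.ndarray
    class_totals_nm2: dict[str, float]
    total_nm2: float


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform points on the unit sphere (golden-spiral layout)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley(
    coords_nm: np.ndarray,
    radii_nm: np.ndarray,
    probe_radius_nm: float = PROBE_RADIUS_NM,
    n_points: int = DEFAULT_N_POINTS,
    orientation: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom accessible area (nm^2) for a set of spheres.

    ``orientation`` optionally rotates the quadrature sphere (3x3 rotation);
    passing the same rotation that was applied to the coordinates makes the
    result exactly invariant under that rigid transform.
    """
    coords = np.asarray(coords_nm, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii_nm, dtype=float).reshape(-1)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    if len(radii) != n:
        raise ValueError("radii and coordinates disagree in length")
    if probe_radius_nm <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 16:
        raise ValueError("need at least 16 quadrature points")
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")

    expanded = radii + probe_radius_nm
    tree = cKDTree(coords)
    close = tree.query_pairs(1e-6, output_type="ndarray")
    if len(close):
        i, j = close[0]
        raise ValueError(f"coincident atoms {i} and {j} (distance < 1e-6 nm)")

    sphere = golden_spiral_points(n_points)
    if orientation is not None:
        sphere = sphere @ np.asarray(orientation, dtype=float).T

    max_reach = 2.0 * expanded.max()
    neighbours = tree.query_ball_point(coords, max_reach)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * sphere
        nbrs = [j for j in neighbours[i] if j != i]
        if nbrs:
            nbr_idx = np.array(nbrs)
            d2 = np.sum(
                (pts[:, None, :] - coords[nbr_idx][None, :, :]) ** 2, axis=-1
            )
            buried = (d2 < expanded[nbr_idx][None, :] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return areas


def atom_radii(
    seq: PeptideSequence, scheme: ResidueClassScheme | None = None
) -> np.ndarray:
    """Per-atom radii (nm) for one chain, shape ``(n_residues, 5)``."""
    if scheme is None:
        scheme = default_class_scheme()
    out = np.empty((len(seq), len(ATOM_NAMES)))
    for j, name in enumerate(ATOM_NAMES):
        if name == "CB":
            out[:, j] = [
                GLY_CB_RADIUS_NM if aa == "G" else CLASS_CB_RADII_NM[scheme[aa]]
                for aa in seq
            ]
        else:
            out[:, j] = BACKBONE_RADII_NM[name]
    return out


def _decompose(
    areas: np.ndarray,
    seq: PeptideSequence,
    scheme: ResidueClassScheme,
    n_chains: int,
) -> SasaResult:
    n_res = len(seq)
    per_res = areas.reshape(n_chains, n_res, len(ATOM_NAMES)).sum(axis=2)
    classes = scheme.classify(seq)
    totals = {cls: 0.0 for cls in ResidueClassScheme.CLASSES}
    for r, cls in enumerate(classes):
        totals[cls] += float(per_res[:, r].sum())
    per_res_out = per_res[0] if n_chains == 1 else per_res
    return SasaResult(
        per_atom_nm2=areas,
        per_residue_nm2=per_res_out,
        class_totals_nm2=totals,
        total_nm2=float(areas.sum()),
    )


def conformation_sasa(
    conf: Conformation,
    scheme: ResidueClassScheme | None = None,
    probe_radius_nm: float = PROBE_RADIUS_NM,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Class-decomposed SASA of a single chain."""
    if scheme is None:
        scheme = default_class_scheme()
    radii = atom_radii(conf.sequence, scheme).reshape(-1)
    areas = shrake_rupley(conf.coords_nm, radii, probe_radius_nm, n_points)
    return _decompose(areas, conf.sequence, scheme, 1)


def frame_sasa(
    traj: Trajectory,
    frame: int,
    scheme: ResidueClassScheme | None = None,
    probe_radius_nm: float = PROBE_RADIUS_NM,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Class-decomposed SASA of one frame, all chains pooled."""
    if scheme is None:
        scheme = default_class_scheme()
    radii = np.tile(atom_radii(traj.sequence, scheme).reshape(-1), traj.n_chains)
    coords = traj.frame_coords(frame).reshape(-1, 3)
    areas = shrake_rupley(coords, radii, probe_radius_nm, n_points)
    return _decompose(areas, traj.sequence, scheme, traj.n_chains)


def sasa_by_class(
    traj: Trajectory,
    scheme: ResidueClassScheme | None = None,
    probe_radius_nm: float = PROBE_RADIUS_NM,
    n_points: int = DEFAULT_N_POINTS,
    frames: np.ndarray | list[int] | None = None,
) -> pd.DataFrame:
    """Per-class SASA time series over (a subset of) frames.

    Returns a DataFrame with columns ``time_ns``, one column per class
    (``hydrophobic_nm2`` etc.) and ``total_nm2``.
    """
    if scheme is None:
        scheme = default_class_scheme()
    frame_idx = np.arange(traj.n_frames) if frames is None else np.asarray(frames)
    rows = []
    for f in frame_idx:
        res = frame_sasa(traj, int(f), scheme, probe_radius_nm, n_points)
        row = {"time_ns": traj.times_ns[int(f)]}
        for cls, val in res.class_totals_nm2.items():
            row[f"{cls}_nm2"] = val
        row["total_nm2"] = res.total_nm2
        rows.append(row)
    return pd.DataFrame(rows)


def polar_hydrophobic_ratio(series: pd.DataFrame) -> np.ndarray:
    """Polar-to-hydrophobic SASA ratio per frame.

    Frames with zero hydrophobic area are flagged with NaN rather than
    raising, so a long series survives a single degenerate frame.
    """
    hyd = series["hydrophobic_nm2"].to_numpy(dtype=float)
    pol = series["polar_nm2"].to_numpy(dtype=float)
    out = np.full(len(hyd), np.nan)
    ok = hyd > 0
    out[ok] = pol[ok] / hyd[ok]
    return out
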