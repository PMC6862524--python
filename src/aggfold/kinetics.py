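"""Folding kinetics: stable transitions, the folded count N_h(t), and the
sigmoid saturation fit.

A chain counts as transitioned when it first enters the single-helix state
and then stays there: the single-helix occupancy over the following
persistence window (50 ns by default) must be at least 0.8.  The number of
transitioned chains N_h(t) is a right-continuous step function; its
saturation is summarised by a three-parameter logistic curve

    N_h(t) = h_max / (1 + exp(-k (t - t_half))),   k > 0,

where ``h_max`` is the asymptotic number of straightened monomers,
``t_half`` the half-saturation time and ``k`` the rate (shape) parameter.
The equivalent decreasing-exponent form uses lambda = -k; both are
reported.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .secstruct import ConformationState, StateSeries
from .trajectory import Trajectory

__all__ = [
    "PERSISTENCE_NS",
    "PERSISTENCE_OCCUPANCY",
    "TransitionRecord",
    "SigmoidParams",
    "detect_transitions",
    "folded_count",
    "sigmoid",
    "fit_sigmoid",
    "transitions_table",
]

#: Length of the stability window after a candidate transition.
PERSISTENCE_NS = 50.0
#: Minimum single-helix occupancy over the persistence window.
PERSISTENCE_OCCUPANCY = 0.8


@dataclass
class TransitionRecord:
    """First stable helix-loop-helix -> single-helix transition of a chain."""

    chain_id: str
    time_ns: float
    neighbours: tuple[str, ...] = ()
    aggregate_size: int = 1


@dataclass
class SigmoidParams:
    """Parameters of the logistic saturation curve (increasing convention)."""

    h_max: float
    t_half_ns: float
    k_per_ns: float

    @property
    def lam_per_ns(self) -> float:
        """Shape parameter of the decreasing-exponent form (= -k)."""
        return -self.k_per_ns

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return sigmoid(np.asarray(t, dtype=float), self.h_max, self.t_half_ns, self.k_per_ns)


def detect_transitions(
    states: StateSeries,
    persistence_ns: float = PERSISTENCE_NS,
    min_occupancy: float = PERSISTENCE_OCCUPANCY,
    traj: Trajectory | None = None,
    cutoff_nm: float | None = None,
) -> list[TransitionRecord]:
    """First stable single-helix entry per chain; chains that never satisfy
    the persistence criterion yield no record.

    A candidate is a frame where a chain enters single-helix; it is accepted
    if the chain's single-helix occupancy over ``[t, t + persistence_ns]``
    (clipped to the series end) is at least ``min_occupancy``.  If ``traj``
    is given, each record is annotated with the neighbouring chain ids and
    containing-aggregate size at the transition frame.
    """
    if states.codes.size == 0:
        raise ValueError("empty state series")
    t = states.times_ns
    if len(t) > 1 and persistence_ns < np.diff(t).min():
        raise ValueError("persistence window shorter than the frame interval")
    records: list[TransitionRecord] = []
    flags = states.is_state(ConformationState.SINGLE_HELIX)
    for c, cid in enumerate(states.chain_ids):
        sh = flags[:, c]
        entries = np.where(sh & ~np.concatenate([[False], sh[:-1]]))[0]
        hit = None
        for e in entries:
            in_window = (t >= t[e]) & (t <= t[e] + persistence_ns)
            if sh[in_window].mean() >= min_occupancy:
                hit = e
                break
        if hit is None:
            continue
        rec = TransitionRecord(chain_id=cid, time_ns=float(t[hit]))
        if traj is not None:
            from .aggregation import (
                CONTACT_CUTOFF_NM,
                _components,
                chain_contact_graph,
                neighbors_at_time,
            )

            cut = CONTACT_CUTOFF_NM if cutoff_nm is None else cutoff_nm
            nbrs = neighbors_at_time(traj, cid, rec.time_ns, cut)
            adj = chain_contact_graph(
                traj.frame_coords(traj.nearest_frame(rec.time_ns)), traj.box_nm, cut
            )
            labels = _components(adj)
            size = int((labels == labels[traj.chain_index(cid)]).sum())
            rec = TransitionRecord(
                chain_id=cid,
                time_ns=rec.time_ns,
                neighbours=tuple(sorted(nbrs)),
                aggregate_size=size,
            )
        records.append(rec)
    return records


def folded_count(
    records: list[TransitionRecord], times_ns: np.ndarray
) -> np.ndarray:
    """Step function N_h(t): number of chains transitioned by each time.

    Right-continuous: a transition at t counts at t.
    """
    times = np.asarray(times_ns, dtype=float)
    if not records:
        return np.zeros(len(times), dtype=int)
    trans = np.sort([r.time_ns for r in records])
    return np.searchsorted(trans, times, side="right").astype(int)


def sigmoid(t: np.ndarray, h_max: float, t_half: float, k: float) -> np.ndarray:
    # clip the exponent to dodge overflow at extreme arguments
    z = np.clip(-k * (t - t_half), -500.0, 500.0)
    return h_max / (1.0 + np.exp(z))


def fit_sigmoid(
    times_ns: np.ndarray,
    counts: np.ndarray,
    require_monotone: bool = True,
) -> tuple[SigmoidParams, dict]:
    """Least-squares logistic fit of a folded-count series.

    Initialisation: h_max from the terminal count, t_half from the time of
    half-terminal count, k from the 10-90% rise span; several restarts are
    attempted before giving up.  Returns the parameters plus diagnostics
    (residual sum of squares, number of points).

    ``require_monotone`` enforces the non-decreasing character of a true
    folded count; pass ``False`` when fitting noisy per-frame observations
    that fluctuate around the underlying curve.
    """
    t = np.asarray(times_ns, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(t) != len(y):
        raise ValueError("times and counts differ in length")
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct time points")
    if require_monotone and np.any(np.diff(y[np.argsort(t)]) < 0):
        raise ValueError("folded-count series must be non-decreasing")
    terminal = y[np.argmax(t)]
    if terminal <= 0 or np.ptp(y) == 0:
        raise ValueError("degenerate flat series cannot constrain the fit")

    def crossing(level: float) -> float:
        above = np.where(y >= level)[0]
        return float(t[above[0]]) if len(above) else float(t[-1])

    t10, t50, t90 = (crossing(f * terminal) for f in (0.1, 0.5, 0.9))
    k0 = 4.0 / max(t90 - t10, (t.max() - t.min()) / 100.0)
    span = t.max() - t.min()
    starts = [
        (terminal, t50, k0),
        (terminal, t50, 4.0 / max(span, 1e-9)),
        (1.2 * terminal, 0.5 * (t.min() + t.max()), 10.0 / max(span, 1e-9)),
    ]
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                sigmoid,
                t,
                y,
                p0=p0,
                bounds=([1e-9, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((sigmoid(t, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError("sigmoid fit did not converge from any start")
    popt, rss = best
    params = SigmoidParams(h_max=float(popt[0]), t_half_ns=float(popt[1]), k_per_ns=float(popt[2]))
    diagnostics = {"rss": rss, "n_points": len(t)}
    return params, diagnostics


def transitions_table(records: list[TransitionRecord]) -> pd.DataFrame:
    """Transition records as a table (chain, time, neighbours, aggregate)."""
    from .aggregation import oligomer_name

    rows = [
        {
            "chain_id": r.chain_id,
            "time_ns": r.time_ns,
            "neighbours": ", ".join(r.neighbours),
            "aggregate_size": r.aggregate_size,
            "aggregate": oligomer_name(r.aggregate_size),
        }
        for r in sorted(records, key=lambda r: r.chain_id)
    ]
    return pd.DataFrame(
        rows, columns=["chain_id", "time_ns", "neighbours", "aggregate_size", "aggregate"]
    )
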