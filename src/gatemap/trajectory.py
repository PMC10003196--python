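"""Trajectory analyses: superposition RMSD, stability onset, pair-distance series.

Trajectories arrive as multi-model PDB ensembles (frames exported upstream at
a fixed cadence, 0.2 ns by default).  RMSD against a reference frame uses the
Kabsch closed-form superposition over a configurable atom selection (C-alpha
by default); the equilibration point is the first frame at which a sliding
window of the RMSD series is flat to within a slope tolerance, and pair
distances are averaged only over frames after that onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .bridges import PairDistanceStat, ResiduePairSpec, charged_pair_distance, distance_stats
from .errors import EmptySelectionError
from .model import AtomRecord, StructureEnsemble

logger = logging.getLogger(__name__)


def ca_selection(atom: AtomRecord) -> bool:
    """Default RMSD selection: C-alpha atoms of non-hetero residues."""
    return atom.atom_name == "CA" and not atom.is_hetero


@dataclass
class TrajectoryMeta:
    """Frame cadence and RMSD atom selection for one trajectory."""

    frame_interval: float = 0.2  # ns between exported frames
    selection: Callable[[AtomRecord], bool] = field(default=ca_selection)
    reference_index: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


@dataclass
class RmsdSeries:
    """Aligned RMSD of every frame against the reference frame."""

    times: np.ndarray  # ns
    values: np.ndarray  # A
    reference_index: int


@dataclass(frozen=True)
class StabilityResult:
    """First frame from which the RMSD series is flat (equilibrated)."""

    onset_index: int
    onset_time: float  # ns
    window: int
    slope_tol: float  # A/ns


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    ref: np.ndarray, mov: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mov`` onto ``ref``.

    Closed form: centroid subtraction, SVD of the cross-covariance, and a
    determinant sign correction so the rotation is proper (no reflection).
    Returns ``(R, t, rmsd)`` with ``mov`` best aligned as ``mov @ R.T + t``.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {ref.shape} vs {mov.shape}")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a determined superposition")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    p = ref - ref_c
    q = mov - mov_c
    h = q.T @ p  # cross-covariance (mov -> ref)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    rot = vt.T @ s @ u.T
    t = ref_c - rot @ mov_c
    aligned = q @ rot.T
    rmsd = float(np.sqrt(((aligned - p) ** 2).sum() / n))
    return rot, t, rmsd


def rmsd_series(traj: StructureEnsemble, meta: TrajectoryMeta = TrajectoryMeta()) -> RmsdSeries:
    """Per-frame superposed RMSD against the reference frame."""
    sel_idx = [i for i, a in enumerate(traj.models[0]) if meta.selection(a)]
    if not sel_idx:
        raise EmptySelectionError("RMSD atom selection matched no atoms")
    coords = np.array(
        [[traj.models[f][i].xyz for i in sel_idx] for f in range(traj.n_models)]
    )
    ref = coords[meta.reference_index]
    values = np.array([kabsch_superpose(ref, frame)[2] for frame in coords])
    values[meta.reference_index] = 0.0  # exact by definition
    times = np.arange(traj.n_models) * meta.frame_interval
    return RmsdSeries(times=times, values=values, reference_index=meta.reference_index)


def stability_onset(
    s: RmsdSeries, window: int = 50, slope_tol: float = 0.05
) -> StabilityResult:
    """First index whose forward window has least-squares |slope| <= slope_tol (A/ns).

    Falls back on ``n_frames - window`` with a logged warning when no window
    is flat enough.
    """
    n = len(s.values)
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    onset = None
    for i in range(n - window + 1):
        t = s.times[i : i + window]
        v = s.values[i : i + window]
        slope = np.polyfit(t, v, 1)[0]
        if abs(slope) <= slope_tol:
            onset = i
            break
    if onset is None:
        onset = n - window
        logger.warning(
            "no window of %d frames flat to %.3g A/ns; onset set to %d", window, slope_tol, onset
        )
    return StabilityResult(
        onset_index=onset,
        onset_time=float(s.times[onset]),
        window=window,
        slope_tol=slope_tol,
    )


def pair_distance_series(
    traj: StructureEnsemble,
    p: ResiduePairSpec,
    onset: StabilityResult | None = None,
    *,
    frame_interval: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, PairDistanceStat]:
    """Per-frame pair distance, and its statistics over post-onset frames only.

    Returns ``(times_ns, distances_A, stat)``; the stat's condition label is
    the trajectory's ``source_label``.
    """
    values = np.array([charged_pair_distance(m, p) for m in traj.models])
    times = np.arange(traj.n_models) * frame_interval
    start = onset.onset_index if onset is not None else 0
    stat = distance_stats(values[start:], p.label, traj.source_label)
    return times, values, stat
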