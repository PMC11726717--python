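"""Per-trajectory structural descriptors.

RMSD/RMSF after Kabsch superposition, side-chain dihedrals and rotamer
occupancies, and contact / hydrogen-bond persistency over merged
replicas.  Contacts use heavy (non-hydrogen) atoms with a closed-interval
distance gate; persistency is the percentage of frames, merged across
replicas with frame weighting, in which a residue pair interacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import Selection, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "MetricSeries",
    "RMSFProfile",
    "ContactTable",
    "RotamerDistribution",
    "DegenerateSelectionError",
    "kabsch",
    "superpose",
    "rmsd",
    "rmsd_summary",
    "rmsf",
    "dihedral_angle",
    "dihedral",
    "wrap_angle",
    "rotamer_distribution",
    "contact_persistency",
    "hbond_persistency",
    "contact_difference",
]


class DegenerateSelectionError(ValueError):
    """Raised when a fit selection is too degenerate for superposition."""


@dataclass
class MetricSeries:
    """Per-frame scalar metric (RMSD in Å or a dihedral in degrees)."""

    name: str
    values: np.ndarray
    selection: str
    replica: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def mean_sd(self) -> tuple[float, float]:
        return float(self.values.mean()), float(self.values.std(ddof=1))


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Å) about the mean structure of merged frames."""

    resids: np.ndarray
    values: np.ndarray
    selection: str

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.resids, name="rmsf")


@dataclass
class RotamerDistribution:
    """Occupancy of the three staggered chi states of one dihedral."""

    residue: int
    dihedral_name: str
    g_minus: float
    trans: float
    g_plus: float

    def __post_init__(self) -> None:
        total = self.g_minus + self.trans + self.g_plus
        if abs(total - 1.0) > 1e-9:
            raise ValueError("rotamer occupancies must sum to 1")


@dataclass
class ContactTable:
    """Residue-pair persistency (% of merged frames) with per-replica detail.

    ``table`` columns: ``res_a``, ``res_b``, ``persistency``,
    ``replica_persistency`` (list of per-replica %), ``consecutive``.
    """

    table: pd.DataFrame
    frames_per_replica: tuple[int, ...]

    @property
    def n_replicas(self) -> int:
        return len(self.frames_per_replica)

    @property
    def residues(self) -> set[int]:
        if self.table.empty:
            return set()
        return set(self.table["res_a"]) | set(self.table["res_b"])

    def persistency_map(self) -> dict[tuple[int, int], float]:
        return {
            (int(r.res_a), int(r.res_b)): float(r.persistency)
            for r in self.table.itertuples()
        }


# ---------------------------------------------------------------------------
# Superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t mapping mobile onto reference.

    Least-squares rigid fit: the returned rotation has determinant +1
    (reflections are excluded).  Apply as ``x @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise DegenerateSelectionError("need >= 3 paired atoms for superposition")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    pm, pr = mobile - cm, reference - cr
    if np.linalg.matrix_rank(pr, tol=1e-8) < 2:
        raise DegenerateSelectionError("fit selection is collinear or degenerate")
    h = pm.T @ pr
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    return rot, trans


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: Selection | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Rigid-fit a full frame onto a reference frame using ``selection``.

    Returns the transformed frame and the post-fit RMSD over the
    selection.
    """
    idx = selection.index_array if isinstance(selection, Selection) else np.asarray(selection)
    rot, trans = kabsch(mobile[idx], reference[idx])
    moved = mobile @ rot.T + trans
    return moved, _rmsd_pair(moved[idx], reference[idx])


def _rmsd_pair(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd(
    trajectory: Trajectory,
    reference: np.ndarray,
    analysis_selection: Selection,
    fit_selection: Selection | None = None,
) -> MetricSeries:
    """Per-frame RMSD of a selection, after optional superposition.

    ``fit_selection=None`` computes the RMSD in the laboratory frame
    (no fitting) — the mode appropriate for a ligand analysed in its own
    frame; passing a receptor selection reproduces the conventional
    receptor-superposed ligand RMSD.
    """
    if len(analysis_selection) == 0:
        raise ValueError("analysis selection is empty")
    a_idx = analysis_selection.index_array
    out = np.empty(trajectory.n_frames)
    for f, frame in enumerate(trajectory.coordinates):
        moved = superpose(frame, reference, fit_selection)[0] if fit_selection else frame
        out[f] = _rmsd_pair(moved[a_idx], reference[a_idx])
    return MetricSeries(
        name="RMSD",
        values=out,
        selection=analysis_selection.expression,
        replica=trajectory.replica,
    )


def rmsd_summary(series: Sequence[MetricSeries], decimals: int = 2) -> str:
    """Merged-replica ``mean ± SD`` string, e.g. ``"2.32 ± 0.87"``."""
    merged = np.concatenate([s.values for s in series])
    return f"{merged.mean():.{decimals}f} ± {merged.std(ddof=1):.{decimals}f}"


def rmsf(
    trajectories: Trajectory | Sequence[Trajectory],
    selection: Selection,
    fit_selection: Selection | None = None,
) -> RMSFProfile:
    """Per-residue RMSF over merged replicas.

    Two-pass convention: frames are superposed on ``fit_selection``, the
    mean structure is taken over the aligned frames, frames are
    re-aligned to that mean and the mean recomputed, then fluctuations
    are measured about it.  ``fit_selection=None`` skips superposition
    for frames already sharing a common reference frame (the synthetic
    generator's output); note that fitting removes six rigid-body
    degrees of freedom and therefore slightly deflates fluctuations on
    small selections.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    top = trajectories[0].topology
    frames = np.concatenate([t.coordinates for t in trajectories], axis=0)
    if frames.shape[0] < 2:
        raise ValueError("RMSF needs >= 2 merged frames")
    if fit_selection is not None:
        aligned = np.stack([superpose(f, frames[0], fit_selection)[0] for f in frames])
        mean = aligned.mean(axis=0)
        aligned = np.stack([superpose(f, mean, fit_selection)[0] for f in aligned])
    else:
        aligned = frames
    mean = aligned.mean(axis=0)

    idx = selection.index_array
    sq = np.sum((aligned[:, idx, :] - mean[idx]) ** 2, axis=2)  # (frames, atoms)
    resids_sel = top.resids[idx]
    order, values = [], []
    for resid in pd.unique(resids_sel):
        cols = resids_sel == resid
        order.append(int(resid))
        values.append(float(np.sqrt(sq[:, cols].mean())))
    return RMSFProfile(
        resids=np.array(order), values=np.array(values), selection=selection.expression
    )


# ---------------------------------------------------------------------------
# Dihedrals and rotamers


def wrap_angle(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap degrees into the interval (−180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = a - 360.0 * np.ceil((a - 180.0) / 360.0)
    return float(wrapped) if np.isscalar(angle) else wrapped


def dihedral_angle(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Signed dihedral (degrees, IUPAC convention) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise ValueError("central atoms coincide")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise ValueError("collinear atom triple: dihedral undefined")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(wrap_angle(math.degrees(math.atan2(y, x))))


def dihedral(trajectory: Trajectory, atom_ids: Sequence[int]) -> MetricSeries:
    """Per-frame signed dihedral over four distinct atoms."""
    ids = tuple(int(i) for i in atom_ids)
    if len(ids) != 4 or len(set(ids)) != 4:
        raise ValueError("dihedral needs four distinct atom ids")
    vals = np.array(
        [dihedral_angle(*(frame[list(ids)])) for frame in trajectory.coordinates]
    )
    return MetricSeries(
        name="dihedral", values=vals, selection=str(ids), replica=trajectory.replica
    )


def rotamer_distribution(
    series: MetricSeries | np.ndarray,
    residue: int = 0,
    dihedral_name: str = "chi1",
) -> RotamerDistribution:
    """Occupancies of g+ (0,120], trans (120,180]∪(−180,−120], g− (−120,0]."""
    values = series.values if isinstance(series, MetricSeries) else np.asarray(series, float)
    if values.size == 0:
        raise ValueError("empty dihedral series")
    a = wrap_angle(values)
    g_plus = np.mean((a > 0) & (a <= 120))
    trans = np.mean((a > 120) | (a <= -120))
    g_minus = np.mean((a > -120) & (a <= 0))
    return RotamerDistribution(
        residue=residue,
        dihedral_name=dihedral_name,
        g_minus=float(g_minus),
        trans=float(trans),
        g_plus=float(g_plus),
    )


# ---------------------------------------------------------------------------
# Contacts and hydrogen bonds


def _as_traj_list(trajectories: Trajectory | Sequence[Trajectory]) -> list[Trajectory]:
    return [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)


def _pair_contact_counts(
    traj: Trajectory,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    cutoff: float,
    intra: bool,
) -> dict[tuple[int, int], int]:
    """Frames in which each residue pair has any heavy-atom pair <= cutoff."""
    top = traj.topology
    res_a = top.resids[idx_a]
    res_b = top.resids[idx_b]
    counts: dict[tuple[int, int], int] = {}
    for frame in traj.coordinates:
        d = cdist(frame[idx_a], frame[idx_b])
        within = d <= cutoff  # closed interval: exactly at the cutoff counts
        if not within.any():
            continue
        ia, ib = np.nonzero(within)
        pairs = set()
        for ra, rb in zip(res_a[ia], res_b[ib]):
            if intra:
                if ra == rb:
                    continue
                key = (int(min(ra, rb)), int(max(ra, rb)))
            else:
                key = (int(ra), int(rb))
            pairs.add(key)
        for key in pairs:
            counts[key] = counts.get(key, 0) + 1
    return counts


def contact_persistency(
    trajectories: Trajectory | Sequence[Trajectory],
    selection_a: Selection,
    selection_b: Selection,
    cutoff: float = 4.5,
    allow_overlap: bool = False,
) -> ContactTable:
    """Residue-pair contact persistency over merged replicas.

    A pair is in contact in a frame when any heavy-atom pair across the
    two residues lies within ``cutoff`` Å (closed interval).  Overlapping
    selections are only permitted in intra-receptor mode
    (``allow_overlap=True``), where unordered residue pairs are reported
    and same-residue pairs skipped.
    """
    trajs = _as_traj_list(trajectories)
    top = trajs[0].topology
    heavy = top.heavy_mask()
    idx_a = np.array([i for i in selection_a.indices if heavy[i]], dtype=int)
    idx_b = np.array([i for i in selection_b.indices if heavy[i]], dtype=int)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("contact selections contain no heavy atoms")
    shared = set(idx_a.tolist()) & set(idx_b.tolist())
    if shared and not allow_overlap:
        raise ValueError(
            "selections overlap; pass allow_overlap=True for intra-receptor mode"
        )
    intra = bool(shared)

    per_replica: list[dict[tuple[int, int], int]] = []
    frames: list[int] = []
    for traj in trajs:
        per_replica.append(_pair_contact_counts(traj, idx_a, idx_b, cutoff, intra))
        frames.append(traj.n_frames)

    all_pairs = sorted(set().union(*per_replica)) if per_replica else []
    rows = []
    total = sum(frames)
    for pair in all_pairs:
        rep_pers = [100.0 * c.get(pair, 0) / nf for c, nf in zip(per_replica, frames)]
        merged = 100.0 * sum(c.get(pair, 0) for c in per_replica) / total
        rows.append(
            dict(
                res_a=pair[0],
                res_b=pair[1],
                persistency=merged,
                replica_persistency=rep_pers,
                consecutive=abs(pair[0] - pair[1]) == 1,
            )
        )
    table = pd.DataFrame(
        rows, columns=["res_a", "res_b", "persistency", "replica_persistency", "consecutive"]
    )
    return ContactTable(table=table, frames_per_replica=tuple(frames))


def hbond_persistency(
    trajectories: Trajectory | Sequence[Trajectory],
    donors: Sequence[tuple[int, int | None]],
    acceptors: Sequence[int],
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
    geometric_only: bool = False,
) -> ContactTable:
    """Hydrogen-bond persistency per residue pair over merged replicas.

    A bond is present in a frame when the donor–acceptor heavy-atom
    distance is <= ``distance_cutoff`` Å and the donor–H–acceptor angle
    is >= ``angle_cutoff`` degrees.  ``donors`` is a list of
    ``(donor_atom, hydrogen_atom)`` index pairs; a missing hydrogen is an
    error unless ``geometric_only=True`` selects the distance-only
    criterion.
    """
    trajs = _as_traj_list(trajectories)
    top = trajs[0].topology
    if not geometric_only and any(h is None for _, h in donors):
        raise ValueError(
            "donor without hydrogen: add explicit hydrogens or pass "
            "geometric_only=True for the distance-only criterion"
        )
    cos_limit = math.cos(math.radians(angle_cutoff))

    per_replica: list[dict[tuple[int, int], int]] = []
    frames: list[int] = []
    for traj in trajs:
        counts: dict[tuple[int, int], int] = {}
        for frame in traj.coordinates:
            present = set()
            for d_idx, h_idx in donors:
                for a_idx in acceptors:
                    if a_idx == d_idx:
                        continue
                    res_pair = (int(top.resids[d_idx]), int(top.resids[a_idx]))
                    if res_pair[0] == res_pair[1]:
                        continue
                    if np.linalg.norm(frame[d_idx] - frame[a_idx]) > distance_cutoff:
                        continue
                    if not geometric_only:
                        v1 = frame[d_idx] - frame[h_idx]
                        v2 = frame[a_idx] - frame[h_idx]
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        # angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
                        if cosang > cos_limit + 1e-12:
                            continue
                    present.add(res_pair)
            for key in present:
                counts[key] = counts.get(key, 0) + 1
        per_replica.append(counts)
        frames.append(traj.n_frames)

    all_pairs = sorted(set().union(*per_replica)) if per_replica else []
    total = sum(frames)
    rows = [
        dict(
            res_a=p[0],
            res_b=p[1],
            persistency=100.0 * sum(c.get(p, 0) for c in per_replica) / total,
            replica_persistency=[
                100.0 * c.get(p, 0) / nf for c, nf in zip(per_replica, frames)
            ],
            consecutive=abs(p[0] - p[1]) == 1,
        )
        for p in all_pairs
    ]
    table = pd.DataFrame(
        rows, columns=["res_a", "res_b", "persistency", "replica_persistency", "consecutive"]
    )
    return ContactTable(table=table, frames_per_replica=tuple(frames))


def contact_difference(a: ContactTable, b: ContactTable) -> pd.DataFrame:
    """Per-pair persistency difference A − B with a replica-level SD.

    Pairs absent from one table contribute zero persistency there.  When
    replica counts match, the SD is that of per-replica differences;
    otherwise the two replica SDs are pooled in quadrature.
    """
    if a.residues and b.residues and not (a.residues & b.residues):
        raise ValueError("contact tables have disjoint residue universes")
    map_a = {(r.res_a, r.res_b): r for r in a.table.itertuples()}
    map_b = {(r.res_a, r.res_b): r for r in b.table.itertuples()}
    rows = []
    for pair in sorted(set(map_a) | set(map_b)):
        ra, rb = map_a.get(pair), map_b.get(pair)
        pa = ra.persistency if ra else 0.0
        pb = rb.persistency if rb else 0.0
        reps_a = np.asarray(ra.replica_persistency if ra else [0.0] * a.n_replicas)
        reps_b = np.asarray(rb.replica_persistency if rb else [0.0] * b.n_replicas)
        if len(reps_a) == len(reps_b):
            diffs = reps_a - reps_b
            sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else float("nan")
        else:
            sd_a = float(np.std(reps_a, ddof=1)) if len(reps_a) > 1 else 0.0
            sd_b = float(np.std(reps_b, ddof=1)) if len(reps_b) > 1 else 0.0
            sd = math.hypot(sd_a, sd_b)
        rows.append(
            dict(res_a=pair[0], res_b=pair[1], delta=pa - pb, sd=sd,
                 persistency_a=pa, persistency_b=pb)
        )
    return pd.DataFrame(
        rows, columns=["res_a", "res_b", "delta", "sd", "persistency_a", "persistency_b"]
    )
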