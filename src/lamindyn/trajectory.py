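"""3D locus (telomere) trajectory analysis.

Trajectories are time-stamped 3D positions of fluorescently labelled
telomeres, nominally 50 time points over 20.5 min per nucleus. The analysis
removes whole-nucleus drift and rotation by rigid registration of the
telomere constellation to the first frame, keeps only complete tracks, and
summarizes motion by the convex-hull volume of the visited positions and by
time-averaged mean square displacement (MSD) curves. For free 3D diffusion
MSD(tau) = 6 D tau; anomalous subdiffusion grows sublinearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from . import stats as _stats

__all__ = [
    "Trajectory3D",
    "MotionSummary",
    "RigidTransform",
    "register_frames",
    "filter_complete",
    "hull_volume",
    "msd",
    "population_curves",
]


@dataclass
class Trajectory3D:
    """Track of one telomere: times (s) and xyz positions (um)."""

    telomere_id: int
    nucleus_id: int
    t: np.ndarray
    xyz: np.ndarray
    missing: np.ndarray | None = None  # per-frame flag

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (self.t.size, 3):
            raise ValueError("xyz must be (n_points, 3)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.missing is None:
            self.missing = np.zeros(self.t.size, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        if not np.all(np.isfinite(self.xyz[~self.missing])):
            raise ValueError("non-missing positions must be finite")

    @property
    def n_points(self) -> int:
        return self.t.size

    @property
    def complete(self) -> bool:
        return not bool(self.missing.any())


@dataclass
class MotionSummary:
    telomere_id: int
    hull_volume: float      # um^3
    msd_lag: np.ndarray     # s
    msd: np.ndarray         # um^2
    n_points_used: int


@dataclass
class RigidTransform:
    """Rotation + translation mapping a frame onto the reference frame."""

    rotation: np.ndarray
    translation: np.ndarray
    frame_index: int
    corrected: bool = True

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, v) with dst ~= src @ R.T + v."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    v = mu_d - R @ mu_s
    return R, v


def register_frames(
    trajs: list[Trajectory3D],
) -> tuple[list[Trajectory3D], list[RigidTransform]]:
    """Remove nucleus drift and rotation from all tracks of one nucleus.

    For each frame, the constellation of telomeres visible both in that
    frame and in frame 0 is rigidly aligned to its frame-0 configuration by
    the closed-form (SVD) least-squares rotation + translation; the
    transform is then applied to every telomere of the frame. Frames with
    fewer than three usable points are left uncorrected and flagged.
    """
    if not trajs:
        return [], []
    n_frames = trajs[0].n_points
    if any(tr.n_points != n_frames for tr in trajs):
        raise ValueError("all tracks of a nucleus must share the frame grid")
    pts = np.stack([tr.xyz for tr in trajs])          # (n_tel, n_frames, 3)
    miss = np.stack([tr.missing for tr in trajs])     # (n_tel, n_frames)

    corrected = pts.copy()
    transforms: list[RigidTransform] = []
    ref_ok = ~miss[:, 0]
    for f in range(n_frames):
        usable = ref_ok & ~miss[:, f]
        if f == 0 or usable.sum() < 3:
            ok = f == 0
            transforms.append(RigidTransform(np.eye(3), np.zeros(3), f, ok))
            continue
        R, v = _kabsch(pts[usable, f], pts[usable, 0])
        corrected[:, f] = pts[:, f] @ R.T + v
        transforms.append(RigidTransform(R, v, f))

    out = [
        Trajectory3D(tr.telomere_id, tr.nucleus_id, tr.t, corrected[i],
                     missing=tr.missing.copy())
        for i, tr in enumerate(trajs)
    ]
    return out, transforms


def filter_complete(trajs: list[Trajectory3D], n_required: int = 50) -> list[Trajectory3D]:
    """Keep only tracks observed at every one of ``n_required`` time points."""
    return [tr for tr in trajs
            if tr.n_points == n_required and tr.complete]


def hull_volume(traj: Trajectory3D | np.ndarray) -> float:
    """Volume (um^3) of the convex hull of all track positions.

    Degenerate point sets (fewer than 4 points, collinear or coplanar
    tracks) have zero enclosed volume and return 0.
    """
    pts = traj.xyz if isinstance(traj, Trajectory3D) else np.asarray(traj, float)
    if pts.shape[0] < 4:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return 0.0


def msd(traj: Trajectory3D) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over all ordered point pairs at each lag multiple.

    Returns ``(lags_s, msd_um2)`` for lag multiples 0..n-1 of the frame
    interval; msd[0] = 0 by definition.
    """
    pts, t = traj.xyz, traj.t
    n = pts.shape[0]
    out = np.zeros(n)
    for m in range(1, n):
        d = pts[m:] - pts[:-m]
        out[m] = np.mean(np.sum(d * d, axis=1))
    lags = t - t[0]
    return lags, out


def summarize(traj: Trajectory3D) -> MotionSummary:
    """Hull volume plus MSD curve for one complete track."""
    lags, curve = msd(traj)
    return MotionSummary(traj.telomere_id, hull_volume(traj), lags, curve,
                         traj.n_points)


def population_curves(summaries: list[MotionSummary], band: float = 0.70):
    """Mean MSD with a central-70% population band, plus hull-volume box stats.

    The band at each lag spans the 15th-85th percentiles of per-track MSD
    values (central ``band`` fraction of the population). Returns a dict with
    keys ``lag``, ``mean``, ``lo``, ``hi``, ``hull_box``; the box summary
    follows the Tukey whisker rule.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two tracks per group")
    lag0 = summaries[0].msd_lag
    for s in summaries:
        if s.msd_lag.shape != lag0.shape or not np.allclose(s.msd_lag, lag0):
            raise ValueError("tracks must share the lag grid")
    curves = np.stack([s.msd for s in summaries])
    q = (1.0 - band) / 2.0
    lo, hi = np.quantile(curves, [q, 1.0 - q], axis=0)
    volumes = np.array([s.hull_volume for s in summaries])
    return {
        "lag": lag0,
        "mean": curves.mean(axis=0),
        "lo": lo,
        "hi": hi,
        "hull_volumes": volumes,
        "hull_box": _stats.tukey_box(volumes),
    }
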