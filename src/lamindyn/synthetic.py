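"""Synthetic data generators with stored ground truth.

Every input the pipeline consumes can be generated here with known truth:
nuclei rendered as disks with a bright peripheral rim and a dimmer
nucleoplasm at a configurable true N/P ratio, bimodal (2C/4C) DNA-content
populations, two-population continuous-photobleaching traces, triplet-3D
FCS correlation curves, free / anomalous / confined 3D telomere
trajectories with shared nuclear drift and rotation, and punctate
intranuclear structures with a peripheral exclusion rim. All randomness of
one call flows from a single generator seeded by the mandatory config seed,
so identical configs reproduce identical artifacts bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fcs import FCSCurve, FCSModelParams, eval_model
from .imagequant import NucleusImage
from .photobleach import CPTrace
from .trajectory import Trajectory3D

__all__ = [
    "SyntheticNucleusConfig",
    "SyntheticCPConfig",
    "SyntheticTrajectoryConfig",
    "GroundTruth",
    "gen_nucleus_image",
    "gen_timelapse",
    "gen_cp_trace",
    "gen_fcs_curve",
    "gen_trajectories",
    "gen_structure_image",
]

# coefficient of variation of per-nucleus integrated DNA content around its
# 2C/4C mean; typical width of DAPI histogram peaks in fixed-cell cytometry
DNA_CV = 0.06


@dataclass
class SyntheticNucleusConfig:
    """Geometry, intensities and noise of rendered nuclei."""

    image_size: tuple[int, int] = (512, 512)   # (rows, cols) pixels
    pixel_size: float = 0.1                    # um/pixel
    nucleus_radius: float = 5.0                # um
    rim_width_true: float = 0.8                # um
    peripheral_intensity: float = 200.0        # a.u.
    nucleoplasm_intensity: float = 50.0        # a.u.
    background_intensity: float = 5.0          # a.u.
    noise_sd: float = 0.0                      # a.u.
    n_nuclei: int = 1
    dna_2c_mean: float = 1.0e5                 # a.u. integrated density
    dna_4c_mean: float = 2.0e5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.peripheral_intensity >= self.nucleoplasm_intensity
                >= self.background_intensity >= 0):
            raise ValueError("need peripheral >= nucleoplasm >= background >= 0")
        if self.rim_width_true >= self.nucleus_radius:
            raise ValueError("rim width must be smaller than nucleus radius")
        if self.pixel_size <= 0 or self.nucleus_radius <= 0:
            raise ValueError("pixel_size and nucleus_radius must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")


@dataclass
class SyntheticCPConfig:
    """Two-population continuous-photobleaching trace parameters.

    The immobile fraction bleaches at ``k_fast``; the mobile pool depletes
    slowly at ``k_slow`` because it exchanges with the nucleoplasmic
    reservoir. Traces are normalized to an initial intensity of 1, so
    ``noise_sd`` is relative (a trace at SNR 50 has noise_sd = 0.02).
    """

    f_immobile_true: float = 0.3
    k_fast: float = 1.0      # 1/s
    k_slow: float = 0.01     # 1/s
    duration: float = 60.0   # s
    sample_rate: float = 1000.0  # Hz
    noise_sd: float = 0.02   # a.u. (of an I0=1 trace)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_immobile_true <= 1.0:
            raise ValueError("f_immobile_true must lie in [0, 1]")
        if not self.k_fast > self.k_slow > 0:
            raise ValueError("need k_fast > k_slow > 0")
        if self.duration * self.sample_rate < 2:
            raise ValueError("duration * sample_rate must give >= 2 samples")


@dataclass
class SyntheticTrajectoryConfig:
    """3D locus-motion simulation parameters (50 points over 20.5 min)."""

    motion_model: str = "free"        # free | anomalous | confined
    D_true: float = 5e-4              # um^2/s
    alpha_true: float = 1.0
    confinement_radius: float = 0.5   # um
    n_points: int = 50
    total_time: float = 20.5          # min
    drift_velocity: float = 0.0       # um/s
    rotation_rate: float = 0.0        # rad/s
    n_telomeres: int = 40
    localization_noise_sd: float = 0.0  # um
    nucleus_radius: float = 5.0       # um; initial positions scatter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motion_model not in ("free", "anomalous", "confined"):
            raise ValueError(f"unknown motion model {self.motion_model!r}")
        if self.n_points < 2 or self.total_time <= 0:
            raise ValueError("need n_points >= 2 and total_time > 0")
        if self.motion_model == "free" and self.alpha_true != 1.0:
            raise ValueError("free diffusion requires alpha_true = 1")
        if self.motion_model == "confined" and self.confinement_radius <= 0:
            raise ValueError("confined model needs confinement_radius > 0")


@dataclass
class GroundTruth:
    """Truth fields stored by the generator that produced a dataset."""

    true_np_ratio: np.ndarray | float | None = None
    true_cell_cycle_label: list | None = None
    true_f_immobile: float | None = None
    true_fcs_params: FCSModelParams | None = None
    true_structure_count: int | None = None
    extra: dict = field(default_factory=dict)


def _disk_distance(shape, center, pixel_size):
    yy, xx = np.indices(shape)
    return np.hypot(yy - center[0], xx - center[1]) * pixel_size


def _place_nuclei(cfg: SyntheticNucleusConfig, rng: np.random.Generator,
                  max_attempts: int = 500) -> list[tuple[float, float]]:
    """Non-overlapping nucleus centres (pixel coords); bounded retries."""
    r_px = cfg.nucleus_radius / cfg.pixel_size
    h, w = cfg.image_size
    margin = r_px + 2
    if 2 * margin >= min(h, w):
        raise ValueError("nucleus too large for the image")
    centers: list[tuple[float, float]] = []
    for _ in range(cfg.n_nuclei):
        for attempt in range(max_attempts):
            c = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            if all(np.hypot(c[0] - o[0], c[1] - o[1]) > 2 * r_px + 4
                   for o in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {len(centers) + 1} without overlap "
                f"after {max_attempts} attempts")
    return centers


def _render_lamin(cfg, centers, np_intensity, rng) -> np.ndarray:
    lam = np.full(cfg.image_size, cfg.background_intensity, dtype=float)
    for c in centers:
        d = _disk_distance(cfg.image_size, c, cfg.pixel_size)
        inside = d <= cfg.nucleus_radius
        interior = d <= cfg.nucleus_radius - cfg.rim_width_true
        lam[inside] = cfg.peripheral_intensity
        lam[interior] = np_intensity
    if cfg.noise_sd > 0:
        lam = np.clip(lam + rng.normal(0, cfg.noise_sd, lam.shape), 0, None)
    return lam


def gen_nucleus_image(cfg: SyntheticNucleusConfig
                      ) -> tuple[NucleusImage, GroundTruth]:
    """Render a two-channel (lamin, DNA) field of synthetic nuclei.

    Each nucleus is a disk with a bright annulus of width ``rim_width_true``
    at ``peripheral_intensity`` and an interior at ``nucleoplasm_intensity``;
    the DNA channel gives each nucleus a total integrated intensity drawn
    lognormally around its 2C or 4C mean (labels assigned at random, about
    half each). Truth records the per-nucleus N/P ratio, cell-cycle label
    and the exact label image.
    """
    rng = np.random.default_rng(cfg.seed)
    centers = _place_nuclei(cfg, rng)
    lam = _render_lamin(cfg, centers, cfg.nucleoplasm_intensity, rng)

    dna = np.full(cfg.image_size, 0.0)
    labels = np.zeros(cfg.image_size, dtype=int)
    cycle_labels, dna_totals = [], []
    sigma = math.sqrt(math.log(1 + DNA_CV**2))
    for i, c in enumerate(centers, start=1):
        d = _disk_distance(cfg.image_size, c, cfg.pixel_size)
        inside = d <= cfg.nucleus_radius
        labels[inside] = i
        lab = "G1" if rng.random() < 0.5 else "S-G2"
        mean = cfg.dna_2c_mean if lab == "G1" else cfg.dna_4c_mean
        total = mean * rng.lognormal(-0.5 * sigma**2, sigma)
        dna[inside] = total / inside.sum()
        cycle_labels.append(lab)
        dna_totals.append(total)
    if cfg.noise_sd > 0:
        dna = np.clip(dna + rng.normal(0, cfg.noise_sd, dna.shape), 0, None)

    image = NucleusImage(channels={"lamin": lam, "dna": dna},
                         pixel_size=cfg.pixel_size)
    ratio = (cfg.nucleoplasm_intensity / cfg.peripheral_intensity
             if cfg.peripheral_intensity > 0 else np.nan)
    truth = GroundTruth(
        true_np_ratio=np.full(len(centers), ratio),
        true_cell_cycle_label=cycle_labels,
        extra={"centers_px": centers, "label_image": labels,
               "dna_totals": dna_totals,
               "radius_px": cfg.nucleus_radius / cfg.pixel_size},
    )
    return image, truth


def gen_timelapse(cfg: SyntheticNucleusConfig, ratio_curve: Sequence[float]
                  ) -> tuple[list[NucleusImage], GroundTruth]:
    """Time series of nucleus images following a true N/P ratio curve.

    Frame t renders the nucleoplasm at ``ratio_curve[t] * peripheral``;
    nucleus positions are fixed across frames. Truth stores the full curve.
    """
    curve = np.asarray(ratio_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("ratio_curve must be non-empty")
    if np.any((curve <= 0) | (curve > 1)):
        raise ValueError("ratio_curve values must lie in (0, 1]")
    rng = np.random.default_rng(cfg.seed)
    centers = _place_nuclei(cfg, rng)
    frames = []
    for rho in curve:
        lam = _render_lamin(cfg, centers, rho * cfg.peripheral_intensity, rng)
        frames.append(NucleusImage(channels={"lamin": lam},
                                   pixel_size=cfg.pixel_size))
    truth = GroundTruth(true_np_ratio=curve,
                        extra={"centers_px": centers})
    return frames, truth


def gen_cp_trace(cfg: SyntheticCPConfig) -> tuple[CPTrace, GroundTruth]:
    """Two-exponential continuous-photobleaching trace with Gaussian noise.

    I(t) = f exp(-k_fast t) + (1 - f) exp(-k_slow t) + noise, clipped at 0
    (clipping is flagged in the trace metadata).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    f = cfg.f_immobile_true
    clean = f * np.exp(-cfg.k_fast * t) + (1 - f) * np.exp(-cfg.k_slow * t)
    y = clean + rng.normal(0, cfg.noise_sd, n) if cfg.noise_sd > 0 else clean
    clipped = bool(np.any(y < 0))
    trace = CPTrace(t=t, intensity=np.clip(y, 0, None),
                    metadata={"sample_rate": cfg.sample_rate,
                              "duration": cfg.duration, "clipped": clipped})
    return trace, GroundTruth(true_f_immobile=f)


def gen_fcs_curve(params: FCSModelParams, noise_frac: float = 0.0,
                  seed: int = 0, points_per_decade: int = 16,
                  lag_range: tuple[float, float] | None = None) -> FCSCurve:
    """Triplet-3D model curve on a log-spaced lag grid plus relative noise.

    The grid spans at least 4 decades bracketing every diffusion time; noise
    at each lag is Gaussian with SD ``noise_frac * |G|`` and is recorded in
    the curve weights.
    """
    if lag_range is None:
        lo = min(params.tau_diff.min() / 100, params.tau_trip.min() / 10)
        hi = params.tau_diff.max() * 1000
    else:
        lo, hi = lag_range
    if hi / lo < 1e4:
        hi = lo * 1e4
    n = int(np.ceil(points_per_decade * np.log10(hi / lo))) + 1
    lag = np.geomspace(lo, hi, n)
    g = eval_model(params, lag)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        sd = noise_frac * np.abs(g)
        g = g + rng.normal(0, 1, n) * sd
        return FCSCurve(lag=lag, G=g, weights=np.maximum(sd, 1e-12))
    return FCSCurve(lag=lag, G=g)


def _fgn_increments(n: int, alpha: float, rng: np.random.Generator,
                    n_axes: int = 3) -> np.ndarray:
    """Unit-scale fractional-Gaussian increments with Hurst H = alpha/2.

    Covariance of unit-time increments: gamma(k) = (|k+1|^a - 2|k|^a +
    |k-1|^a)/2; sampled exactly via Cholesky (n is small here).
    """
    k = np.arange(n)
    gamma = 0.5 * (np.abs(k + 1)**alpha - 2 * np.abs(k)**alpha
                   + np.abs(k - 1)**alpha)
    cov = gamma[np.abs(k[:, None] - k[None, :])]
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return (L @ rng.standard_normal((n, n_axes)))


def gen_trajectories(cfg: SyntheticTrajectoryConfig
                     ) -> tuple[list[Trajectory3D], GroundTruth]:
    """Simulate telomere tracks of one nucleus, plus shared rigid motion.

    free: per-axis Gaussian steps with variance 2 D dt. confined: free steps
    specularly reflected into a sphere of ``confinement_radius`` around the
    start point. anomalous: fractional-Gaussian increments with per-axis
    MSD 2 D t^alpha. All telomeres share the nucleus drift (constant
    velocity along a random direction) and rotation about the nucleus
    centre; localization noise is added last. Truth stores the parameters
    and the clean (drift-free, noise-free) coordinates.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_points, cfg.n_telomeres
    total_s = cfg.total_time * 60.0
    dt = total_s / (n - 1)
    t = np.arange(n) * dt

    starts = rng.uniform(-1, 1, (m, 3))
    starts *= (0.6 * cfg.nucleus_radius
               / np.maximum(np.linalg.norm(starts, axis=1, keepdims=True), 1e-9))
    starts *= rng.uniform(0.2, 1.0, (m, 1))

    clean = np.zeros((m, n, 3))
    for i in range(m):
        if cfg.D_true == 0:
            clean[i] = starts[i]
            continue
        if cfg.motion_model == "anomalous":
            inc = _fgn_increments(n - 1, cfg.alpha_true, rng)
            inc *= math.sqrt(2 * cfg.D_true) * dt ** (cfg.alpha_true / 2)
            clean[i] = starts[i] + np.vstack([np.zeros(3), np.cumsum(inc, 0)])
        else:
            steps = rng.normal(0, math.sqrt(2 * cfg.D_true * dt), (n - 1, 3))
            if cfg.motion_model == "free":
                clean[i] = starts[i] + np.vstack([np.zeros(3),
                                                  np.cumsum(steps, 0)])
            else:  # confined: radial specular reflection at the sphere
                pos = np.zeros((n, 3))
                R = cfg.confinement_radius
                for j in range(1, n):
                    p = pos[j - 1] + steps[j - 1]
                    r = np.linalg.norm(p)
                    if r > R:
                        p = p * (2 * R - r) / r
                        r2 = np.linalg.norm(p)
                        if r2 > R:  # huge step: clamp to the boundary
                            p = p * R / r2
                    pos[j] = p
                clean[i] = starts[i] + pos

    # shared rigid nucleus motion: rotation about z through the origin + drift
    drift_dir = rng.standard_normal(3)
    drift_dir /= np.linalg.norm(drift_dir)
    theta = cfg.rotation_rate * t
    observed = np.empty_like(clean)
    for j in range(n):
        c, s = math.cos(theta[j]), math.sin(theta[j])
        Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        observed[:, j] = clean[:, j] @ Rz.T + cfg.drift_velocity * t[j] * drift_dir
    if cfg.localization_noise_sd > 0:
        observed = observed + rng.normal(0, cfg.localization_noise_sd,
                                         observed.shape)

    trajs = [Trajectory3D(telomere_id=i, nucleus_id=0, t=t, xyz=observed[i])
             for i in range(m)]
    truth = GroundTruth(extra={
        "motion_model": cfg.motion_model, "D_true": cfg.D_true,
        "alpha_true": cfg.alpha_true, "clean_xyz": clean, "t": t,
        "drift_dir": drift_dir, "drift_velocity": cfg.drift_velocity,
        "rotation_rate": cfg.rotation_rate,
    })
    return trajs, truth


def gen_structure_image(
    spots: Sequence[tuple[tuple[float, float], float]],
    cfg: SyntheticNucleusConfig,
    rim: float = 0.8,
    area_bounds: tuple[float, float] = (0.0001, 5.0),
    spot_intensity: float | None = None,
) -> tuple[NucleusImage, GroundTruth]:
    """Draw bright punctate structures inside a single centred nucleus.

    ``spots`` is a sequence of ((y_um, x_um), area_um2) with centroids
    relative to the nucleus centre. Truth counts the spots that pass the
    analysis filters: area within ``area_bounds`` and centroid farther than
    ``rim`` from the nucleus boundary.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    d = _disk_distance(cfg.image_size, center, cfg.pixel_size)
    inside = d <= cfg.nucleus_radius
    interior = d <= cfg.nucleus_radius - cfg.rim_width_true
    lam = np.full(cfg.image_size, cfg.background_intensity, dtype=float)
    lam[inside] = cfg.peripheral_intensity
    lam[interior] = cfg.nucleoplasm_intensity
    if spot_intensity is None:
        spot_intensity = cfg.peripheral_intensity * 1.5

    kept = 0
    per_spot = []
    for (sy, sx), area in spots:
        if area <= 0:
            raise ValueError("spot areas must be positive")
        r_um = math.sqrt(area / math.pi)
        dist_center = math.hypot(sy, sx)
        if dist_center + r_um > cfg.nucleus_radius:
            raise ValueError("spot extends outside the nucleus")
        cy = center[0] + sy / cfg.pixel_size
        cx = center[1] + sx / cfg.pixel_size
        ds = _disk_distance(cfg.image_size, (cy, cx), cfg.pixel_size)
        lam[ds <= r_um] = spot_intensity
        boundary_dist = cfg.nucleus_radius - dist_center
        ok = (area_bounds[0] <= area <= area_bounds[1]) and boundary_dist > rim
        per_spot.append({"centroid_um": (sy, sx), "area_um2": area,
                         "boundary_distance_um": boundary_dist, "counted": ok})
        kept += int(ok)

    if cfg.noise_sd > 0:
        lam = np.clip(lam + rng.normal(0, cfg.noise_sd, lam.shape), 0, None)
    image = NucleusImage(channels={"lamin": lam}, pixel_size=cfg.pixel_size)
    truth = GroundTruth(true_structure_count=kept,
                        extra={"spots": per_spot,
                               "center_px": center,
                               "radius_px": cfg.nucleus_radius / cfg.pixel_size})
    return image, truth
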