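"""Fluorescence correlation spectroscopy: correlator, triplet-3D model, fitting.

The intensity fluctuations of fluorophores diffusing through a femtoliter
confocal volume decay with a characteristic residence (diffusion) time
``tau_diff``. The correlation model used throughout is the triplet-3D form

    G(t) = [1 + sum_j T_j (exp(-t/tau_trip_j) - 1)]
           * sum_i rho_i * [1 + (t/tau_diff_i)^a_i]^-1
                         * [1 + (t/tau_diff_i)^a_i / k^2]^-1/2
           + G_inf

with one triplet (dark) state and two diffusing species by default, an axial
to lateral ratio ``k`` of the focal volume and a calibrated effective
excitation volume ``V_eff`` that links diffusion times to diffusion
coefficients through the beam waist ``w0``:

    w0  = (V_eff / (pi^{3/2} k))^{1/3}        (1 fl == 1 um^3)
    D_i = w0^2 / (4 tau_diff_i)

The module also provides the Stokes-Einstein mass-ratio prediction used to
interpret diffusion-coefficient ratios between protein complexes of different
molecular weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FCSCurve",
    "FCSModelParams",
    "ComplexMass",
    "autocorrelate",
    "eval_model",
    "fit_model",
    "beam_waist",
    "diffusion_coefficient",
    "predicted_d_ratio",
]

# Defaults used by the calibrated confocal setup the pipeline models.
DEFAULT_K = 7.92          # length-to-diameter ratio of the focal volume
DEFAULT_V_EFF = 0.267     # effective excitation volume [fl]


@dataclass
class FCSCurve:
    """Autocorrelation curve: lag times (s, strictly increasing) and G values."""

    lag: np.ndarray
    G: np.ndarray
    weights: np.ndarray | None = None  # per-lag SDs, optional

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lag.ndim != 1 or self.lag.shape != self.G.shape:
            raise ValueError("lag and G must be 1-D arrays of equal length")
        if np.any(self.lag <= 0):
            raise ValueError("lag times must be positive")
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lag grid must be strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G values must be finite")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.lag.shape:
                raise ValueError("weights must match lag grid")


@dataclass
class FCSModelParams:
    """Parameter set of the triplet-3D correlation model.

    ``rho``, ``tau_diff`` and ``alpha`` are per diffusing species (fast
    species first); ``T`` and ``tau_trip`` are per triplet state. ``w0`` and
    ``D`` are derived quantities, filled in from ``V_eff`` and ``k``.
    """

    rho: np.ndarray
    tau_diff: np.ndarray
    T: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    tau_trip: np.ndarray = field(default_factory=lambda: np.array([1e-6]))
    alpha: np.ndarray | None = None
    k: float = DEFAULT_K
    V_eff: float = DEFAULT_V_EFF   # fl == um^3
    G_inf: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        self.tau_diff = np.atleast_1d(np.asarray(self.tau_diff, dtype=float))
        self.T = np.atleast_1d(np.asarray(self.T, dtype=float))
        self.tau_trip = np.atleast_1d(np.asarray(self.tau_trip, dtype=float))
        if self.alpha is None:
            self.alpha = np.ones_like(self.tau_diff)
        else:
            self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.rho.shape != self.tau_diff.shape:
            raise ValueError("rho and tau_diff must have equal length")
        if self.alpha.shape != self.tau_diff.shape:
            raise ValueError("alpha must match the number of species")
        if self.T.shape != self.tau_trip.shape:
            raise ValueError("T and tau_trip must have equal length")
        if np.any(self.tau_diff <= 0) or np.any(self.tau_trip <= 0):
            raise ValueError("all characteristic times must be positive")
        if np.any(self.rho < 0):
            raise ValueError("species contributions rho must be >= 0")
        if np.any((self.T < 0) | (self.T >= 1)):
            raise ValueError("triplet fractions must lie in [0, 1)")
        if self.k <= 1:
            raise ValueError("axial ratio k must exceed 1")
        if self.V_eff <= 0:
            raise ValueError("V_eff must be positive")

    @property
    def n_diff(self) -> int:
        return self.tau_diff.size

    @property
    def n_trip(self) -> int:
        return self.tau_trip.size

    @property
    def w0(self) -> float:
        """Lateral beam waist in um."""
        return beam_waist(self.V_eff, self.k)

    @property
    def D(self) -> np.ndarray:
        """Diffusion coefficient per species in um^2/s."""
        return diffusion_coefficient(self.tau_diff, self.w0)

    def sorted_fast_first(self) -> "FCSModelParams":
        """Return a copy with species ordered by increasing tau_diff."""
        order = np.argsort(self.tau_diff)
        return replace(
            self,
            rho=self.rho[order],
            tau_diff=self.tau_diff[order],
            alpha=self.alpha[order],
        )


@dataclass(frozen=True)
class ComplexMass:
    """A molecular complex and its mass in kDa."""

    label: str
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass of {self.label!r} must be positive")


def autocorrelate(trace: np.ndarray, dt: float, max_lag: float | None = None,
                  points_per_decade: int = 16) -> FCSCurve:
    """Normalized intensity autocorrelation on a quasi-logarithmic lag grid.

    G(tau) = <dI(t) dI(t+tau)> / <I>^2, computed for all integer lags by FFT
    and then averaged within log-spaced lag bins (the software analogue of a
    multi-tau correlator).

    Parameters
    ----------
    trace : intensity samples at uniform spacing ``dt`` seconds.
    max_lag : largest lag in seconds (default: a quarter of the trace).
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("trace must be a 1-D array with at least 2 samples")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("trace mean must be positive for normalization")
    n = x.size
    if max_lag is None:
        max_lag = n * dt / 4
    m = min(n - 1, max(1, int(round(max_lag / dt))))

    d = x - mean
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(d, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: m + 1]
    acov /= n - np.arange(m + 1)          # unbiased estimator
    g = acov / mean**2                    # lag 0..m

    # quasi-log binning of integer lags 1..m
    edges = np.unique(np.round(np.logspace(0, np.log10(m), num=max(2, int(
        points_per_decade * np.log10(m)) + 1))).astype(int))
    lags, gvals = [], []
    lo = 1
    for hi in edges:
        if hi < lo:
            continue
        sl = slice(lo, hi + 1)
        idx = np.arange(lo, hi + 1)
        lags.append(idx.mean() * dt)
        gvals.append(g[sl].mean())
        lo = hi + 1
    return FCSCurve(lag=np.array(lags), G=np.array(gvals))


def eval_model(params: FCSModelParams, lag: np.ndarray | float) -> np.ndarray:
    """Evaluate the triplet-3D correlation model at the given lag times."""
    t = np.asarray(lag, dtype=float)
    trip = 1.0 + sum(
        Tj * (np.exp(-t / tauj) - 1.0)
        for Tj, tauj in zip(params.T, params.tau_trip)
    )
    diff = np.zeros_like(t, dtype=float)
    k2 = params.k**2
    for rho_i, tau_i, a_i in zip(params.rho, params.tau_diff, params.alpha):
        u = (t / tau_i) ** a_i
        diff = diff + rho_i / ((1.0 + u) * np.sqrt(1.0 + u / k2))
    return trip * diff + params.G_inf


def beam_waist(V_eff: float, k: float) -> float:
    """Lateral 1/e^2 focal radius w0 (um) from V_eff (fl) and axial ratio k.

    Inverts the effective-volume relation V_eff = pi^{3/2} k w0^3 (1 fl ==
    1 um^3).
    """
    if V_eff <= 0 or k <= 0:
        raise ValueError("V_eff and k must be positive")
    return (V_eff / (math.pi**1.5 * k)) ** (1.0 / 3.0)


def diffusion_coefficient(tau_diff, w0: float):
    """D = w0^2 / (4 tau_diff), in um^2/s for w0 in um and tau_diff in s."""
    tau = np.asarray(tau_diff, dtype=float)
    if np.any(tau <= 0) or w0 <= 0:
        raise ValueError("tau_diff and w0 must be positive")
    return w0**2 / (4.0 * tau)


def predicted_d_ratio(m_a: ComplexMass, m_b: ComplexMass) -> float:
    """Predicted D_a/D_b for spherical complexes of equal density.

    Under Stokes-Einstein, D is inversely proportional to the hydrodynamic
    radius and hence to the cube root of molecular mass, so the expected
    ratio of diffusion coefficients is (m_b / m_a)^{1/3}.
    """
    return (m_b.mass / m_a.mass) ** (1.0 / 3.0)


def _features(curve: FCSCurve) -> tuple[float, float]:
    """Rough amplitude and half-decay lag used to seed the fit."""
    g = curve.G - curve.G[-1]
    amp = max(g[0], 1e-6)
    below = np.nonzero(g <= amp / 2)[0]
    tau_half = curve.lag[below[0]] if below.size else curve.lag[-1]
    return amp, tau_half


def fit_model(
    curve: FCSCurve,
    n_diff: int = 2,
    n_trip: int = 1,
    k: float = DEFAULT_K,
    V_eff: float = DEFAULT_V_EFF,
    alpha: np.ndarray | float = 1.0,
    fit_triplet: bool = True,
    n_starts: int = 5,
    seed: int | None = 0,
) -> FCSModelParams:
    """Weighted least-squares fit of the triplet-3D model to a curve.

    ``k``, ``V_eff``, ``alpha`` and the state counts are fixed; the free
    parameters are the species contributions rho_i, diffusion times
    tau_diff_i (fitted on a log scale), the triplet fraction(s) T and
    lifetime(s) tau_trip, and the offset G_inf. Species in the returned
    parameter set are ordered fast first (increasing tau_diff). Uses
    multi-start initialization seeded from the curve's amplitude and
    half-decay lag.
    """
    alpha_arr = np.broadcast_to(np.atleast_1d(np.asarray(alpha, float)),
                                (n_diff,)).copy()
    amp, tau_half = _features(curve)
    w = (1.0 / curve.weights) if curve.weights is not None else None
    rng = np.random.default_rng(seed)
    lag_lo, lag_hi = curve.lag[0], curve.lag[-1]

    def unpack(theta):
        rho = theta[:n_diff]
        tau = np.exp(theta[n_diff:2 * n_diff])
        pos = 2 * n_diff
        if fit_triplet and n_trip > 0:
            T = theta[pos:pos + n_trip]
            tau_t = np.exp(theta[pos + n_trip:pos + 2 * n_trip])
            pos += 2 * n_trip
        else:
            T = np.zeros(max(n_trip, 1))
            tau_t = np.full(max(n_trip, 1), 1e-6)
        return rho, tau, T, tau_t, theta[pos]

    def residuals(theta):
        rho, tau, T, tau_t, g_inf = unpack(theta)
        p = FCSModelParams(rho=rho, tau_diff=tau, T=np.clip(T, 0, 1 - 1e-9),
                           tau_trip=tau_t, alpha=alpha_arr, k=k, V_eff=V_eff,
                           G_inf=g_inf)
        r = eval_model(p, curve.lag) - curve.G
        return r * w if w is not None else r

    # spread initial diffusion times around the half-decay lag
    spread = np.geomspace(0.3, 3.0, n_diff) if n_diff > 1 else np.array([1.0])
    best, best_cost = None, np.inf
    for s in range(n_starts):
        jit = rng.lognormal(0.0, 0.4, size=n_diff) if s else np.ones(n_diff)
        tau0 = np.clip(tau_half * spread * jit, lag_lo, lag_hi)
        theta0 = [amp / n_diff] * n_diff + list(np.log(tau0))
        lb = [0.0] * n_diff + [np.log(lag_lo / 10)] * n_diff
        ub = [np.inf] * n_diff + [np.log(lag_hi * 10)] * n_diff
        if fit_triplet and n_trip > 0:
            theta0 += [0.1] * n_trip + [np.log(max(lag_lo, 1e-7))] * n_trip
            lb += [0.0] * n_trip + [np.log(1e-8)] * n_trip
            ub += [1 - 1e-6] * n_trip + [np.log(tau_half)] * n_trip
        theta0.append(curve.G[-1])
        lb.append(-np.inf)
        ub.append(np.inf)
        try:
            sol = least_squares(residuals, theta0, bounds=(lb, ub),
                                method="trf", max_nfev=4000)
        except ValueError:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    if best is None:
        raise RuntimeError("FCS fit failed from every start")

    rho, tau, T, tau_t, g_inf = unpack(best.x)
    params = FCSModelParams(rho=rho, tau_diff=tau, T=T, tau_trip=tau_t,
                            alpha=alpha_arr, k=k, V_eff=V_eff, G_inf=g_inf,
                            converged=bool(best.success))
    return params.sorted_fast_first()
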