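"""Four-parameter drift-diffusion model of switch response times.

The model describes the firing rate ``x(t)`` of an output unit that
accumulates evidence from striatal medium spiny neurons:

    dx = (F - x) D dt + sigma dxi(t),    x(0) = b

with target input level ``F``, drift rate ``D`` (1/s), noise strength
``sigma``, and baseline ``b``.  A switch response is emitted at the first
time ``t*`` at which ``x`` reaches the threshold

    T(F, b) = (1 - b/4) F + (b/4) (1 - F).

Simulated switch-response-time samples are summarised by two-parameter
gamma fits (shape ``alpha``, rate ``beta``), whose mean ``alpha/beta``
and coefficient of variation ``1/sqrt(alpha)`` are the targets of the
(D, sigma) grid search used to select model parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DDMParams",
    "DDMRun",
    "GammaFit",
    "FitError",
    "compute_threshold",
    "noise_free_crossing_time",
    "simulate_trial",
    "simulate_batch",
    "fit_gamma",
    "gamma_sample_r2",
    "summary_stats",
    "fit_errors",
    "grid_search_params",
    "INTACT_D2",
    "INTACT_D1",
    "DISRUPTED_D2",
    "DISRUPTED_D1",
]


def compute_threshold(F: float, b: float) -> float:
    """Decision threshold T(F, b) = (1 - b/4) F + (b/4) (1 - F).

    ``b`` must lie in [0, 1].  The two published algebraic renderings,
    ``(1 - b/4) F + (b/4)(1 - F)`` and ``F (1 - b/4) + (1 - F) b/4``,
    are identical term by term, so a single expression serves both.
    """
    if not (np.isfinite(F) and np.isfinite(b)):
        raise ValueError("F and b must be finite")
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"baseline b must be in [0, 1], got {b}")
    return (1.0 - b / 4.0) * F + (b / 4.0) * (1.0 - F)


@dataclass(frozen=True)
class DDMParams:
    """Parameters and integration settings for one simulation batch.

    F : target input level (dimensionless, typically 0 or 1)
    D : drift rate (1/s)
    sigma : noise strength (per sqrt(s))
    b : initial value x(0), in [0, 1]
    dt : Euler-Maruyama step (s)
    t_max : per-trial horizon (s)
    n_sims : trials per batch
    seed : RNG seed for the batch
    """

    F: float
    D: float
    sigma: float
    b: float
    dt: float = 0.1
    t_max: float = 25.0
    n_sims: int = 500
    seed: int | None = None
    store_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.n_sims < 1:
            raise ValueError("n_sims must be at least 1")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("b must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def threshold(self) -> float:
        return compute_threshold(self.F, self.b)

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))

    def with_seed(self, seed: int) -> "DDMParams":
        return replace(self, seed=seed)


# Published parameter sets (intact and disrupted pathways).
INTACT_D2 = DDMParams(F=1.0, b=0.52, D=0.135, sigma=0.052)
INTACT_D1 = DDMParams(F=0.0, b=0.48, D=0.141, sigma=0.052)
DISRUPTED_D2 = DDMParams(F=1.0, b=0.52, D=0.129, sigma=0.043)
DISRUPTED_D1 = DDMParams(F=0.0, b=0.48, D=0.122, sigma=0.043)


@dataclass
class DDMRun:
    """Result of a simulated batch.

    ``times`` holds one entry per trial: the crossing time ``t*`` for
    non-censored trials and NaN for trials that never reach threshold
    within ``t_max``.  ``trajectories`` (optional) holds the full sample
    paths on the dt grid, integrated over the whole horizon even after
    the first crossing.
    """

    params: DDMParams
    times: np.ndarray
    censored: np.ndarray
    degenerate: bool = False
    trajectories: np.ndarray | None = None

    @property
    def switch_times(self) -> np.ndarray:
        """Crossing times of non-censored trials only."""
        return self.times[~self.censored]

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())


def noise_free_crossing_time(params: DDMParams) -> float:
    """Closed-form crossing time of the noise-free model.

    With sigma = 0 the path is x(t) = F + (b - F) exp(-D t), which
    reaches T at t* = (1/D) ln(|F - b| / |F - T|).  Serves as the
    analytic oracle for the Euler-Maruyama integrator as dt -> 0.
    """
    if params.D <= 0:
        raise ValueError("noise-free crossing requires D > 0")
    T = params.threshold
    F, b = params.F, params.b
    if b == T:
        return 0.0
    # T must lie strictly between b and F for pure drift to reach it.
    if not (min(b, F) < T < max(b, F)):
        raise ValueError("threshold unreachable under pure drift")
    return math.log(abs(F - b) / abs(F - T)) / params.D


def _integrate(params: DDMParams, rng: np.random.Generator, n: int,
               store: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Vectorised Euler-Maruyama over `n` trials.

    Returns (times, censored, trajectories).  Paths keep evolving after
    their first crossing so downstream consumers see full trajectories.
    """
    T = params.threshold
    upward = T >= params.b
    n_steps = params.n_steps
    dt = params.dt
    sq = params.sigma * math.sqrt(dt)

    x = np.full(n, float(params.b))
    times = np.full(n, np.nan)
    crossed = np.zeros(n, dtype=bool)
    traj = np.empty((n, n_steps + 1)) if store else None
    if store:
        traj[:, 0] = x

    for k in range(1, n_steps + 1):
        x = x + (params.F - x) * params.D * dt + sq * rng.standard_normal(n)
        hit = (x >= T) if upward else (x <= T)
        new = hit & ~crossed
        times[new] = k * dt
        crossed |= new
        if store:
            traj[:, k] = x
    return times, ~crossed, traj


def simulate_trial(params: DDMParams,
                   rng: np.random.Generator | None = None
                   ) -> tuple[np.ndarray, float]:
    """Simulate a single trial; returns (trajectory, t*).

    ``t*`` is NaN if the path never reaches threshold within ``t_max``.
    A start exactly at threshold reports t* = 0 (degenerate crossing).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.b == params.threshold:
        # Degenerate: already at threshold at t = 0.
        times, censored, traj = _integrate(params, rng, 1, True)
        return traj[0], 0.0
    times, censored, traj = _integrate(params, rng, 1, True)
    return traj[0], float(times[0])


def simulate_batch(params: DDMParams) -> DDMRun:
    """Run ``n_sims`` independent trials with a seeded RNG.

    Identical seeds give bit-identical output.  Raises if every trial is
    censored, since no response-time distribution exists in that case.
    """
    rng = np.random.default_rng(params.seed)
    degenerate = params.b == params.threshold
    if degenerate:
        times = np.zeros(params.n_sims)
        censored = np.zeros(params.n_sims, dtype=bool)
        traj = None
        if params.store_trajectories:
            _, _, traj = _integrate(params, rng, params.n_sims, True)
        return DDMRun(params, times, censored, True, traj)
    times, censored, traj = _integrate(params, rng, params.n_sims,
                                       params.store_trajectories)
    if censored.all():
        raise RuntimeError(
            "all trials censored: parameters cannot produce a "
            "switch-response-time distribution within t_max")
    return DDMRun(params, times, censored, False, traj)


@dataclass(frozen=True)
class GammaFit:
    """Two-parameter gamma fit (shape ``alpha``, rate ``beta``)."""

    alpha: float
    beta: float
    n: int
    r2: float | None = None

    @property
    def mu(self) -> float:
        """Implied mean alpha / beta (s)."""
        return self.alpha / self.beta

    @property
    def cv(self) -> float:
        """Implied coefficient of variation 1 / sqrt(alpha)."""
        return 1.0 / math.sqrt(self.alpha)


def fit_gamma(samples: Sequence[float] | np.ndarray) -> GammaFit:
    """Maximum-likelihood gamma fit (no location shift).

    Requires at least 10 positive, finite samples with non-degenerate
    spread; the rate parameterisation beta = 1/scale is reported.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples for a gamma fit")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    if np.any(x <= 0):
        raise ValueError("samples must be strictly positive")
    if np.std(x) < 1e-12 * max(1.0, float(np.mean(x))):
        raise ValueError("near-zero variance: gamma MLE diverges")
    alpha, _, scale = stats.gamma.fit(x, floc=0)
    return GammaFit(alpha=float(alpha), beta=float(1.0 / scale), n=int(x.size))


def gamma_sample_r2(samples: Sequence[float] | np.ndarray,
                    fit: GammaFit,
                    bin_width: float = 0.5,
                    t_max: float = 25.0,
                    method: str = "cdf") -> float:
    """Goodness of fit (R^2) of a gamma fit to a response-time sample.

    ``method="cdf"`` (default) compares the empirical cumulative
    distribution with the fitted gamma CDF at the bin edges, the
    comparison used for the published distribution-function overlays.
    ``method="pdf"`` compares the sample's normalised histogram density
    against the gamma density at bin centres.  Both return
    1 - SS_res / SS_tot.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    hist, _ = np.histogram(x, bins=edges)
    if hist.sum() == 0:
        raise ValueError("all histogram bins empty on [0, t_max]")
    if method == "pdf":
        dens = hist / (hist.sum() * bin_width)
        centers = (edges[:-1] + edges[1:]) / 2.0
        model = stats.gamma.pdf(centers, fit.alpha, scale=1.0 / fit.beta)
        obs = dens
    elif method == "cdf":
        obs = np.cumsum(hist) / x.size
        model = stats.gamma.cdf(edges[1:], fit.alpha, scale=1.0 / fit.beta)
    else:
        raise ValueError(f"unknown method {method!r}")
    ss_res = float(np.sum((obs - model) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total variance in observed distribution")
    return 1.0 - ss_res / ss_tot


def _repeat_seeds(seed: int | None, n: int) -> list[int]:
    """Deterministic per-repeat seeds derived from a base seed."""
    ss = np.random.SeedSequence(0 if seed is None else seed)
    return [int(s) for s in ss.generate_state(n)]


def summary_stats(params: DDMParams, n_repeats: int = 10
                  ) -> tuple[float, float]:
    """Group-median (mu_S, CV_S) over repeated 500-trial experiments.

    Each repeat is one ``simulate_batch``; mu_S and CV_S are the medians
    across repeats of the per-repeat sample mean and sample CV of the
    non-censored switch times.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    mus, cvs = [], []
    for s in _repeat_seeds(params.seed, n_repeats):
        run = simulate_batch(params.with_seed(s))
        ts = run.switch_times
        m = float(ts.mean())
        mus.append(m)
        cvs.append(float(ts.std(ddof=1) / m) if ts.size > 1 else 0.0)
    return float(np.median(mus)), float(np.median(cvs))


@dataclass(frozen=True)
class FitError:
    """Relative mean error and absolute CV error against targets."""

    mu_S: float
    cv_S: float
    e_mu: float
    e_cv: float
    accepted: bool


# Acceptance bounds for the (D, sigma) selection.
E_MU_MAX = 0.05
E_CV_MAX = 0.02


def fit_errors(mu_S: float, cv_S: float, mu_M: float, cv_M: float) -> FitError:
    """E_mu = |(mu_S - mu_M)/mu_M| and E_cv = |CV_S - CV_M|.

    A parameter pair is accepted whenever E_mu <= 0.05 and E_cv <= 0.02
    (inclusive bounds).
    """
    if mu_M <= 0:
        raise ValueError("target mean mu_M must be positive")
    e_mu = abs((mu_S - mu_M) / mu_M)
    e_cv = abs(cv_S - cv_M)
    return FitError(mu_S=mu_S, cv_S=cv_S, e_mu=e_mu, e_cv=e_cv,
                    accepted=(e_mu <= E_MU_MAX and e_cv <= E_CV_MAX))


DEFAULT_D_GRID = np.round(np.arange(0.05, 0.25 + 1e-9, 0.002), 6)
DEFAULT_SIGMA_GRID = np.round(np.arange(0.02, 0.10 + 1e-9, 0.002), 6)


def grid_search_params(F: float,
                       b: float,
                       D_grid: Sequence[float],
                       sigma_grid: Sequence[float],
                       mu_M: float,
                       cv_M: float,
                       base_seed: int = 0,
                       n_repeats: int = 10,
                       n_sims: int = 500,
                       dt: float = 0.1,
                       t_max: float = 25.0) -> pd.DataFrame:
    """Error surfaces E_mu(D, sigma) and E_cv(D, sigma) over a grid.

    Each cell runs ``summary_stats`` with a seed derived from
    (base_seed, cell index), so surfaces are reproducible regardless of
    evaluation order.  An empty accepted region is a valid outcome.
    Cells whose batches are entirely censored are marked not accepted
    with NaN errors.
    """
    D_grid = np.asarray(D_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if D_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if mu_M <= 0 or cv_M <= 0:
        raise ValueError("targets must be positive")
    rows = []
    for i, D in enumerate(D_grid):
        for j, sigma in enumerate(sigma_grid):
            cell_seed = int(np.random.SeedSequence(
                [base_seed, i, j]).generate_state(1)[0])
            p = DDMParams(F=F, b=b, D=float(D), sigma=float(sigma), dt=dt,
                          t_max=t_max, n_sims=n_sims, seed=cell_seed)
            try:
                mu_S, cv_S = summary_stats(p, n_repeats=n_repeats)
                err = fit_errors(mu_S, cv_S, mu_M, cv_M)
                rows.append((D, sigma, err.e_mu, err.e_cv, err.accepted))
            except RuntimeError:
                rows.append((D, sigma, np.nan, np.nan, False))
    return pd.DataFrame(rows,
                        columns=["D", "sigma", "e_mu", "e_cv", "accepted"])
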