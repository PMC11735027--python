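"""Synthetic behavioral sessions and spike-train ensembles.

Everything downstream of the raw recordings — switch-time extraction,
PETH/PCA, GLM slopes, temporal decoding, the ensemble readout — is
exercised here on generated data with the statistical structure the
analyses assume: gamma-distributed switch response times, trial-gated
linear ramping of MSN firing over the 0-6 s interval, Poisson spiking
in the 0.5-20 Hz band, short-latency opto-tagging responses, and
ensembles whose weighted, kernel-smoothed activity crosses a fixed
level at the trial's switch time.

All generators draw from explicit seeds; identical spec + seed gives
identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .ddm import DDMParams, DDMRun

__all__ = [
    "SynthBehaviorSpec",
    "SynthUnitSpec",
    "SynthEnsembleSpec",
    "EnsembleData",
    "gen_switch_times",
    "gen_event_log",
    "gen_ramping_unit",
    "gen_unit_population",
    "gen_ensemble_ddm_linked",
    "gen_poisson_matched_surrogate",
    "gen_tagging_responses",
    "gen_blockade_ensemble",
]


@dataclass(frozen=True)
class SynthBehaviorSpec:
    """Behavioral session generator settings.

    Switch response times are gamma(shape, rate) draws; the defaults
    match the model-derived fits (shape 6.08, rate 0.69 /s).  Half of
    the trials are 18-s "switch" trials; 6-s trials are generated but
    flagged, mirroring the task in which they are not analysed.
    """

    n_trials: int = 100
    gamma_shape: float = 6.08
    gamma_rate: float = 0.69
    p_long: float = 0.5
    iti_geometric_mean_s: float = 30.0
    nosepoke_duration_median_s: float = 1.2
    traversal_median_s: float = 1.0
    p_extra_bout: float = 0.3
    laser_fraction: float = 0.0
    laser_shift_s: float = 0.0
    mouse_id: str = "m01"
    session_id: str = "s01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValueError("gamma parameters must be positive")
        if not 0.0 <= self.p_long <= 1.0:
            raise ValueError("p_long must be in [0, 1]")
        if not 0.0 <= self.laser_fraction <= 1.0:
            raise ValueError("laser_fraction must be in [0, 1]")


def gen_switch_times(spec: SynthBehaviorSpec,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """I.i.d. gamma(shape, rate) switch times for the long trials."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_long = int(round(spec.n_trials * spec.p_long))
    return rng.gamma(spec.gamma_shape, 1.0 / spec.gamma_rate, size=n_long)


def gen_event_log(spec: SynthBehaviorSpec,
                  switch_times: np.ndarray | None = None) -> pd.DataFrame:
    """Emit a tidy event log (one event per row, trial-relative times).

    Long trials carry: trial_start, optional earlier first-nosepoke
    bouts, a final first-nosepoke bout whose exit is exactly the switch
    time, a second-nosepoke entry after a log-normal traversal gap, and
    a reward at max(18 s, second entry).  Short (6-s) trials are emitted
    with trial_type "short" and are excluded downstream.
    """
    rng = np.random.default_rng(spec.seed)
    n_long = int(round(spec.n_trials * spec.p_long))
    if switch_times is None:
        switch_times = gen_switch_times(spec, rng)
    switch_times = np.asarray(switch_times, dtype=float)
    if switch_times.size != n_long:
        raise ValueError("need one switch time per long trial")
    if np.any(switch_times <= 0):
        raise ValueError("switch times must be positive")

    # Interleave long/short trials in a seeded random order.
    kinds = np.array(["long"] * n_long + ["short"] * (spec.n_trials - n_long))
    rng.shuffle(kinds)
    laser = rng.random(spec.n_trials) < spec.laser_fraction

    rows = []
    i_long = 0
    log_sd = 0.4
    for trial_id, kind in enumerate(kinds):
        add = lambda ev, t: rows.append(
            (spec.mouse_id, spec.session_id, trial_id, kind, ev, float(t)))
        add("trial_start", 0.0)
        if laser[trial_id]:
            add("laser_on", 0.0)
        if kind == "short":
            t_in = 6.0 + rng.exponential(0.5)
            add("first_np_in", t_in)
            add("reward", t_in)
            add("first_np_out", t_in + rng.exponential(0.5))
            continue
        t_switch = float(switch_times[i_long])
        if laser[trial_id]:
            t_switch += spec.laser_shift_s
        i_long += 1
        # Final switch bout: entry strictly before the exit at t_switch.
        dur = min(spec.nosepoke_duration_median_s
                  * math.exp(log_sd * rng.standard_normal()),
                  0.9 * t_switch)
        t_entry = t_switch - dur
        if rng.random() < spec.p_extra_bout and t_entry > 1.0:
            e_in = rng.uniform(0.2, 0.7) * t_entry
            e_out = e_in + rng.uniform(0.1, 0.9) * (t_entry - e_in)
            add("first_np_in", e_in)
            add("first_np_out", e_out)
        add("first_np_in", t_entry)
        add("first_np_out", t_switch)
        gap = spec.traversal_median_s * math.exp(log_sd * rng.standard_normal())
        t_second = t_switch + gap
        add("second_np_in", t_second)
        add("reward", max(18.0, t_second))
        add("second_np_out", max(18.0, t_second) + rng.exponential(0.5))
        if laser[trial_id]:
            add("laser_off", 18.0)
    df = pd.DataFrame(rows, columns=["mouse_id", "session_id", "trial_id",
                                     "trial_type", "event_type", "time_s"])
    return df.sort_values(["trial_id", "time_s"],
                          kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class SynthUnitSpec:
    """One synthetic unit: baseline Poisson rate plus a trial-gated ramp.

    ``ramp_slope`` is in spikes/s per s over the 0-6 s interval after
    each trial start (sign encodes up- vs down-ramping, at the scale of
    the reported per-unit GLM slopes).  ``trial_gain_noise`` is the SD
    of a multiplicative log-normal per-trial gain.
    """

    unit_id: str = "u001"
    baseline_rate: float = 5.0
    ramp_slope: float = 0.0
    trial_gain_noise: float = 0.1
    tagged: bool = False
    tag_latency_ms: float = 2.0
    peak_trough_ratio: float = 1.5
    half_peak_width_ms: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        if self.tag_latency_ms < 0:
            raise ValueError("tag_latency_ms must be non-negative")


def gen_ramping_unit(spec: SynthUnitSpec,
                     trial_starts: np.ndarray,
                     horizon: float,
                     ramp_interval: tuple[float, float] = (0.0, 6.0)
                     ) -> np.ndarray:
    """Inhomogeneous-Poisson spikes for one unit over a session.

    The rate is ``max(0, baseline + slope * t_in_interval)`` during the
    ramp interval of every trial and baseline elsewhere, scaled by a
    per-trial gain.  Sampling is by thinning against the session rate
    maximum, which is exact for this piecewise-linear rate.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    rng = np.random.default_rng(spec.seed)
    starts = np.sort(np.asarray(trial_starts, dtype=float))
    a, bnd = ramp_interval
    gains = np.exp(spec.trial_gain_noise * rng.standard_normal(starts.size)
                   - 0.5 * spec.trial_gain_noise ** 2)

    def rate(t: np.ndarray) -> np.ndarray:
        r = np.full(t.shape, spec.baseline_rate)
        idx = np.searchsorted(starts, t, side="right") - 1
        ok = idx >= 0
        rel = np.where(ok, t - starts[np.clip(idx, 0, None)], -1.0)
        in_ramp = ok & (rel >= a) & (rel < bnd)
        r[in_ramp] = np.maximum(
            0.0, spec.baseline_rate + spec.ramp_slope * rel[in_ramp])
        gain = np.where(ok, gains[np.clip(idx, 0, None)], 1.0)
        return r * gain

    r_max = (spec.baseline_rate
             + max(0.0, spec.ramp_slope * (bnd - a))) * float(gains.max()
                                                              if gains.size
                                                              else 1.0)
    r_max = max(r_max, 1e-9)
    n_cand = rng.poisson(r_max * horizon)
    cand = np.sort(rng.uniform(0.0, horizon, n_cand))
    keep = rng.random(n_cand) < rate(cand) / r_max
    return cand[keep]


def gen_unit_population(n_msn: int,
                        n_fsi: int = 0,
                        slope_range: tuple[float, float] = (-0.5, 0.5),
                        baseline_range: tuple[float, float] = (2.0, 15.0),
                        seed: int = 0) -> list[SynthUnitSpec]:
    """A mixed population of unit specs with MSN- and FSI-like waveforms.

    MSNs get wide half-peak widths and mixed up/down ramp slopes; FSIs
    get narrow waveforms, high rates, and no ramp.
    """
    rng = np.random.default_rng(seed)
    units = []
    for i in range(n_msn):
        units.append(SynthUnitSpec(
            unit_id=f"msn{i:03d}",
            baseline_rate=float(rng.uniform(*baseline_range)),
            ramp_slope=float(rng.uniform(*slope_range)),
            peak_trough_ratio=float(rng.normal(1.6, 0.15)),
            half_peak_width_ms=float(rng.normal(0.32, 0.04)),
            seed=int(rng.integers(2 ** 31)),
        ))
    for i in range(n_fsi):
        units.append(SynthUnitSpec(
            unit_id=f"fsi{i:03d}",
            baseline_rate=float(rng.uniform(8.0, 19.0)),
            ramp_slope=0.0,
            peak_trough_ratio=float(rng.normal(0.9, 0.1)),
            half_peak_width_ms=float(rng.normal(0.12, 0.02)),
            seed=int(rng.integers(2 ** 31)),
        ))
    return units


def gen_blockade_ensemble(units: list[SynthUnitSpec],
                          slope_shrink: float) -> list[SynthUnitSpec]:
    """Shrink every unit's ramp slope toward flat (blockade-like shift)."""
    if not 0.0 <= slope_shrink <= 1.0:
        raise ValueError("slope_shrink must be in [0, 1]")
    return [replace(u, ramp_slope=u.ramp_slope * slope_shrink)
            for u in units]


def gen_tagging_responses(units: list[SynthUnitSpec],
                          n_pulses: int,
                          pulse_start_s: float = 0.0,
                          pulse_interval_s: float = 1.0,
                          latency_sd_ms: float = 0.5,
                          seed: int = 0
                          ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Photostimulation pulse times and light-evoked spikes.

    Tagged units emit one evoked spike per pulse at a latency drawn from
    a positive-truncated normal around their mean tag latency; untagged
    units emit nothing in response to light.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be at least 1")
    rng = np.random.default_rng(seed)
    pulses = pulse_start_s + np.arange(n_pulses) * pulse_interval_s
    evoked: dict[str, np.ndarray] = {}
    for u in units:
        if not u.tagged:
            evoked[u.unit_id] = np.array([])
            continue
        lat = rng.normal(u.tag_latency_ms, latency_sd_ms, n_pulses)
        lat = np.abs(lat) + 1e-3  # reflect at zero: latencies are positive
        evoked[u.unit_id] = np.sort(pulses + lat / 1000.0)
    return pulses, evoked


@dataclass(frozen=True)
class SynthEnsembleSpec:
    """DDM-linked ensemble generator settings.

    Per-unit instantaneous rates are affine in a trial-specific
    accumulation signal: a blend (``ramp_mix``) of the trial's realised
    DDM trajectory, mapped to threshold progress, and the trial's
    normalised elapsed-time ramp, raised to ``link_power``.  The drive
    is deconvolved against the 1-s exponential readout kernel so that
    the ``beta``-weighted, kernel-convolved ensemble activity crosses
    0.5 at the trial's switch time by construction.
    """

    n_units: int = 16
    n_trials: int = 40
    gain: float = 20.0
    base_lo: float = 1.0
    link_power: float = 2.0
    ramp_mix: float = 0.5
    smooth_s: float = 0.5
    kernel_w: float = 1.0
    horizon: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("need at least 2 units")
        if self.kernel_w <= 0:
            raise ValueError("kernel width must be positive")
        if not 0.0 <= self.ramp_mix <= 1.0:
            raise ValueError("ramp_mix must be in [0, 1]")


@dataclass
class EnsembleData:
    """Per-trial, per-unit spike trains with ground truth.

    ``spikes[i][j]`` holds unit ``j``'s spike times (s, trial-relative)
    on trial ``i``; ``t_star`` the true switch times; ``beta`` the
    generator's readout weights; ``rates``/``grid`` the underlying rate
    functions used to emit spikes (for surrogates and invariants).
    """

    spikes: list[list[np.ndarray]]
    t_star: np.ndarray
    horizon: float
    beta: np.ndarray | None = None
    rates: np.ndarray | None = None
    grid: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    @property
    def n_units(self) -> int:
        return len(self.spikes[0]) if self.spikes else 0

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, j, t) for i, tr in enumerate(self.spikes)
                for j, st in enumerate(tr) for t in st]
        return pd.DataFrame(rows, columns=["trial", "unit", "time_s"])


def _spikes_from_rates(rates: np.ndarray, dt: float,
                       rng: np.random.Generator) -> list[list[np.ndarray]]:
    """Poisson spikes from piecewise-constant rates (trials, units, bins)."""
    n_tr, n_units, n_bins = rates.shape
    counts = rng.poisson(rates * dt)
    out = []
    for i in range(n_tr):
        trial = []
        for j in range(n_units):
            c = counts[i, j]
            tot = int(c.sum())
            if tot == 0:
                trial.append(np.array([]))
                continue
            t = np.repeat(np.arange(n_bins) * dt, c) + rng.uniform(0, dt, tot)
            trial.append(np.sort(t))
        out.append(trial)
    return out


def gen_ensemble_ddm_linked(spec: SynthEnsembleSpec,
                            ddm_run: DDMRun) -> EnsembleData:
    """Spike-train ensembles whose readout encodes the DDM crossing.

    For each non-censored trial the accumulation signal

        y(t) = 0.5 * ((1 - m) * p(t) + m * min(t / t*, cap)) ** q

    with threshold progress p(t) = (x(t) - b) / (T - b), ramp mix ``m``
    and link power ``q``, is smoothed, offset so y(t*) = 0.5 exactly,
    and deconvolved against the exponential readout kernel to give the
    common rate drive h(t).  Unit rates are a_j + c_j h(t) with mixed
    signs of c_j; the weights ``beta`` solve beta@c = 1, beta@a = 0 with
    minimum norm, so the expected kernel-convolved weighted sum equals
    y(t) on the grid and crosses 0.5 at t*.
    """
    if ddm_run.trajectories is None:
        raise ValueError("DDM run must be simulated with store_trajectories")
    params = ddm_run.params
    dt = params.dt
    rng = np.random.default_rng(spec.seed)

    keep = (~ddm_run.censored) & (ddm_run.times <= spec.horizon - 1.0)
    if keep.sum() < 2:
        raise ValueError("too few usable (non-censored, in-horizon) trials")
    idx = np.flatnonzero(keep)[:spec.n_trials]
    X = ddm_run.trajectories[idx]
    t_star = ddm_run.times[idx]
    n_tr = idx.size

    T = params.threshold
    cap = 1.15
    p = np.clip((X - params.b) / (T - params.b), 0.0, cap)
    tgrid = np.arange(X.shape[1]) * dt
    ramp = np.minimum(tgrid[None, :] / t_star[:, None], cap)
    y = 0.5 * ((1 - spec.ramp_mix) * p
               + spec.ramp_mix * ramp) ** spec.link_power
    ys = gaussian_filter1d(y, spec.smooth_s / dt, axis=1, mode="nearest")
    ki = np.rint(t_star / dt).astype(int)
    ys += (0.5 - ys[np.arange(n_tr), ki])[:, None]  # pin y(t*) = 0.5

    # Discrete deconvolution against K(t) = w exp(-t/w): the causal
    # convolution of h with K on the dt grid reproduces ys exactly.
    w = spec.kernel_w
    decay = math.exp(-dt / w)
    h = (ys[:, 1:] - decay * ys[:, :-1]) / (w * decay * dt)

    N = spec.n_units
    sgn = np.tile([1.0, -1.0], (N + 1) // 2)[:N]
    a = np.where(sgn > 0, spec.base_lo,
                 spec.base_lo + spec.gain * 0.75) + rng.uniform(0, 2, N)
    c = sgn * spec.gain
    A = np.vstack([c, a])
    beta = A.T @ np.linalg.solve(A @ A.T, np.array([1.0, 0.0]))

    n_bins = int(round(spec.horizon / dt))
    rates = np.clip(a[None, :, None] + c[None, :, None] * h[:, None, :n_bins],
                    0.0, None)
    spikes = _spikes_from_rates(rates, dt, rng)
    grid = np.arange(1, n_bins + 1) * dt
    return EnsembleData(spikes=spikes, t_star=t_star, horizon=spec.horizon,
                        beta=beta, rates=rates, grid=grid)


def gen_poisson_matched_surrogate(ens: EnsembleData,
                                  seed: int = 0) -> EnsembleData:
    """Homogeneous-Poisson surrogate with matched trial-average rates.

    Each unit's spikes on each trial are replaced by a homogeneous
    Poisson train whose rate equals that unit's observed trial-average
    rate; all within-trial temporal structure is destroyed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for trial in ens.spikes:
        new_trial = []
        for st in trial:
            rate = len(st) / ens.horizon
            n = rng.poisson(rate * ens.horizon)
            new_trial.append(np.sort(rng.uniform(0, ens.horizon, n)))
        out.append(new_trial)
    return EnsembleData(spikes=out, t_star=ens.t_star.copy(),
                        horizon=ens.horizon, beta=None,
                        rates=None, grid=ens.grid)
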