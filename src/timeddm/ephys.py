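"""Unit selection, tagging, PETHs, ensemble PCA, and GLM ramp slopes.

Analysis chain for striatal single-unit recordings during interval
timing: units firing 0.5-20 Hz are kept; putative MSNs are separated
from fast-spiking interneurons by hierarchical clustering of waveform
shape; opto-tagged units are identified by short-latency (<= 5 ms)
light-evoked spikes with conserved waveforms; peri-event time
histograms (0.2-s bins, Gaussian kernel bandwidth 1 s, z-scored) feed a
PCA whose first component captures time-dependent ramping; per-unit
ramp slopes come from trial-by-trial GLMs of firing rate against time
in the interval with a nosepoke regressor for movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA as _SKPCA

__all__ = [
    "UnitRecording",
    "PETHConfig",
    "PETH",
    "PCAResult",
    "TagResult",
    "RampFit",
    "select_units",
    "classify_msn_fsi",
    "tag_units",
    "compute_peth",
    "pca_ensemble",
    "pc1_random_baseline",
    "glm_ramp_slope",
    "epoch_activity_compare",
]

TAG_LATENCY_MAX_MS = 5.0
TAG_CORR_MIN = 0.9
RATE_MIN_HZ = 0.5
RATE_MAX_HZ = 20.0


@dataclass
class UnitRecording:
    """Spike times plus waveform features for one recorded unit."""

    unit_id: str
    spike_times_s: np.ndarray
    mean_rate_hz: float | None = None
    peak_trough_ratio: float | None = None
    half_peak_width_ms: float | None = None
    waveform: np.ndarray | None = None
    evoked_waveform: np.ndarray | None = None
    mouse_id: str = ""
    session_id: str = ""
    condition: str = "none"

    def __post_init__(self) -> None:
        self.spike_times_s = np.sort(np.asarray(self.spike_times_s, float))

    def rate_over(self, span_s: float) -> float:
        if self.mean_rate_hz is not None:
            return self.mean_rate_hz
        return self.spike_times_s.size / span_s if span_s > 0 else 0.0


def select_units(units: list[UnitRecording],
                 session_span_s: float | None = None) -> list[UnitRecording]:
    """Keep units firing between 0.5 and 20 Hz (inclusive) over the session."""
    out = []
    for u in units:
        rate = (u.mean_rate_hz if u.mean_rate_hz is not None
                else u.rate_over(session_span_s or 0.0))
        if RATE_MIN_HZ <= rate <= RATE_MAX_HZ:
            out.append(u)
    return out


def classify_msn_fsi(units: list[UnitRecording]) -> dict[str, str]:
    """Two-cluster split of waveform features into MSN vs FSI labels.

    Ward hierarchical clustering on standardised (peak-to-trough ratio,
    half-peak width); by convention the cluster with the larger median
    half-peak width is the MSN cluster, since interneuron waveforms are
    narrow.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 units to cluster")
    feats = np.array([[u.peak_trough_ratio, u.half_peak_width_ms]
                      for u in units], dtype=float)
    if np.any(~np.isfinite(feats)):
        raise ValueError("all units need both waveform features")
    sd = feats.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("all waveform features identical: single cluster")
    z = (feats - feats.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    labels = fcluster(linkage(z, method="ward"), 2, criterion="maxclust")
    widths = feats[:, 1]
    med1 = np.median(widths[labels == 1])
    med2 = np.median(widths[labels == 2])
    msn_cluster = 1 if med1 >= med2 else 2
    return {u.unit_id: ("MSN" if lab == msn_cluster else "FSI")
            for u, lab in zip(units, labels)}


@dataclass(frozen=True)
class TagResult:
    unit_id: str
    mean_latency_ms: float
    waveform_corr_ratio: float
    tagged: bool
    n_responses: int


def tag_units(units: list[UnitRecording],
              pulse_times: np.ndarray,
              window_ms: float = 10.0,
              default_corr: float = 1.0) -> list[TagResult]:
    """Opto-tagging classification from post-pulse first-spike latencies.

    For each pulse, the first spike within the search window counts as
    the evoked response; a unit is tagged when its mean latency is
    <= 5 ms and its stimulated-to-unstimulated waveform correlation
    ratio exceeds 0.9 (both inclusive of the latency bound).  Units with
    no waveforms use ``default_corr``.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    win = window_ms / 1000.0
    out = []
    for u in units:
        st = u.spike_times_s
        lats = []
        for p in pulse_times:
            i = np.searchsorted(st, p, side="right")
            if i < st.size and st[i] - p <= win:
                lats.append((st[i] - p) * 1000.0)
        if not lats:
            out.append(TagResult(u.unit_id, np.nan, default_corr, False, 0))
            continue
        mean_lat = float(np.mean(lats))
        if u.waveform is not None and u.evoked_waveform is not None:
            corr = float(np.corrcoef(u.waveform, u.evoked_waveform)[0, 1])
        else:
            corr = default_corr
        # small epsilon keeps the inclusive <= 5 ms bound robust to
        # floating-point representation of latencies
        tagged = (mean_lat <= TAG_LATENCY_MAX_MS + 1e-9
                  and corr > TAG_CORR_MIN)
        out.append(TagResult(u.unit_id, mean_lat, corr, tagged, len(lats)))
    return out


@dataclass(frozen=True)
class PETHConfig:
    """Peri-event time histogram settings.

    ``bandwidth`` is the Gaussian smoothing kernel SD in seconds (the
    same units as the time axis); the default window (-4, 22) s with
    0.2-s bins yields 130 bins.
    """

    window: tuple[float, float] = (-4.0, 22.0)
    bin_width: float = 0.2
    bandwidth: float = 1.0
    zscore: bool = True
    analysis_interval: tuple[float, float] = (0.0, 6.0)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        lo, hi = self.window
        a, b = self.analysis_interval
        if not (lo <= a < b <= hi):
            raise ValueError("window must cover the analysis interval")

    @property
    def bin_edges(self) -> np.ndarray:
        lo, hi = self.window
        n = int(round((hi - lo) / self.bin_width))
        return lo + np.arange(n + 1) * self.bin_width

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return (e[:-1] + e[1:]) / 2.0


@dataclass
class PETH:
    """Trial-averaged smoothed (optionally z-scored) firing-rate curve."""

    unit_id: str
    bin_centers_s: np.ndarray
    rate: np.ndarray
    raw_counts: np.ndarray
    n_trials: int
    zscored: bool
    flat: bool = False


def compute_peth(spike_times_s: np.ndarray,
                 trial_starts: np.ndarray,
                 config: PETHConfig = PETHConfig(),
                 unit_id: str = "") -> PETH:
    """Align, bin, average, smooth, and optionally z-score a spike train.

    Counts are binned per trial around trial start, summed across
    trials (``raw_counts`` conserves the total in-window spike count),
    converted to a trial-averaged rate, then smoothed with a Gaussian
    kernel of SD ``bandwidth`` seconds.  Empty spike trains are returned
    flat with the z-score flagged undefined.
    """
    trial_starts = np.asarray(trial_starts, dtype=float)
    if trial_starts.size == 0:
        raise ValueError("need at least one trial")
    st = np.asarray(spike_times_s, dtype=float)
    edges = config.bin_edges
    counts = np.zeros(edges.size - 1)
    for t0 in trial_starts:
        c, _ = np.histogram(st - t0, bins=edges)
        counts += c
    rate = counts / (trial_starts.size * config.bin_width)
    if config.bandwidth > 0:
        rate = gaussian_filter1d(rate, config.bandwidth / config.bin_width,
                                 mode="nearest")
    flat = False
    if config.zscore:
        sd = rate.std()
        if sd == 0:
            flat = True
        else:
            rate = (rate - rate.mean()) / sd
    return PETH(unit_id=unit_id, bin_centers_s=config.bin_centers,
                rate=rate, raw_counts=counts,
                n_trials=trial_starts.size, zscored=config.zscore, flat=flat)


@dataclass
class PCAResult:
    components: np.ndarray          # (n_pc, n_bins) time-course loadings
    explained_fraction: np.ndarray  # (n_pc,)
    scores: np.ndarray              # (n_units, n_pc)
    bin_centers_s: np.ndarray
    baseline: np.ndarray | None = None
    p_empirical: float | None = None


def _interval_mask(bin_centers: np.ndarray,
                   interval: tuple[float, float]) -> np.ndarray:
    a, b = interval
    return (bin_centers >= a) & (bin_centers < b)


def pca_ensemble(peths: list[PETH],
                 analysis_interval: tuple[float, float] = (0.0, 6.0)
                 ) -> PCAResult:
    """PCA across units of PETH segments over the analysis interval.

    Units are observations, time bins variables.  The sign of each
    component is fixed so its linear trend over the interval is
    non-positive; with a down-trending PC1, up-ramping units score
    negative (the D2-MSN pattern) and down-ramping units positive.
    """
    if len(peths) < 2:
        raise ValueError("need at least 2 units for PCA")
    mask = _interval_mask(peths[0].bin_centers_s, analysis_interval)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 bins in the analysis interval")
    M = np.array([p.rate[mask] for p in peths])
    if np.allclose(M.var(axis=0), 0):
        raise ValueError("zero variance across units: PCA undefined")
    n_pc = min(M.shape)
    pca = _SKPCA(n_components=n_pc)
    scores = pca.fit_transform(M)
    comps = pca.components_.copy()
    centers = peths[0].bin_centers_s[mask]
    tt = centers - centers.mean()
    for k in range(n_pc):
        if float(tt @ comps[k]) > 0:  # trend must be downward
            comps[k] = -comps[k]
            scores[:, k] = -scores[:, k]
    return PCAResult(components=comps,
                     explained_fraction=pca.explained_variance_ratio_,
                     scores=scores, bin_centers_s=centers)


def pc1_random_baseline(units_spikes: list[np.ndarray],
                        trial_starts: np.ndarray,
                        session_span_s: float,
                        config: PETHConfig = PETHConfig(),
                        analysis_interval: tuple[float, float] = (0.0, 6.0),
                        n_iter: int = 1000,
                        seed: int = 0) -> PCAResult:
    """Empirical null for the PC1 explained fraction.

    Each iteration replaces every unit's spikes by uniform random
    timestamps over the session (identical spike counts), reruns the
    identical PETH + PCA pipeline, and records the PC1 explained
    fraction; p_empirical is the fraction of iterations at or above the
    observed value.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)
    peths = [compute_peth(st, trial_starts, config, unit_id=str(i))
             for i, st in enumerate(units_spikes)]
    obs = pca_ensemble(peths, analysis_interval)
    counts = [st.size for st in units_spikes]
    null = np.empty(n_iter)
    for it in range(n_iter):
        surr = [compute_peth(rng.uniform(0, session_span_s, n),
                             trial_starts, config) for n in counts]
        try:
            null[it] = pca_ensemble(surr,
                                    analysis_interval).explained_fraction[0]
        except ValueError:
            null[it] = 0.0
    p = float(np.mean(null >= obs.explained_fraction[0]))
    return PCAResult(components=obs.components,
                     explained_fraction=obs.explained_fraction,
                     scores=obs.scores, bin_centers_s=obs.bin_centers_s,
                     baseline=null, p_empirical=p)


@dataclass(frozen=True)
class RampFit:
    unit_id: str
    slope: float            # spikes/s per s over the interval
    intercept: float
    nosepoke_beta: float | None
    variant: str
    n_obs: int


def glm_ramp_slope(spike_times_s: np.ndarray,
                   trial_starts: np.ndarray,
                   nosepoke_times_s: np.ndarray | None = None,
                   switch_times_s: np.ndarray | None = None,
                   interval: tuple[float, float] = (0.0, 6.0),
                   bin_width: float = 0.2,
                   variant: str = "full_interval",
                   unit_id: str = "") -> RampFit:
    """Trial-by-trial GLM ramp slope of firing rate vs time in interval.

    Observations are (trial, bin) firing rates over the interval after
    each trial start, pooled across trials and fit with an identity-link
    Gaussian GLM: rate ~ time + nosepoke count per bin.  The nosepoke
    regressor is dropped when no nosepokes fall in the interval on any
    trial.  Variants: "outlier_excluded" refits after dropping
    observations outside the 95% prediction interval; "to_switch" ends
    each trial's observations at that trial's switch response time.
    """
    trial_starts = np.asarray(trial_starts, dtype=float)
    st = np.asarray(spike_times_s, dtype=float)
    a, b = interval
    edges = a + np.arange(int(round((b - a) / bin_width)) + 1) * bin_width
    centers = (edges[:-1] + edges[1:]) / 2.0

    rates, times, pokes = [], [], []
    for i, t0 in enumerate(trial_starts):
        if variant == "to_switch":
            if switch_times_s is None:
                raise ValueError("to_switch variant needs switch times")
            end = min(b, float(switch_times_s[i]))
        else:
            end = b
        keep = centers < end
        if not keep.any():
            continue
        c, _ = np.histogram(st - t0, bins=edges)
        rates.append(c[keep] / bin_width)
        times.append(centers[keep])
        if nosepoke_times_s is not None:
            pc, _ = np.histogram(np.asarray(nosepoke_times_s) - t0,
                                 bins=edges)
            pokes.append(pc[keep])
    y = np.concatenate(rates)
    t = np.concatenate(times)
    if np.unique(t).size < 2:
        raise ValueError("fewer than 2 distinct time bins")
    cols = {"time_s": t}
    use_pokes = bool(pokes) and np.concatenate(pokes).sum() > 0
    if use_pokes:
        cols["nosepokes"] = np.concatenate(pokes)
    X = sm.add_constant(pd.DataFrame(cols))
    res = sm.OLS(y, X).fit()
    if variant == "outlier_excluded":
        pred = res.get_prediction(X).summary_frame(alpha=0.05)
        keep = ((y >= pred["obs_ci_lower"].to_numpy())
                & (y <= pred["obs_ci_upper"].to_numpy()))
        res = sm.OLS(y[keep], X.loc[keep]).fit()
        n_obs = int(keep.sum())
    else:
        n_obs = y.size
    return RampFit(unit_id=unit_id,
                   slope=float(res.params["time_s"]),
                   intercept=float(res.params["const"]),
                   nosepoke_beta=(float(res.params["nosepokes"])
                                  if use_pokes else None),
                   variant=variant, n_obs=n_obs)


def epoch_activity_compare(peths: list[PETH],
                           groups: list[str],
                           early: tuple[float, float] = (0.0, 5.0),
                           late: tuple[float, float] = (5.0, 6.0)
                           ) -> pd.DataFrame:
    """Per-unit mean activity in early/late epochs with a group contrast.

    Returns one row per epoch with the two group means, a rank-sum
    p-value, and Cohen's d; raises if an epoch contains no bins.
    """
    if len(peths) != len(groups):
        raise ValueError("one group label per PETH required")
    from .behavior import cohens_d
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    rows = []
    for name, epoch in [("early", early), ("late", late)]:
        mask = _interval_mask(peths[0].bin_centers_s, epoch)
        if not mask.any():
            raise ValueError(f"no bins in {name} epoch {epoch}")
        means = np.array([p.rate[mask].mean() for p in peths])
        g0 = means[np.array(groups) == labels[0]]
        g1 = means[np.array(groups) == labels[1]]
        p = float(stats.mannwhitneyu(g0, g1).pvalue) if (
            g0.size and g1.size) else np.nan
        rows.append((name, epoch[0], epoch[1], g0.mean(), g1.mean(),
                     cohens_d(g0, g1), p))
    return pd.DataFrame(rows, columns=["epoch", "start_s", "end_s",
                                       f"mean_{labels[0]}",
                                       f"mean_{labels[1]}",
                                       "cohens_d", "p_value"])
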