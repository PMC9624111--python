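"""Ensemble statistics: bursts, noise decomposition, cross-correlation,
toggle stability, and ensemble summaries.

All routines operate on plain arrays / the trajectory tables produced by
:mod:`supertx.dynamics`, and are independent of how the underlying runs
were generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

#: Default burst threshold, s: a burst ends once this long passes without a
#: new polymerase loading.  20/60 s give qualitatively identical contrasts;
#: 10 s is too short and shreds bursts.
BURST_THRESHOLD = 30.0
BURST_THRESHOLD_PRESETS = (10.0, 20.0, 30.0, 60.0)


@dataclass
class BurstSummary:
    """Burst sizes (polymerases per burst) and the gaps separating bursts."""

    burst_sizes: List[int]
    inter_burst_times: List[float]
    threshold: float

    @property
    def n_events(self) -> int:
        return sum(self.burst_sizes)

    @property
    def mean_size(self) -> float:
        return float(np.mean(self.burst_sizes)) if self.burst_sizes else math.nan

    @property
    def mean_inter_burst(self) -> float:
        return float(np.mean(self.inter_burst_times)) if self.inter_burst_times else math.nan


def detect_bursts(initiation_times: Sequence[float], threshold: float = BURST_THRESHOLD) -> BurstSummary:
    """Partition sorted initiation times into bursts.

    Gaps of at most ``threshold`` seconds join consecutive events into one
    burst; larger gaps end a burst and are recorded as inter-burst times.
    The partition is exact: burst sizes sum to the number of events and
    there is one fewer inter-burst time than bursts.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(initiation_times, dtype=float)
    if t.size == 0:
        return BurstSummary([], [], threshold)
    if np.any(np.diff(t) < 0):
        raise ValueError("initiation times must be sorted")
    gaps = np.diff(t)
    breaks = np.where(gaps > threshold)[0]
    sizes = np.diff(np.concatenate([[0], breaks + 1, [t.size]])).astype(int)
    return BurstSummary(list(sizes), list(gaps[breaks]), threshold)


@dataclass
class NoiseDecomposition:
    """Dual-reporter variance split (channels scaled to equal means)."""

    intrinsic: float
    extrinsic: float

    @property
    def ratio(self) -> float:
        if self.extrinsic == 0.0:
            return math.inf if self.intrinsic > 0 else 0.0
        return self.intrinsic / self.extrinsic


def noise_decomposition(a: Sequence[float], b: Sequence[float]) -> NoiseDecomposition:
    """Intrinsic/extrinsic decomposition of paired reporter ensembles.

    After scaling each channel to unit mean, intrinsic noise is the mean
    squared within-pair difference / 2 and extrinsic noise the across-pair
    covariance; their sum equals the pooled variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length ensembles with >= 2 members")
    ma, mb = a.mean(), b.mean()
    if ma == 0.0 or mb == 0.0:
        raise ValueError("cannot scale a zero-mean channel to unit mean")
    an, bn = a / ma, b / mb
    intrinsic = float(np.mean((an - bn) ** 2) / 2.0)
    extrinsic = float(np.mean(an * bn) - an.mean() * bn.mean())
    return NoiseDecomposition(intrinsic=intrinsic, extrinsic=extrinsic)


def cross_correlation(
    f: Sequence[float],
    g: Sequence[float],
    dt: float = 1.0,
    max_lag: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of two uniformly sampled series.

    Returns ``(lags, cc)`` with cc(tau) = sum_t fc(t) gc(t+tau) divided by
    the geometric mean of the two lag-zero autocorrelations, fc/gc being
    the mean-centered series.  cc(0) is exactly the Pearson correlation
    coefficient.  Lag convention: a positive peak at tau > 0 means g is a
    delayed copy of f (g lags f by tau).
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape or f.ndim != 1:
        raise ValueError("series must be 1-D and equally sampled")
    fc = f - f.mean()
    gc = g - g.mean()
    n0 = math.sqrt(float(np.dot(fc, fc)) * float(np.dot(gc, gc)))
    if n0 == 0.0:
        raise ValueError("cross-correlation undefined for constant series")
    # full[k + n - 1] = sum_t fc(t) gc(t + k)
    full = np.correlate(gc, fc, mode="full")
    n = f.size
    lags = np.arange(-(n - 1), n) * dt
    cc = full / n0
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        lags, cc = lags[keep], cc[keep]
    return lags, cc


def ensemble_cross_correlation(
    series_a: Sequence[Sequence[float]],
    series_b: Sequence[Sequence[float]],
    dt: float,
    max_lag: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean of per-replicate normalized cross-correlations."""
    accum = None
    lags = None
    m = 0
    for fa, fb in zip(series_a, series_b):
        try:
            lags, cc = cross_correlation(fa, fb, dt=dt, max_lag=max_lag)
        except ValueError:
            continue  # a replicate with a constant channel carries no signal
        accum = cc if accum is None else accum + cc
        m += 1
    if accum is None:
        raise ValueError("no replicate had non-constant series")
    return lags, accum / m


def first_positive_side_peak(
    lags: np.ndarray, cc: np.ndarray, min_lag: float = 0.0
) -> Optional[float]:
    """Lag of the first positive local maximum at |lag| > min_lag.

    Peaks on the positive- and negative-lag branches are pooled by |lag|
    (the correlation of a periodic pair is symmetric); returns None when no
    positive side-peak exists.
    """
    peaks, _ = find_peaks(cc)
    cand = [
        (abs(lags[i]), lags[i]) for i in peaks
        if abs(lags[i]) > min_lag and cc[i] > 0.0
    ]
    if not cand:
        return None
    return min(cand)[1]


@dataclass
class StableFractionCurve:
    times: np.ndarray
    fraction: np.ndarray
    half_life: Optional[float]   # None when right-censored at run end
    censored: bool


def hysteresis_basins(
    a: Sequence[float], b: Sequence[float], band: float = 0.0
) -> np.ndarray:
    """Basin labels (+1 = A, -1 = B) with a +/- band hysteresis on a - b.

    The trajectory starts in the basin of the initial sign and switches
    only when the difference crosses the opposite band edge, suppressing
    chatter near the separatrix.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    labels = np.empty(d.size, dtype=int)
    cur = 1 if d[0] >= 0 else -1
    for i, v in enumerate(d):
        if cur > 0 and v < -band:
            cur = -1
        elif cur < 0 and v > band:
            cur = 1
        labels[i] = cur
    return labels


def stable_fraction(
    basin_labels: Sequence[Sequence[int]],
    times: Sequence[float],
) -> StableFractionCurve:
    """Fraction of trajectories that have never left their initial basin.

    A trajectory counts as stable at time t only if its basin label has
    never differed from its initial label up to t; excursions that return
    do not restore stability.  The resulting curve is a non-increasing
    step function on [0, 1]; the half-life is the first time it drops to
    <= 0.5 (right-censored at the final sample if it never does).
    """
    times = np.asarray(times, dtype=float)
    exits = []
    for lab in basin_labels:
        lab = np.asarray(lab)
        changed = np.nonzero(lab != lab[0])[0]
        exits.append(times[changed[0]] if changed.size else math.inf)
    exits = np.asarray(exits)
    frac = np.array([(exits > t).mean() for t in times])
    below = np.nonzero(frac <= 0.5)[0]
    if below.size:
        return StableFractionCurve(times, frac, float(times[below[0]]), False)
    return StableFractionCurve(times, frac, None, True)


def oscillation_amplitude(
    series: Sequence[float],
    settle: int = 0,
    prominence_frac: float = 0.1,
) -> float:
    """Mean peak-to-trough difference of a series after a settling window.

    Peaks and troughs are detected with a minimum prominence of
    ``prominence_frac`` of the series range; returns NaN when fewer than
    one peak/trough pair is found.
    """
    y = np.asarray(series, dtype=float)[settle:]
    if y.size < 3:
        return math.nan
    rng = float(y.max() - y.min())
    if rng == 0.0:
        return 0.0
    prom = prominence_frac * rng
    peaks, _ = find_peaks(y, prominence=prom)
    troughs, _ = find_peaks(-y, prominence=prom)
    if peaks.size == 0 or troughs.size == 0:
        return math.nan
    return float(y[peaks].mean() - y[troughs].mean())


@dataclass
class EnsembleSummary:
    times: np.ndarray
    mean: pd.DataFrame                  # ensemble mean of every trajectory column
    std: pd.DataFrame                   # ensemble std-dev of every column
    normalized_output: Dict[str, np.ndarray]
    position_grid: Optional[np.ndarray] = None
    mean_sigma: Optional[np.ndarray] = None
    amplitude: Dict[str, float] = field(default_factory=dict)


def summarize_ensemble(
    runs,
    normalization: float = 1.0,
    *,
    mrna_columns: Optional[List[str]] = None,
    settle_time: float = 0.0,
    sigma_positions: int = 256,
    sigma_window: Optional[Tuple[float, float]] = None,
) -> EnsembleSummary:
    """Ensemble mean/std trajectories, normalized outputs, mean sigma profile.

    ``runs`` is a list of :class:`~supertx.dynamics.ReplicateResult` sharing
    one layout and output grid.  The supercoiling profile is averaged
    segment-wise on a common position grid across every snapshot in
    ``sigma_window`` (all snapshots by default); snapshots must have been
    collected with ``collect_sigma=True``.
    """
    if not runs:
        raise ValueError("empty ensemble")
    times = runs[0].trajectory["time"].to_numpy()
    cols = [c for c in runs[0].trajectory.columns if c != "time"]
    for r in runs[1:]:
        if len(r.trajectory) != len(times) or not np.allclose(
            r.trajectory["time"].to_numpy(), times
        ):
            raise ValueError("replicates sampled on different grids")
    stack = {c: np.stack([r.trajectory[c].to_numpy(dtype=float) for r in runs]) for c in cols}
    mean = pd.DataFrame({c: stack[c].mean(axis=0) for c in cols})
    std = pd.DataFrame({c: stack[c].std(axis=0, ddof=1) if len(runs) > 1 else
                        np.zeros_like(times) for c in cols})
    if mrna_columns is None:
        mrna_columns = [c for c in cols if c.endswith("_mRNA")]
    normalized = {c: mean[c].to_numpy() / normalization for c in mrna_columns}
    settle_idx = int(np.searchsorted(times, settle_time))
    amplitude = {
        c: float(np.nanmean([
            oscillation_amplitude(stack[c][k], settle=settle_idx)
            for k in range(len(runs))
        ]))
        for c in mrna_columns
    }
    position_grid = None
    mean_sigma = None
    snapshots = [s for r in runs if r.sigma_snapshots for s in r.sigma_snapshots]
    if snapshots:
        if sigma_window is not None:
            lo, hi = sigma_window
            snapshots = [s for s in snapshots if lo <= s[0] <= hi]
        breaks0 = snapshots[0][1].breaks
        z0, z1 = float(breaks0[0]), float(breaks0[-1])
        position_grid = np.linspace(z0, z1, sigma_positions, endpoint=False) + \
            0.5 * (z1 - z0) / sigma_positions
        acc = np.zeros(sigma_positions)
        for _, prof in snapshots:
            acc += np.array([prof.sigma_at(z) for z in position_grid])
        mean_sigma = acc / len(snapshots)
    return EnsembleSummary(
        times=times, mean=mean, std=std, normalized_output=normalized,
        position_grid=position_grid, mean_sigma=mean_sigma, amplitude=amplitude,
    )


def burst_table(
    runs,
    gene: str,
    threshold: float = BURST_THRESHOLD,
    t_min: float = 0.0,
) -> pd.DataFrame:
    """Tidy burst summary (one row per replicate) for one gene."""
    rows = []
    for r in runs:
        times = r.events.times("initiation", gene)
        times = times[times >= t_min]
        summary = detect_bursts(times, threshold)
        rows.append({
            "replicate": r.seed,
            "gene": gene,
            "n_bursts": len(summary.burst_sizes),
            "mean_burst_size": summary.mean_size,
            "mean_inter_burst": summary.mean_inter_burst,
        })
    return pd.DataFrame(rows)
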