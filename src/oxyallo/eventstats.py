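"""Swim-event statistics: matched-trial selection, triggered averages,
hypoxic stress, swim -> pO2 metrics, lagged LOWESS forecasting of stress
from astroglial calcium, and oxygen-dependent gain fits.

Hypoxic stress is the oxygen drop relative to its prior availability,
-dpO2(t)/pO2_baseline, with the baseline taken as the mean pO2 in the
second before the swim; the same absolute drop is twice as stressful at
half the baseline.  The lag fit regresses stress(t) on the astroglial
trace at t - tau with LOWESS (tricube local-linear, fraction 2/3) over a
grid of lags, reporting the lag that maximizes variance explained
r^2 = 1 - <residual^2> / var(stress).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "Trial",
    "MatchingError",
    "select_matched_trials",
    "swim_series",
    "TriggeredAverage",
    "triggered_average",
    "StressTrace",
    "hypoxic_stress",
    "SwimPo2Metrics",
    "swim_po2_metrics",
    "LagFit",
    "LaggedLowess",
    "fit_lag_lowess",
    "GainFit",
    "fit_gain_model",
    "spike_vigor_regression",
]


@dataclass(frozen=True)
class Trial:
    onset_s: float
    offset_s: float
    vigor: float
    condition: str
    pre_pause_s: float
    post_pause_s: float

    @property
    def duration(self) -> float:
        return self.offset_s - self.onset_s


class MatchingError(RuntimeError):
    """Raised when matched-trial selection cannot satisfy its constraints."""


def swim_series(bouts: pd.DataFrame, min_pause: float = 5.0) -> pd.DataFrame:
    """Group bouts into swim series separated by pauses >= min_pause."""
    if not len(bouts):
        return pd.DataFrame(columns=["onset_s", "offset_s", "vigor"])
    onsets = bouts["onset_s"].values
    offsets = bouts["offset_s"].values
    gaps = onsets[1:] - offsets[:-1]
    starts = np.concatenate([[0], np.flatnonzero(gaps >= min_pause) + 1])
    ends = np.concatenate([starts[1:], [len(bouts)]])
    return pd.DataFrame(
        {
            "onset_s": onsets[starts],
            "offset_s": offsets[ends - 1],
            "vigor": [bouts["vigor"].values[s:e].sum() for s, e in zip(starts, ends)],
        }
    )


def _candidate_trials(bouts, window, condition, min_isi, duration):
    onsets = bouts["onset_s"].values
    offsets = bouts["offset_s"].values
    out = []
    for i in range(len(bouts)):
        if not (window[0] <= onsets[i] < window[1]):
            continue
        pre = onsets[i] - offsets[i - 1] if i > 0 else onsets[i]
        post = onsets[i + 1] - offsets[i] if i + 1 < len(bouts) else (
            duration - offsets[i]
        )
        if pre <= min_isi:
            continue
        out.append(
            Trial(
                onset_s=float(onsets[i]),
                offset_s=float(offsets[i]),
                vigor=float(bouts["vigor"].values[i]),
                condition=condition,
                pre_pause_s=float(pre),
                post_pause_s=float(post),
            )
        )
    return out


def select_matched_trials(
    bouts: pd.DataFrame,
    windows: dict[str, tuple[float, float]] | None = None,
    tolerance: float = 0.2,
    min_isi: float = 1.0,
    min_trials: int = 10,
    duration: float = 2400.0,
) -> tuple[list[Trial], list[Trial]]:
    """Cross-condition swim-matched trials.

    Candidates are bouts inside the sampling windows (default: late
    normoxia 10-20 min and late hypoxia 30-40 min) whose preceding
    inter-swim interval exceeds 1 s.  Hypoxia trials are matched greedily
    to normoxia trials with both vigor and duration within +/- tolerance
    (relative); fewer than ``min_trials`` matches raises
    :class:`MatchingError` naming the binding constraint.
    """
    windows = windows or {
        "normoxia": (600.0, 1200.0),
        "hypoxia": (1800.0, 2400.0),
    }
    cands = {
        cond: _candidate_trials(bouts, win, cond, min_isi, duration)
        for cond, win in windows.items()
    }
    for cond, lst in cands.items():
        if len(lst) < min_trials:
            raise MatchingError(
                f"only {len(lst)} candidate trials in {cond} "
                f"(need >= {min_trials}; binding constraint: candidate count)"
            )
    norm, hyp = cands["normoxia"], cands["hypoxia"]
    used = np.zeros(len(norm), dtype=bool)
    pairs: list[tuple[Trial, Trial]] = []
    for th in hyp:
        best, best_cost = -1, np.inf
        for j, tn in enumerate(norm):
            if used[j]:
                continue
            dv = abs(th.vigor - tn.vigor) / max(tn.vigor, 1e-12)
            dd = abs(th.duration - tn.duration) / max(tn.duration, 1e-12)
            if dv <= tolerance and dd <= tolerance and dv + dd < best_cost:
                best, best_cost = j, dv + dd
        if best >= 0:
            used[best] = True
            pairs.append((norm[best], th))
    if len(pairs) < min_trials:
        raise MatchingError(
            f"only {len(pairs)} cross-condition matches at +/-{tolerance:.0%} "
            f"(need >= {min_trials}; binding constraint: matching tolerance)"
        )
    return [p[0] for p in pairs], [p[1] for p in pairs]


@dataclass
class TriggeredAverage:
    t: np.ndarray  # s relative to onset
    mean: np.ndarray
    sem: np.ndarray
    n: int
    n_dropped: int


def triggered_average(
    series: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    window: tuple[float, float] = (-5.0, 30.0),
    baseline_s: float = 1.0,
) -> TriggeredAverage:
    """Onset-aligned mean +/- sem with per-trial pre-onset baselining."""
    series = np.asarray(series, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    i0, i1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    nb = max(int(round(baseline_s * fs)), 1)
    snips = []
    dropped = 0
    for onset in onsets:
        c = int(round(onset * fs))
        if c + i0 < 0 or c + i1 > series.size or c - nb < 0:
            dropped += 1
            continue
        snip = series[c + i0 : c + i1].astype(float)
        snips.append(snip - series[c - nb : c].mean())
    if len(snips) < 2:
        raise ValueError("need at least 2 usable trials")
    arr = np.asarray(snips)
    return TriggeredAverage(
        t=np.arange(i0, i1) / fs,
        mean=arr.mean(axis=0),
        sem=arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]),
        n=arr.shape[0],
        n_dropped=dropped,
    )


@dataclass
class StressTrace:
    t: np.ndarray  # s relative to onset
    stress: np.ndarray  # -dpO2/pO2_baseline, dimensionless
    baseline: float  # mg/L


def hypoxic_stress(
    po2: np.ndarray,
    fs: float,
    onset: float,
    window: tuple[float, float] = (0.0, 30.0),
    baseline_s: float = 1.0,
) -> StressTrace:
    """stress(t) = -(pO2(t) - baseline)/baseline with a 1-s pre-onset baseline."""
    po2 = np.asarray(po2, dtype=float)
    c = int(round(onset * fs))
    nb = max(int(round(baseline_s * fs)), 1)
    if c - nb < 0:
        raise ValueError("pre-onset baseline window unavailable")
    baseline = float(po2[c - nb : c].mean())
    if baseline <= 0:
        raise ValueError("non-positive pO2 baseline")
    i0, i1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    i1 = min(c + i1, po2.size)
    seg = po2[c + i0 : i1]
    return StressTrace(
        t=np.arange(seg.size) / fs + window[0],
        stress=-(seg - baseline) / baseline,
        baseline=baseline,
    )


@dataclass
class SwimPo2Metrics:
    minimum_drop: float | None  # mg/L, depth of the pO2 minimum (negative)
    decay_time_s: float | None  # pre-swim level to 50% of the minimum
    rise_time_s: float | None  # minimum back to 50% recovery
    stop_to_min_s: float | None  # bout offset to the minimum
    flagged: bool


def swim_po2_metrics(
    po2: np.ndarray,
    fs: float,
    onset: float,
    offset: float,
    window: float = 30.0,
    baseline_s: float = 1.0,
) -> SwimPo2Metrics:
    """Depth and timing of the swim-induced pO2 dip on a smoothed trace."""
    po2 = np.asarray(po2, dtype=float)
    c = int(round(onset * fs))
    nb = max(int(round(baseline_s * fs)), 1)
    n_win = int(round(window * fs))
    if c - nb < 0 or c + n_win > po2.size:
        raise ValueError("post-bout window must cover 30 s")
    pre = po2[c - nb : c].mean()
    seg = po2[c : c + n_win]
    delta = seg - pre
    k_min = int(np.argmin(delta))
    d_min = float(delta[k_min])
    interior = 0 < k_min < n_win - 1
    if d_min >= 0 or not interior:
        return SwimPo2Metrics(None, None, None, None, flagged=True)
    half = 0.5 * d_min
    below = np.flatnonzero(delta[: k_min + 1] <= half)
    decay = below[0] / fs if below.size else None
    after = np.flatnonzero(delta[k_min:] >= half)
    rise = after[0] / fs if after.size else None
    return SwimPo2Metrics(
        minimum_drop=d_min,
        decay_time_s=decay,
        rise_time_s=rise,
        stop_to_min_s=k_min / fs - (offset - onset),
        flagged=False,
    )


@dataclass
class LagFit:
    tau: float  # s, best lag
    r2: float
    tau_grid: np.ndarray
    r2_curve: np.ndarray
    frac: float
    fitted: np.ndarray  # fitted stress at the best lag
    degenerate: bool = False


class LaggedLowess:
    """Forecast hypoxic stress from lagged astroglial calcium.

    For each lag tau on the grid, stress(t) is LOWESS-regressed on
    astro(t - tau); the reported lag maximizes variance explained.
    """

    def __init__(self, astro: np.ndarray, stress: np.ndarray, fs: float,
                 tau_max: float = 20.0, frac: float = 2.0 / 3.0, it: int = 1):
        astro = np.asarray(astro, dtype=float)
        stress = np.asarray(stress, dtype=float)
        if astro.shape != stress.shape:
            raise ValueError("astro and stress must share a sampling grid")
        self.astro = astro
        self.stress = stress
        self.fs = fs
        self.tau_max = tau_max
        self.frac = frac
        self.it = it

    def fit(self) -> LagFit:
        n_lags = int(round(self.tau_max * self.fs)) + 1
        taus = np.arange(n_lags) / self.fs
        var = float(np.var(self.stress))
        if np.std(self.astro) == 0 or var == 0:
            return LagFit(0.0, 0.0, taus, np.zeros(n_lags), self.frac,
                          np.zeros_like(self.stress), degenerate=True)
        r2 = np.full(n_lags, -np.inf)
        best_fit = None
        for k in range(n_lags):
            x = self.astro[: self.astro.size - k] if k else self.astro
            y = self.stress[k:]
            if x.size < 10 or np.std(x) == 0:
                r2[k] = 0.0
                continue
            yhat = lowess(y, x, frac=self.frac, it=self.it,
                          return_sorted=False)
            resid = y - yhat
            r2[k] = 1.0 - float(np.mean(resid**2)) / var
            if best_fit is None or r2[k] >= np.nanmax(r2[: k + 1]):
                if r2[k] == np.nanmax(r2[: k + 1]):
                    best_fit = (k, yhat)
        k_best = int(np.nanargmax(r2))
        if best_fit is None or best_fit[0] != k_best:
            x = self.astro[: self.astro.size - k_best] if k_best else self.astro
            y = self.stress[k_best:]
            best_fit = (k_best, lowess(y, x, frac=self.frac, it=self.it,
                                       return_sorted=False))
        return LagFit(
            tau=float(taus[k_best]),
            r2=float(r2[k_best]),
            tau_grid=taus,
            r2_curve=r2,
            frac=self.frac,
            fitted=best_fit[1],
        )


def fit_lag_lowess(astro, stress, fs, tau_max: float = 20.0, **kwargs) -> LagFit:
    return LaggedLowess(astro, stress, fs, tau_max=tau_max, **kwargs).fit()


@dataclass
class GainFit:
    blocks: pd.DataFrame  # block_t, gain, po2_mean, n_swims
    decay_s: float
    r2: float  # global single-gain fit quality


def _vigor_regressor(bouts, n, frame_rate, decay_s):
    v = np.zeros(n)
    for onset, vigor in bouts[["onset_s", "vigor"]].values:
        i = int(onset * frame_rate)
        if 0 <= i < n:
            v[i] += vigor
    kern = np.exp(-np.arange(int(5 * decay_s * frame_rate) + 1)
                  / (decay_s * frame_rate))
    return np.convolve(v, kern)[:n], v


def fit_gain_model(
    dff: np.ndarray,
    frame_rate: float,
    bouts: pd.DataFrame,
    po2: np.ndarray,
    po2_fs: float,
    block_s: float = 30.0,
    decay_grid: np.ndarray | None = None,
) -> GainFit:
    """Oxygen-dependent gain of swim-evoked calcium transients.

    The regressor is the vigor impulse train convolved with an exponential
    decay whose constant is fitted once globally (grid search); each 30-s
    block's gain is the least-squares coefficient of dFF on the regressor,
    assembled against the block-mean pO2.  Blocks without swims are
    skipped.
    """
    dff = np.asarray(dff, dtype=float)
    n = dff.size
    if decay_grid is None:
        decay_grid = np.geomspace(0.5, 10.0, 12)
    best = None
    for tau in decay_grid:
        reg, _ = _vigor_regressor(bouts, n, frame_rate, tau)
        if reg.std() == 0:
            continue
        X = np.column_stack([np.ones(n), reg])
        coef, *_ = np.linalg.lstsq(X, dff, rcond=None)
        r2 = 1.0 - np.sum((dff - X @ coef) ** 2) / max(np.sum(
            (dff - dff.mean()) ** 2), 1e-12)
        if best is None or r2 > best[0]:
            best = (r2, tau)
    if best is None:
        return GainFit(
            blocks=pd.DataFrame(columns=["block_t", "gain", "po2_mean", "n_swims"]),
            decay_s=float("nan"), r2=0.0,
        )
    r2_global, decay_s = best
    reg, impulses = _vigor_regressor(bouts, n, frame_rate, decay_s)
    po2_f = np.interp(np.arange(n) / frame_rate,
                      np.arange(len(po2)) / po2_fs, po2)
    per_block = int(round(block_s * frame_rate))
    rows = []
    for b in range(n // per_block):
        sl = slice(b * per_block, (b + 1) * per_block)
        n_swims = int(np.count_nonzero(impulses[sl]))
        if n_swims == 0 or reg[sl].std() == 0:
            continue
        X = np.column_stack([np.ones(per_block), reg[sl]])
        coef, *_ = np.linalg.lstsq(X, dff[sl], rcond=None)
        rows.append(
            {
                "block_t": b * block_s,
                "gain": float(coef[1]),
                "po2_mean": float(po2_f[sl].mean()),
                "n_swims": n_swims,
            }
        )
    return GainFit(blocks=pd.DataFrame(rows), decay_s=float(decay_s),
                   r2=float(r2_global))


def spike_vigor_regression(
    counts: np.ndarray,
    vigor: np.ndarray,
    condition: np.ndarray,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Per-condition OLS slope of swim-coupled spike counts on vigor.

    Returns one row per condition (slope, se, CI) plus the
    normoxia/hypoxia slope ratio as a DataFrame attribute ``slope_ratio``.
    """
    counts = np.asarray(counts, dtype=float)
    vigor = np.asarray(vigor, dtype=float)
    condition = np.asarray(condition)
    rows = {}
    for cond in dict.fromkeys(condition):
        m = condition == cond
        if m.sum() < min_pairs:
            raise ValueError(f"fewer than {min_pairs} pairs in {cond}")
        v = vigor[m]
        if np.ptp(v) == 0:
            raise ValueError(f"degenerate vigor range in {cond}")
        res = sm.OLS(counts[m], sm.add_constant(v)).fit()
        ci = res.conf_int()[1]
        rows[cond] = {
            "slope": float(res.params[1]),
            "se": float(res.bse[1]),
            "ci_lo": float(ci[0]),
            "ci_hi": float(ci[1]),
            "n": int(m.sum()),
        }
    out = pd.DataFrame(rows).T
    if {"normoxia", "hypoxia"} <= set(out.index):
        out.attrs["slope_ratio"] = (
            out.loc["normoxia", "slope"] / out.loc["hypoxia", "slope"]
        )
    return out
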