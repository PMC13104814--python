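"""Event detection and behavioral metrics from raw electrode channels.

Swim bouts are detected from the fictive-swim channel as supra-threshold
runs of the 10-ms windowed standard deviation ("swim power"); the
threshold is found on the histogram of log power (Otsu), with an
amplitude floor and minimum-duration guard so a silent channel yields no
bouts.  Bout vigor is the time integral of power over the bout.
Respiration events are peaks of the 10-Hz low-passed respiration channel
restricted to inter-bout intervals.  Patch-clamp spike trains are split
into phasic bursts (>= 3 spikes with inter-spike intervals <= 70 ms) and
tonic spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt
from skimage.filters import threshold_otsu

from .paradigm import Paradigm

__all__ = [
    "BoutTable",
    "RespEvents",
    "SpikeClassification",
    "swim_power",
    "detect_swim_bouts",
    "detect_respiration",
    "classify_spikes",
    "smooth_po2",
    "behavior_metrics",
]


BoutTable = pd.DataFrame  # columns: onset_s, offset_s, vigor, peak_power


@dataclass
class RespEvents:
    times: np.ndarray  # s
    rate: np.ndarray  # events/min, instantaneous (at 1 Hz)
    rate_t: np.ndarray  # s, time base of the rate series


@dataclass
class SpikeClassification:
    total_rate: float  # Hz
    tonic_rate: float  # Hz
    phasic_per_min: float  # bursts/min
    burst_id: np.ndarray  # per spike: -1 tonic, else burst index


def swim_power(swim: np.ndarray, fs: float, window_s: float = 0.010) -> np.ndarray:
    """Centered rolling standard deviation of the swim channel."""
    w = max(int(round(window_s * fs)), 2)
    x = np.asarray(swim, dtype=float)
    mean = uniform_filter1d(x, w, mode="nearest")
    sq = uniform_filter1d(x * x, w, mode="nearest")
    return np.sqrt(np.maximum(sq - mean * mean, 0.0))


def detect_swim_bouts(
    swim: np.ndarray,
    fs: float,
    min_duration_s: float = 0.020,
    merge_gap_s: float = 0.010,
    floor_mads: float = 6.0,
) -> BoutTable:
    """Detect swim bouts from the raw electrode channel.

    Threshold = Otsu on the log-power histogram, floored at
    median + ``floor_mads`` scaled MADs of log power so that a channel
    containing only noise produces no detections.  Supra-threshold runs
    are merged across gaps < 10 ms and runs < 20 ms are dropped.
    """
    if fs < 1000:
        raise ValueError("sampling rate must be >= 1 kHz")
    power = swim_power(swim, fs)
    empty = pd.DataFrame(columns=["onset_s", "offset_s", "vigor", "peak_power"])
    if not np.any(power > 0):
        return empty

    logp = np.log(power + 1e-12)
    med = np.median(logp)
    mad = 1.4826 * np.median(np.abs(logp - med))
    thr_log = max(threshold_otsu(logp, nbins=256), med + floor_mads * max(mad, 1e-3))
    above = logp > thr_log
    if not above.any():
        return empty

    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])

    # merge runs separated by < merge_gap
    gap = int(round(merge_gap_s * fs))
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_len = int(round(min_duration_s * fs))
    rows = []
    for s, e in merged:
        if e - s < min_len:
            continue
        seg = power[s:e]
        rows.append(
            {
                "onset_s": s / fs,
                "offset_s": e / fs,
                "vigor": float(np.trapezoid(seg, dx=1.0 / fs)),
                "peak_power": float(seg.max()),
            }
        )
    return pd.DataFrame(rows) if rows else empty


def detect_respiration(
    resp: np.ndarray,
    fs: float,
    bouts: BoutTable,
    prominence_mads: float = 4.0,
    min_spacing_s: float = 0.100,
    lowpass_hz: float = 10.0,
) -> RespEvents:
    """Peak-pick the low-passed respiration channel between swim bouts."""
    resp = np.asarray(resp, dtype=float)
    sos = butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
    filt = sosfiltfilt(sos, resp)
    mad = 1.4826 * np.median(np.abs(filt - np.median(filt)))
    # relative floor guards the near-noiseless case (MAD ~ 0), where filter
    # ringing would otherwise be picked up
    floor = 0.05 * np.ptp(filt)
    peaks, _ = find_peaks(
        filt,
        prominence=max(prominence_mads * mad, floor, 1e-12),
        distance=max(int(min_spacing_s * fs), 1),
    )
    times = peaks / fs
    # restrict to inter-bout intervals
    if len(bouts):
        keep = np.ones(times.size, dtype=bool)
        for onset, offset in bouts[["onset_s", "offset_s"]].values:
            keep &= ~((times >= onset) & (times <= offset))
        times = times[keep]

    duration = resp.size / fs
    rate_t = np.arange(int(duration))
    rate = np.zeros(rate_t.size)
    if times.size:
        window = 30.0  # s, centered rate window
        for i, tc in enumerate(rate_t):
            lo, hi = max(tc - window / 2, 0), min(tc + window / 2, duration)
            rate[i] = np.sum((times >= lo) & (times < hi)) / (hi - lo) * 60.0
    return RespEvents(times=times, rate=rate, rate_t=rate_t.astype(float))


def classify_spikes(
    spike_times: np.ndarray,
    max_isi_s: float = 0.070,
    min_burst_spikes: int = 3,
    duration: float | None = None,
) -> SpikeClassification:
    """Split a spike train into phasic bursts and tonic spikes.

    A burst is a maximal run of spikes whose consecutive inter-spike
    intervals are all <= 70 ms (inclusive) with at least 3 spikes.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    duration = duration if duration is not None else (t[-1] if t.size else 1.0)
    duration = max(duration, 1e-9)
    burst_id = np.full(t.size, -1, dtype=int)
    if t.size:
        short = np.diff(t) <= max_isi_s
        run_start = 0
        n_bursts = 0
        for i in range(t.size):
            end_of_run = i == t.size - 1 or not short[i]
            if end_of_run:
                if i - run_start + 1 >= min_burst_spikes:
                    burst_id[run_start : i + 1] = n_bursts
                    n_bursts += 1
                run_start = i + 1
    n_burst_spikes = int(np.sum(burst_id >= 0))
    n_bursts = int(burst_id.max() + 1) if n_burst_spikes else 0
    return SpikeClassification(
        total_rate=t.size / duration,
        tonic_rate=(t.size - n_burst_spikes) / duration,
        phasic_per_min=n_bursts / duration * 60.0,
        burst_id=burst_id,
    )


def smooth_po2(po2: np.ndarray, fs: float, window_s: float = 10.0) -> np.ndarray:
    """Centered moving average (10-s window), shrinking at the edges."""
    po2 = np.asarray(po2, dtype=float)
    w = int(round(window_s * fs))
    if w < 3:
        raise ValueError("smoothing window must cover at least 3 samples")
    half = w // 2
    c = np.concatenate([[0.0], np.cumsum(po2)])
    idx = np.arange(po2.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, po2.size)
    return (c[hi] - c[lo]) / (hi - lo)


def behavior_metrics(
    bouts: BoutTable,
    resp: RespEvents | None,
    schedule: Paradigm,
    long_pause_s: float = 5.0,
    stimulus_table: pd.DataFrame | None = None,
    min_swim_hz: float = 0.4,
) -> pd.DataFrame:
    """Per-epoch behavioral summary.

    Columns: swim frequency (bouts/s), respiration frequency (events/s),
    mean vigor per bout, mean inter-bout interval, count of long pauses
    (inter-bout interval >= 5 s), OMR rate (swim rate during visual
    stimulus minus during static periods; NaN without a stimulus table),
    and an inclusion flag (normoxic swim frequency >= 0.4 Hz).
    """
    rows = []
    onsets = bouts["onset_s"].values if len(bouts) else np.array([])
    offsets = bouts["offset_s"].values if len(bouts) else np.array([])
    for ep in schedule.epochs:
        m = (onsets >= ep.start) & (onsets < ep.end)
        n_bouts = int(m.sum())
        swim_hz = n_bouts / ep.duration
        ibis = (
            onsets[m][1:] - offsets[m][:-1] if n_bouts > 1 else np.array([])
        )
        omr = np.nan
        if stimulus_table is not None and len(stimulus_table):
            stim = moving = 0.0
            t_stim = t_stat = 0.0
            for s0, s1, kind in stimulus_table[["start_s", "end_s", "kind"]].values:
                s0, s1 = max(s0, ep.start), min(s1, ep.end)
                if s1 <= s0:
                    continue
                cnt = np.sum((onsets >= s0) & (onsets < s1))
                if kind == "stimulus":
                    moving += cnt
                    t_stim += s1 - s0
                else:
                    stim += cnt
                    t_stat += s1 - s0
            if t_stim > 0 and t_stat > 0:
                omr = moving / t_stim - stim / t_stat
        resp_hz = np.nan
        if resp is not None:
            resp_hz = np.sum(
                (resp.times >= ep.start) & (resp.times < ep.end)
            ) / ep.duration
        rows.append(
            {
                "epoch": ep.label,
                "start_s": ep.start,
                "end_s": ep.end,
                "swim_freq_hz": swim_hz,
                "resp_freq_hz": resp_hz,
                "mean_vigor": float(bouts.loc[m, "vigor"].mean()) if n_bouts else np.nan,
                "mean_ibi_s": float(ibis.mean()) if ibis.size else np.nan,
                "long_pauses": int(np.sum(ibis >= long_pause_s)) if ibis.size else 0,
                "omr_rate": omr,
            }
        )
    out = pd.DataFrame(rows)
    norm = out[out["epoch"] == "normoxia"]
    included = bool((norm["swim_freq_hz"] >= min_swim_hz).all()) if len(norm) else True
    out["included"] = included
    return out
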