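"""Stochastic simulator of the noradrenergic (NE-MO) - astroglial swim circuit.

A central pattern generator (CPG) proposes one swim bout per second by
kicking a fast swim-probability variable ``P_swim`` (decay 50 ms).  A swim
event fires when ``P_swim`` exceeds a uniform random threshold; each fired
event is an efference copy that drives the NE-MO unit with an
oxygen-dependent gain (``f_pO2`` = 1 in normoxia, 10 in hypoxia).  NE-MO
output above a threshold releases norepinephrine (``F_NE``, 100 ms), which
astroglia integrate slowly (``F_glia``, 3 s, gain 3).  The NE - glia
difference modulates the CPG kick, so accumulated glial calcium suppresses
bout initiation while the fast NE surge transiently regenerates ``P_swim``
within a bout, producing multi-event (vigorous) bouts under hypoxia.

Events closer than 50 ms are grouped into bouts; bout vigor is the number
of events it contains.

Numerical notes
---------------
* The printed circuit equations omit the minus signs on the decay terms;
  they are integrated here as ``-X/tau`` (states diverge otherwise).
* The uniform threshold is redrawn at each CPG kick and after each fired
  event, so with modulation clamped off the bout rate is exactly the 1 Hz
  CPG rate.  A fired event consumes ``P_swim`` (reset to 0).
* ``dt`` = 10 ms is part of the model definition: event generation is a
  per-step threshold crossing, so statistics are tied to the step size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CircuitParams",
    "CircuitState",
    "CircuitTrace",
    "step",
    "simulate",
    "simulate_filters",
    "group_events",
]


@dataclass(frozen=True)
class CircuitParams:
    tau_swim: float = 0.05  # s, P_swim decay
    tau_nemo: float = 0.1  # s, NE-MO efference filter
    tau_ne: float = 0.1  # s, NE release filter
    tau_glia: float = 3.0  # s, astroglial integration
    f_po2_normoxia: float = 1.0  # efference gain in normoxia
    f_po2_hypoxia: float = 10.0  # efference gain in hypoxia
    relu_threshold: float = 0.3  # x0 of the NE-MO -> NE rectifier
    glial_gain: float = 3.0  # g, NE -> glia coupling
    modulator_slope: float = 1.0 / 3.0  # p(x) = x/3 before clipping
    fast_drive_threshold: float = 2.0  # NE-MO level igniting within-bout drive
    dt: float = 0.01  # s
    cpg_period: float = 1.0  # s
    bout_gap: float = 0.05  # s, events closer than this share a bout
    event_duration: float = 0.1  # s, nominal single-event excursion (~2 tau_swim)
    modulation_mode: str = "impulse_gain"  # impulse_gain | additive_drive | literal

    def __post_init__(self) -> None:
        for name in ("tau_swim", "tau_nemo", "tau_ne", "tau_glia", "cpg_period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt <= 0 or self.dt > self.tau_swim / 2:
            raise ValueError("dt must satisfy 0 < dt <= tau_swim/2")
        if self.modulation_mode not in ("impulse_gain", "additive_drive", "literal"):
            raise ValueError(f"unknown modulation_mode {self.modulation_mode!r}")

    def gain_for(self, condition: str) -> float:
        if condition == "normoxia":
            return self.f_po2_normoxia
        if condition == "hypoxia":
            return self.f_po2_hypoxia
        raise ValueError(f"unknown condition {condition!r}")


@dataclass
class CircuitState:
    p_swim: float = 0.0
    f_nemo: float = 0.0
    f_ne: float = 0.0
    f_glia: float = 0.0
    threshold: float = 1.0  # current uniform event threshold


def step(
    state: CircuitState,
    params: CircuitParams,
    f_po2: float,
    rng: np.random.Generator,
    cpg_kick: bool,
    modulation: bool = True,
) -> tuple[CircuitState, bool]:
    """Advance the circuit one Euler step; returns (state, event_fired).

    ``f_po2`` is the oxygen-dependent efference gain at this step (1 for
    normoxia, 10 for hypoxia, or a continuous value in between).
    """
    p = params
    dt = p.dt
    s = state

    f_nemo = s.f_nemo + dt * (-s.f_nemo / p.tau_nemo)
    f_ne = s.f_ne + dt * (-s.f_ne / p.tau_ne + max(s.f_nemo - p.relu_threshold, 0.0))
    f_glia = s.f_glia + dt * (-s.f_glia / p.tau_glia + p.glial_gain * s.f_ne)
    if not modulation:
        f_ne = 0.0
        f_glia = 0.0

    diff = f_ne - f_glia
    m = float(np.clip(diff * p.modulator_slope, -1.0, 1.0))
    # fast within-bout drive: NE-MO efference above ignition threshold,
    # shunted by accumulated glial calcium
    shunt = float(np.clip(1.0 - f_glia * p.modulator_slope, 0.0, 1.0))
    fast = (
        float(
            np.clip(
                (f_nemo - p.fast_drive_threshold) / p.fast_drive_threshold, 0.0, 1.0
            )
        )
        * shunt
    )

    p_swim = s.p_swim + dt * (-s.p_swim / p.tau_swim)
    threshold = s.threshold
    if p.modulation_mode == "impulse_gain":
        p_swim += dt * fast / p.tau_swim
        if cpg_kick:
            p_swim += float(np.clip(1.0 + m, 0.0, 2.0))
            threshold = rng.uniform()
    elif p.modulation_mode == "additive_drive":
        p_swim += dt * fast / p.tau_swim + dt * m
        if cpg_kick:
            p_swim += 1.0
            threshold = rng.uniform()
    else:  # literal: printed one-sided modulator added to P'
        p_swim += dt * float(np.clip(diff * p.modulator_slope, 0.0, 1.0))
        if cpg_kick:
            p_swim += 1.0
            threshold = rng.uniform()
    p_swim = float(np.clip(p_swim, 0.0, 1.0))

    fired = p_swim > threshold
    if fired:
        p_swim = 0.0
        threshold = rng.uniform()
        f_nemo += f_po2  # efference copy with oxygen-dependent gain

    return (
        CircuitState(p_swim=p_swim, f_nemo=f_nemo, f_ne=f_ne, f_glia=f_glia,
                     threshold=threshold),
        fired,
    )


@dataclass
class CircuitTrace:
    """State trajectories, event times, and grouped bouts of one simulation."""

    t: np.ndarray
    p_swim: np.ndarray
    f_nemo: np.ndarray
    f_ne: np.ndarray
    f_glia: np.ndarray
    events: np.ndarray  # event times, s
    bouts: pd.DataFrame  # onset_s, offset_s, vigor (event count)
    params: CircuitParams

    @property
    def bout_rate(self) -> float:
        return len(self.bouts) / (self.t[-1] + self.params.dt)

    @property
    def mean_vigor(self) -> float:
        return float(self.bouts["vigor"].mean()) if len(self.bouts) else float("nan")

    def long_pauses(self, min_pause: float = 5.0) -> int:
        """Number of inter-bout intervals (offset to next onset) >= min_pause."""
        if len(self.bouts) < 2:
            return 0
        gaps = self.bouts["onset_s"].values[1:] - self.bouts["offset_s"].values[:-1]
        return int(np.sum(gaps >= min_pause))


def group_events(
    events: np.ndarray, gap: float = 0.05, event_duration: float = 0.1
) -> pd.DataFrame:
    """Group instantaneous swim events into bouts.

    Events with inter-event interval < ``gap`` share a bout; vigor is the
    event count.  The bout offset extends one nominal event duration past
    its last event.
    """
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        return pd.DataFrame(columns=["onset_s", "offset_s", "vigor"]).astype(
            {"onset_s": float, "offset_s": float, "vigor": int}
        )
    starts = np.concatenate([[0], np.flatnonzero(np.diff(events) >= gap) + 1])
    ends = np.concatenate([starts[1:], [events.size]])
    onsets = events[starts]
    offsets = events[ends - 1] + event_duration
    # the nominal event duration must not overrun the next bout's onset;
    # leave a clear inter-bout gap so the bouts stay physically separable
    offsets[:-1] = np.minimum(offsets[:-1], onsets[1:] - 0.025)
    return pd.DataFrame(
        {
            "onset_s": onsets,
            "offset_s": offsets,
            "vigor": (ends - starts).astype(int),
        }
    )


def _gain_series(params, condition, n_steps):
    """Per-step oxygen gain from a condition name, scalar, callable or array."""
    t = np.arange(n_steps) * params.dt
    if isinstance(condition, str):
        return np.full(n_steps, params.gain_for(condition))
    if callable(condition):
        return np.asarray([float(condition(ti)) for ti in t])
    arr = np.asarray(condition, dtype=float)
    if arr.ndim == 0:
        return np.full(n_steps, float(arr))
    if arr.size != n_steps:
        raise ValueError("per-step gain array length mismatch")
    return arr


def simulate(
    params: CircuitParams | None = None,
    duration: float = 600.0,
    condition="normoxia",
    seed: int | None = 0,
    modulation: bool = True,
) -> CircuitTrace:
    """Run the circuit for ``duration`` seconds.

    ``condition`` may be a condition name, a scalar gain, a callable
    ``t -> f_pO2`` or a per-step gain array (for continuous hypoxia maps).
    With ``modulation=False`` the NE and glial states are clamped to zero,
    leaving the bare 1 Hz CPG.
    """
    params = params or CircuitParams()
    if duration < params.cpg_period:
        raise ValueError("duration must cover at least one CPG period")
    rng = np.random.default_rng(seed)
    n = int(round(duration / params.dt))
    steps_per_cpg = int(round(params.cpg_period / params.dt))
    gains = _gain_series(params, condition, n)

    t = np.arange(n) * params.dt
    p_swim = np.empty(n)
    f_nemo = np.empty(n)
    f_ne = np.empty(n)
    f_glia = np.empty(n)
    events: list[float] = []

    state = CircuitState(threshold=rng.uniform())
    for k in range(n):
        state, fired = step(
            state,
            params,
            gains[k],
            rng,
            cpg_kick=(k % steps_per_cpg == 0),
            modulation=modulation,
        )
        if fired:
            events.append(t[k])
        p_swim[k] = state.p_swim
        f_nemo[k] = state.f_nemo
        f_ne[k] = state.f_ne
        f_glia[k] = state.f_glia

    bouts = group_events(
        np.asarray(events), gap=params.bout_gap, event_duration=params.event_duration
    )
    return CircuitTrace(
        t=t,
        p_swim=p_swim,
        f_nemo=f_nemo,
        f_ne=f_ne,
        f_glia=f_glia,
        events=np.asarray(events),
        bouts=bouts,
        params=params,
    )


def simulate_filters(
    event_times: np.ndarray,
    params: CircuitParams | None = None,
    duration: float | None = None,
    f_po2: float = 1.0,
    ne_input: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Integrate the deterministic NE-MO / NE / glia filter cascade.

    Drives the linear subsystem with a prescribed event train (each event
    increments ``F_NEMO`` by ``f_po2``), or, if ``ne_input`` is given, drives
    ``F_glia`` directly with that per-step ``F_NE`` trace.  Useful for
    impulse/step-response analysis of the cascade in isolation.
    """
    params = params or CircuitParams()
    dt = params.dt
    event_times = np.asarray(event_times, dtype=float)
    if duration is None:
        duration = (event_times.max() if event_times.size else 0.0) + 10 * params.tau_glia
    n = int(round(duration / dt))
    t = np.arange(n) * dt

    kicks = np.zeros(n)
    if event_times.size:
        idx = np.clip(np.round(event_times / dt).astype(int), 0, n - 1)
        np.add.at(kicks, idx, f_po2)

    f_nemo = np.zeros(n)
    f_ne = np.zeros(n)
    f_glia = np.zeros(n)
    x_nemo = x_ne = x_glia = 0.0
    drive_ne = ne_input if ne_input is not None else None
    for k in range(n):
        x_nemo += dt * (-x_nemo / params.tau_nemo)
        x_nemo += kicks[k]
        x_ne += dt * (-x_ne / params.tau_ne + max(x_nemo - params.relu_threshold, 0.0))
        ne_k = x_ne if drive_ne is None else float(drive_ne[k])
        x_glia += dt * (-x_glia / params.tau_glia + params.glial_gain * ne_k)
        f_nemo[k] = x_nemo
        f_ne[k] = ne_k
        f_glia[k] = x_glia
    return {"t": t, "f_nemo": f_nemo, "f_ne": f_ne, "f_glia": f_glia}
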