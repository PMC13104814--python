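"""Oxygen-gated NE-MO neuron: generalized leaky integrate-and-fire with
exponential escape-rate spiking, plus a calcium/fluorescence forward model.

The membrane integrates a leak toward rest, an oxygen-dependent drive
``E_O2(pO2)`` that rises as pO2 falls (the cell's intrinsic hypoxia
sensitivity), and pulse currents representing motor efference copies:

    tau_m dV/dt = -(V - E_L) + (E_O2(pO2) - E_L) w + R I_pulse(t)

Spikes are drawn from the inhomogeneous escape rate

    lambda(t) = lambda0 exp((V - V_T) / dV)

The exponential makes the oxygen and synaptic contributions *additive in
log-rate*, i.e. the spike rate factorizes as f(O2) x g(vigor) - the
multiplicative oxygen-by-motor interaction observed in NE-MO recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LifParams", "CalciumForward", "simulate_neuron", "fluorescence_forward"]


@dataclass(frozen=True)
class LifParams:
    tau_m: float = 0.02  # s, membrane time constant
    e_leak: float = -60.0  # mV, rest
    w_o2: float = 1.0  # weight of the oxygen drive
    o2_gain_mv: float = 4.0  # mV of drive per unit (po2_norm/po2 - 1)
    po2_norm: float = 8.0  # mg/L, normoxic reference
    r_input: float = 1.0  # input resistance (pulse currents given in mV)
    lambda0: float = 10.0  # Hz, escape-rate base
    v_thresh: float = -50.0  # mV
    delta_v: float = 4.0  # mV, escape-rate sharpness
    pulse_amp: float = 8.0  # mV, efference-copy pulse
    pulse_dur: float = 0.02  # s

    def __post_init__(self) -> None:
        if min(self.tau_m, self.lambda0, self.delta_v) <= 0:
            raise ValueError("tau_m, lambda0 and delta_v must be positive")

    def e_o2_drive(self, po2: np.ndarray) -> np.ndarray:
        """E_O2 - E_L in mV: zero at normoxia, increasing as pO2 falls."""
        po2 = np.asarray(po2, dtype=float)
        return self.o2_gain_mv * (self.po2_norm / np.maximum(po2, 1e-6) - 1.0)


@dataclass(frozen=True)
class CalciumForward:
    tau_ca: float = 1.5  # s, GCaMP decay
    increment: float = 1.0  # calcium units per spike
    gain: float = 0.2  # dF/F per calcium unit
    f0: float = 100.0  # baseline fluorescence (may be a trace)

    def __post_init__(self) -> None:
        if self.tau_ca <= 0:
            raise ValueError("tau_ca must be positive")
        if np.any(np.asarray(self.f0) <= 0):
            raise ValueError("baseline fluorescence must be positive")


def simulate_neuron(
    params: LifParams,
    po2: np.ndarray,
    pulse_times: np.ndarray,
    dt: float = 0.001,
    seed: int | None = 0,
    pulse_amps: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate V_m and draw spikes; returns (V_m trace, spike times).

    ``po2`` is a per-step trace (mg/L); ``pulse_times`` are efference-copy
    onsets, each delivering a rectangular pulse of ``pulse_amp`` mV (or the
    matching entry of ``pulse_amps``) for ``pulse_dur`` seconds.  Raises if
    the escape rate would violate lambda dt <= 0.5 (refine dt).
    """
    p = params
    po2 = np.asarray(po2, dtype=float)
    n = po2.size
    t = np.arange(n) * dt

    drive = np.zeros(n)
    pulse_times = np.asarray(pulse_times, dtype=float)
    amps = (
        np.full(pulse_times.size, p.pulse_amp)
        if pulse_amps is None
        else np.asarray(pulse_amps, dtype=float)
    )
    width = max(int(round(p.pulse_dur / dt)), 1)
    for t0, a in zip(pulse_times, amps):
        i = int(round(t0 / dt))
        if 0 <= i < n:
            drive[i : i + width] += p.r_input * a

    o2 = p.w_o2 * p.e_o2_drive(po2)
    v = np.empty(n)
    v[0] = p.e_leak + o2[0]
    rng = np.random.default_rng(seed)
    spikes = []
    for k in range(n):
        lam = p.lambda0 * np.exp((v[k] - p.v_thresh) / p.delta_v)
        if lam * dt > 0.5:
            raise ValueError(
                f"escape rate {lam:.1f} Hz violates lambda*dt <= 0.5; refine dt"
            )
        if rng.uniform() < lam * dt:
            spikes.append(t[k])
        if k + 1 < n:
            v[k + 1] = v[k] + dt / p.tau_m * (
                -(v[k] - p.e_leak) + o2[k] + drive[k]
            )
    return v, np.asarray(spikes)


def fluorescence_forward(
    spikes: np.ndarray,
    cal: CalciumForward,
    duration: float,
    dt: float = 0.01,
    f0_trace: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike train -> raw fluorescence F_raw = F0 (1 + gain * C).

    Calcium C jumps by ``increment`` at each spike and decays with
    ``tau_ca``; returns (time, F_raw).
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size > 1 and np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    kicks = np.zeros(n)
    idx = np.round(spikes / dt).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(kicks, idx, cal.increment)
    c = np.empty(n)
    acc = 0.0
    decay = np.exp(-dt / cal.tau_ca)
    for k in range(n):
        acc = acc * decay + kicks[k]
        c[k] = acc
    f0 = np.full(n, cal.f0) if f0_trace is None else np.asarray(f0_trace, dtype=float)
    return t, f0 * (1.0 + cal.gain * c)
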