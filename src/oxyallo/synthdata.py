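"""Fully seeded synthetic oxygen-behavior experiments.

Emulates the standard 40-minute normoxia (8 mg/L) -> hypoxia (4 mg/L)
assay: swim bouts deplete brain pO2 through a delayed first-order oxygen
plant, a 6-kHz fictive-swim electrode channel carries band-limited bursts
whose amplitude scales with bout vigor, a respiration channel carries a
slow pulse train whose rate rises under hypoxia, and a fluorescence matrix
realizes slow-baseline x fast-transient structure across configurable cell
archetypes (hypoxia-excited NTS-like cells, astroglia with 1/pO2 swim
gain, swim-coupled neurons, hypoxia-inhibited cells, ...).

Behavior can be produced by four generators: a reactive controller
(swim probability follows current pO2), the predictive logistic
history-kernel model, the stochastic NE-MO/astroglia circuit
(:mod:`oxyallo.circuitsim`), or the normative delayed controller
(:mod:`oxyallo.controlmodel`).

Every random draw descends from a single recorded seed, so identical
ground truth yields byte-identical arrays, and every ground-truth
parameter (including bout and respiration-event tables) is stored in a
JSON-serializable manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import get_window

from . import circuitsim, controlmodel
from .paradigm import Paradigm, default_paradigm

__all__ = [
    "O2System",
    "Archetype",
    "GroundTruth",
    "Recording",
    "FluorescenceSet",
    "SyntheticExperiment",
    "simulate_po2",
    "synthesize_recording",
    "synthesize_fluorescence",
    "make_experiment",
    "default_archetypes",
]


@dataclass(frozen=True)
class O2System:
    """Delayed first-order brain-oxygen plant (see controlmodel docstring)."""

    alpha: float = 0.1  # 1/s, uptake rate (~10 s recovery)
    beta: float = 0.2  # (mg/L) per unit vigor, consumption scale
    tau_d: float = 2.0  # s, motor-to-oxygen delay

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0 or self.tau_d < 0:
            raise ValueError("beta and tau_d must be non-negative")


def simulate_po2(
    schedule: Paradigm,
    vigor_series: np.ndarray,
    sys: O2System,
    dt: float,
    x0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate brain and bath pO2 given an instantaneous vigor drive.

    Bath pO2 relaxes first-order toward the epoch target; brain pO2 obeys
    dx/dt = alpha (x_bath - x) - beta u(t - tau_d), integrated with an
    exponential (exact for piecewise-constant forcing) update and clipped
    at zero.  Deterministic given its inputs.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.asarray(vigor_series, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("vigor series contains non-finite values")
    if np.any(u < 0):
        raise ValueError("vigor series must be non-negative")
    d = sys.tau_d / dt
    if not np.isclose(d, round(d)):
        raise ValueError("dt must divide the motor-to-oxygen delay tau_d")
    d = int(round(d))

    t = np.arange(u.size) * dt
    bath = schedule.bath_trace(t)
    x = np.empty(u.size)
    x[0] = bath[0] if x0 is None else x0
    decay = np.exp(-sys.alpha * dt)
    for k in range(u.size - 1):
        u_del = u[k - d] if k - d >= 0 else 0.0
        # exact update for constant forcing over the step:
        # x -> x_inf + (x - x_inf) e^{-alpha dt}, x_inf = bath - beta u / alpha
        x_inf = bath[k] - sys.beta * u_del / sys.alpha
        x[k + 1] = max(x_inf + (x[k] - x_inf) * decay, 0.0)
    return x, bath


@dataclass(frozen=True)
class Archetype:
    """A population of cells sharing response structure.

    ``slow_shape`` selects the slow-baseline response to hypoxia:
    ``direct`` tracks -pO2, ``lagged`` is a 120-s filtered version,
    ``adapting`` is biphasic (responds then relaxes), ``drift`` is a slow
    monotone trend, ``flat`` is none.  ``slow_coupling`` scales and signs
    it.  ``po2_gain`` scales swim-evoked transients by po2_norm/pO2 (the
    NE-MO/astroglial hypoxia gain).
    """

    name: str
    n_cells: int = 20
    f0: float = 100.0  # a.u., baseline fluorescence
    slow_coupling: float = 0.0  # signed fractional baseline modulation
    slow_shape: str = "direct"
    fast_gain: float = 0.0  # dF/F per unit vigor drive
    ca_decay: float = 2.0  # s
    po2_gain: bool = False
    center: tuple[float, float, float] = (100.0, 150.0, 50.0)  # um
    spread: float = 15.0  # um

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError(f"archetype {self.name!r} has non-positive baseline")
        if self.slow_shape not in ("direct", "lagged", "adapting", "drift", "flat"):
            raise ValueError(f"unknown slow_shape {self.slow_shape!r}")
        if self.ca_decay <= 0:
            raise ValueError("ca_decay must be positive")


def default_archetypes() -> tuple[Archetype, ...]:
    """Populations emulating the major response classes of the assay."""
    return (
        Archetype("nts", 20, 100.0, 0.5, "direct", 0.25, 1.5, True,
                  (80.0, 160.0, 60.0), 12.0),
        Archetype("astroglia", 20, 120.0, 0.4, "lagged", 0.35, 6.0, True,
                  (100.0, 170.0, 40.0), 18.0),
        Archetype("motor", 20, 90.0, 0.0, "flat", 0.4, 1.5, False,
                  (120.0, 120.0, 55.0), 15.0),
        Archetype("inhibited", 20, 110.0, -0.4, "direct", 0.0, 2.0, False,
                  (60.0, 100.0, 45.0), 20.0),
    )


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator needs; fully recorded in the manifest."""

    generator: str = "circuit"  # reactive | predictive_glm | circuit | controller
    generator_params: dict = field(default_factory=dict)
    o2: O2System = field(default_factory=O2System)
    archetypes: tuple[Archetype, ...] = field(default_factory=default_archetypes)
    fs: float = 6000.0  # Hz, electrode channels
    po2_fs: float = 10.0  # Hz, microelectrode traces (not printed; flagged)
    frame_rate: float = 2.5  # volumes/s, imaging
    swim_snr: float = 20.0  # bout amplitude over swim-channel noise SD
    resp_snr: float = 10.0  # respiration pulse over pink-noise SD
    po2_noise_sd: float = 1.0  # mg/L RMS electrode noise on the raw 10-Hz
    # pO2 channels; the assay's 10-s smoothing reduces it ~10-fold
    resp_rates: tuple[tuple[str, float], ...] = (
        ("normoxia", 1.5),
        ("hypoxia", 2.5),
        ("hyperoxia", 1.2),
    )
    fluo_noise: float = 0.02  # log-normal sigma, multiplicative
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator not in ("reactive", "predictive_glm", "circuit",
                                  "controller"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.fs < 1000:
            raise ValueError("electrode sampling rate must be >= 1 kHz")

    def resp_rate(self, label: str) -> float:
        return dict(self.resp_rates)[label]


@dataclass
class Recording:
    """Synchronized multichannel recording on a common clock."""

    swim: np.ndarray  # a.u. at fs
    resp: np.ndarray  # a.u. at fs
    po2_brain: np.ndarray  # mg/L at po2_fs
    po2_bath: np.ndarray  # mg/L at po2_fs
    fs: float
    po2_fs: float
    schedule: Paradigm

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.swim.size) / self.fs

    @property
    def t_po2(self) -> np.ndarray:
        return np.arange(self.po2_brain.size) / self.po2_fs

    @property
    def duration(self) -> float:
        return self.swim.size / self.fs


@dataclass
class FluorescenceSet:
    """Raw fluorescence matrix with cell coordinates."""

    F: np.ndarray  # cells x time, a.u., > 0
    coords: np.ndarray  # cells x 3, um
    frame_rate: float
    cell_archetype: np.ndarray | None = None  # ground-truth labels

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.F.shape[1]) / self.frame_rate

    @property
    def n_cells(self) -> int:
        return self.F.shape[0]


@dataclass
class SyntheticExperiment:
    recording: Recording
    bouts: pd.DataFrame  # ground truth: onset_s, offset_s, vigor
    resp_events: np.ndarray  # ground-truth respiration times
    fluo: FluorescenceSet
    manifest: dict


# ---------------------------------------------------------------------------
# behavior generators
# ---------------------------------------------------------------------------


def _bouts_from_bins(onsets, rng, vigor, mean_dur=0.18):
    """Assemble a bout table from onset times with lognormal durations."""
    onsets = np.asarray(onsets, dtype=float)
    vigor = np.broadcast_to(np.asarray(vigor, dtype=float), onsets.shape)
    dur = np.clip(
        rng.lognormal(np.log(mean_dur), 0.3, size=onsets.size), 0.06, 0.6
    )
    tbl = pd.DataFrame(
        {"onset_s": onsets, "offset_s": onsets + dur, "vigor": vigor}
    ).sort_values("onset_s", ignore_index=True)
    # enforce non-overlap
    keep = [0] if len(tbl) else []
    for i in range(1, len(tbl)):
        if tbl.onset_s[i] > tbl.offset_s[keep[-1]]:
            keep.append(i)
    return tbl.iloc[keep].reset_index(drop=True)


def _generate_reactive(truth, schedule, rng):
    gp = {"base_rate": 1.2, "x_half": 5.0, "x_scale": 1.0}
    gp.update(truth.generator_params)
    dt = 1.0 / truth.po2_fs
    n = int(round(schedule.duration * truth.po2_fs))
    bath = schedule.bath_trace(np.arange(n) * dt)
    rate = gp["base_rate"] / (1.0 + np.exp(-(bath - gp["x_half"]) / gp["x_scale"]))
    per_bin = int(round(truth.po2_fs))
    onsets, vigors = [], []
    for b in range(n // per_bin):
        p = min(rate[b * per_bin : (b + 1) * per_bin].mean(), 1.0)
        if rng.uniform() < p:
            onsets.append(b + rng.uniform(0, 0.4))
            vigors.append(rng.lognormal(0.0, 0.3))
    return _bouts_from_bins(onsets, rng, np.asarray(vigors))


def _generate_predictive_glm(truth, schedule, rng):
    """Sequential sampling from the logistic history-kernel model."""
    gp = {
        "swim_kernel": [0.6, 0.3, -0.3, -0.4, -0.4, -0.3, -0.2, -0.1, -0.1],
        "o2_kernel": [0.5, 0.3, 0.2, 0.1, 0.1, 0.0, 0.0, 0.0, 0.0],
        "offset": -0.2,
    }
    gp.update(truth.generator_params)
    a = np.asarray(gp["swim_kernel"], dtype=float)  # lags 1..9
    b = np.asarray(gp["o2_kernel"], dtype=float)  # lags 0..8
    n_bins = int(schedule.duration)
    bath = schedule.bath_trace(np.arange(n_bins) + 0.5)
    z = (bath - bath.mean()) / bath.std() if bath.std() > 0 else bath * 0.0
    swim = np.zeros(n_bins, dtype=int)
    onsets, vigors = [], []
    for tb in range(n_bins):
        hist_s = sum(
            a[s - 1] * swim[tb - s] for s in range(1, 10) if tb - s >= 0
        )
        hist_o = sum(b[s] * z[tb - s] for s in range(0, 9) if tb - s >= 0)
        p = 1.0 / (1.0 + np.exp(-(hist_s + hist_o + gp["offset"])))
        if rng.uniform() < p:
            swim[tb] = 1
            onsets.append(tb + rng.uniform(0, 0.4))
            vigors.append(rng.lognormal(0.0, 0.3))
    return _bouts_from_bins(onsets, rng, np.asarray(vigors))


def _generate_circuit(truth, schedule, rng):
    gp = dict(truth.generator_params)
    params = gp.pop("params", circuitsim.CircuitParams())
    n = int(round(schedule.duration / params.dt))
    labels = schedule.label_at(np.arange(n) * params.dt)
    gains = np.where(labels == "hypoxia", params.f_po2_hypoxia,
                     params.f_po2_normoxia)
    trace = circuitsim.simulate(
        params,
        duration=schedule.duration,
        condition=gains,
        seed=int(rng.integers(2**31)),
    )
    return trace.bouts.astype({"vigor": float})


def _generate_controller(truth, schedule, rng):
    gp = dict(truth.generator_params)
    base = gp.pop("system", None) or controlmodel.ControlSystem(
        alpha=truth.o2.alpha, beta=truth.o2.beta, tau=truth.o2.tau_d
    )
    dt = 0.1
    n = int(round(schedule.duration / dt))
    env = schedule.bath_trace(np.arange(n) * dt)
    # the law adapts per epoch (the animal re-solves for the new environment)
    u = np.empty(n)
    x_state: float | None = None
    for ep in schedule.epochs:
        sys_ep = dataclasses.replace(base, x_env=ep.bath_o2)
        law = controlmodel.derive_law(sys_ep)
        k0 = int(round(ep.start / dt))
        k1 = int(round(ep.end / dt))
        tr = controlmodel.simulate_closed_loop(
            sys_ep, law, duration=(k1 - k0) * dt, dt=dt,
            x0=x_state, clip_u=True, x_env=env[k0:k1],
        )
        u[k0:k1] = tr.u
        x_state = float(tr.x[-1])
    onsets = controlmodel.behavior_bridge(
        u, dt, seed=int(rng.integers(2**31)), rate_scale=1.0
    )
    idx = np.minimum((onsets / dt).astype(int), n - 1)
    vigors = np.maximum(u[idx], 0.1)
    return _bouts_from_bins(onsets, rng, vigors)


_GENERATORS = {
    "reactive": _generate_reactive,
    "predictive_glm": _generate_predictive_glm,
    "circuit": _generate_circuit,
    "controller": _generate_controller,
}


# ---------------------------------------------------------------------------
# channel synthesis
# ---------------------------------------------------------------------------


def rasterize_vigor(
    bouts: pd.DataFrame, duration: float, dt: float, smooth_s: float = 0.0
) -> np.ndarray:
    """Instantaneous vigor drive: each bout contributes vigor/duration over
    its extent, so the time integral equals total vigor.

    With ``smooth_s`` > 0 the drive is additionally convolved with a
    normalized exponential kernel of that time constant, spreading each
    bout's oxygen cost over the following seconds (tissues keep consuming
    oxygen after movement stops); the integral is preserved.
    """
    n = int(round(duration / dt))
    u = np.zeros(n)
    for onset, offset, vigor in bouts[["onset_s", "offset_s", "vigor"]].values:
        i0 = int(round(onset / dt))
        i1 = max(int(round(offset / dt)), i0 + 1)
        u[i0 : min(i1, n)] += vigor / ((i1 - i0) * dt)
    if smooth_s > 0:
        kern = np.exp(-np.arange(int(6 * smooth_s / dt) + 1) * dt / smooth_s)
        kern /= kern.sum()
        u = np.convolve(u, kern)[:n]
    return u


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / out.std()


def _swim_channel(bouts, truth, n, rng):
    """300-Hz carrier bursts with 10-ms raised-cosine (Tukey) ramps."""
    fs = truth.fs
    sig = np.zeros(n)
    carrier_hz = 300.0
    for onset, offset, vigor in bouts[["onset_s", "offset_s", "vigor"]].values:
        i0 = int(round(onset * fs))
        i1 = min(int(round(offset * fs)), n)
        m = i1 - i0
        if m <= 0:
            continue
        ramp = min(2 * 0.010 * fs / m, 1.0)  # 10-ms ramps as a Tukey fraction
        env = get_window(("tukey", ramp), m, fftbins=False)
        tt = np.arange(m) / fs
        sig[i0:i1] += vigor * env * np.sin(2 * np.pi * carrier_hz * tt)
    noise_sd = 1.0 / truth.swim_snr
    return sig + noise_sd * rng.standard_normal(n)


def _resp_events(bouts, truth, schedule, rng):
    """Inhomogeneous respiration event train, excluded from swim bouts."""
    events = []
    t = 0.0
    min_gap = 0.25
    while t < schedule.duration:
        label = str(schedule.label_at(t)[0])
        rate = truth.resp_rate(label)
        t += max(rng.exponential(1.0 / rate), min_gap)
        if t >= schedule.duration:
            break
        inside = np.any(
            (bouts["onset_s"].values - 0.08 <= t)
            & (t <= bouts["offset_s"].values + 0.08)
        )
        if not inside:
            events.append(t)
    return np.asarray(events)


def _resp_channel(events, truth, n, rng):
    fs = truth.fs
    sig = np.zeros(n)
    sigma = 0.03  # s, respiration pulse width
    half = int(4 * sigma * fs)
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / (sigma * fs)) ** 2)
    for ev in events:
        i = int(round(ev * fs))
        lo, hi = max(i - half, 0), min(i + half + 1, n)
        sig[lo:hi] += kernel[lo - (i - half) : hi - (i - half)]
    return sig + (1.0 / truth.resp_snr) * _pink_noise(n, rng)


def synthesize_recording(
    truth: GroundTruth, schedule: Paradigm | None = None
) -> tuple[Recording, pd.DataFrame, dict]:
    """Generate ground-truth behavior and raw channels; returns
    (recording, bout table, manifest)."""
    schedule = schedule or default_paradigm()
    ss = np.random.SeedSequence(truth.seed)
    rng_beh, rng_swim, rng_resp, rng_fluo, rng_meas = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    bouts = _GENERATORS[truth.generator](truth, schedule, rng_beh)
    if len(bouts) > 1 and np.any(
        bouts["onset_s"].values[1:] < bouts["offset_s"].values[:-1]
    ):
        raise ValueError("ground-truth bouts overlap")

    dt_po2 = 1.0 / truth.po2_fs
    u = rasterize_vigor(bouts, schedule.duration, dt_po2, smooth_s=2.0)
    po2_brain, po2_bath = simulate_po2(schedule, u, truth.o2, dt_po2)

    n = int(round(schedule.duration * truth.fs))
    swim = _swim_channel(bouts, truth, n, rng_swim)
    resp_events = _resp_events(bouts, truth, schedule, rng_resp)
    resp = _resp_channel(resp_events, truth, n, rng_resp)

    sd = truth.po2_noise_sd
    recording = Recording(
        swim=swim,
        resp=resp,
        po2_brain=np.maximum(
            po2_brain + sd * rng_meas.standard_normal(po2_brain.size), 0.0
        ),
        po2_bath=np.maximum(
            po2_bath + sd * rng_meas.standard_normal(po2_bath.size), 0.0
        ),
        fs=truth.fs,
        po2_fs=truth.po2_fs,
        schedule=schedule,
    )
    manifest = build_manifest(truth, schedule, bouts, resp_events)
    return recording, bouts, manifest


def _slow_response(shape: str, hyp: np.ndarray, frame_rate: float) -> np.ndarray:
    """Unit slow-response trace for an archetype given normalized hypoxia."""
    if shape == "flat":
        return np.zeros_like(hyp)
    if shape == "direct":
        return hyp
    if shape == "lagged":
        tau_f = 120.0 * frame_rate  # frames
        out = np.empty_like(hyp)
        acc = hyp[0]
        a = 1.0 / tau_f
        for k, h in enumerate(hyp):
            acc += a * (h - acc)
            out[k] = acc
        return out
    if shape == "adapting":
        lag = _slow_response("lagged", hyp, frame_rate)
        return hyp - 0.8 * lag
    if shape == "drift":
        t = np.linspace(0.0, 1.0, hyp.size)
        return t
    raise ValueError(shape)


def synthesize_fluorescence(
    truth: GroundTruth,
    bouts: pd.DataFrame,
    po2: np.ndarray,
    schedule: Paradigm | None = None,
    rng: np.random.Generator | None = None,
) -> FluorescenceSet:
    """Build F = baseline(t) * (1 + transient(t)) * noise per archetype.

    The baseline couples (with the archetype's sign and shape) to
    normalized hypoxia; transients are vigor impulses convolved with an
    exponential calcium kernel, with an optional po2_norm/pO2 gain.
    Multiplicative log-normal noise keeps F > 0.
    """
    schedule = schedule or default_paradigm()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(4)[3])
    if len(bouts) and bouts["offset_s"].max() > schedule.duration + 1.0:
        raise ValueError("bouts extend past the recording span")

    fr = truth.frame_rate
    n_frames = int(round(schedule.duration * fr))
    t_f = np.arange(n_frames) / fr
    x_ref = schedule.epochs[0].bath_o2
    po2_f = np.interp(t_f, np.arange(po2.size) / truth.po2_fs, po2)
    hyp = (x_ref - po2_f) / x_ref  # normalized hypoxia, 0 in equilibrated normoxia

    # vigor impulse train at frame resolution
    v_f = np.zeros(n_frames)
    for onset, vigor in bouts[["onset_s", "vigor"]].values:
        i = int(onset * fr)
        if 0 <= i < n_frames:
            v_f[i] += vigor
    gain_f = x_ref / np.maximum(po2_f, 0.1 * x_ref)

    F_rows, coords, labels = [], [], []
    for arch in truth.archetypes:
        s_t = _slow_response(arch.slow_shape, hyp, fr)
        kern = np.exp(-np.arange(int(5 * arch.ca_decay * fr) + 1) / (arch.ca_decay * fr))
        drive = v_f * (gain_f if arch.po2_gain else 1.0)
        trans_t = np.convolve(drive, kern)[:n_frames]
        for _ in range(arch.n_cells):
            f0 = arch.f0 * rng.lognormal(0.0, 0.1)
            c_slow = arch.slow_coupling * rng.uniform(0.8, 1.2)
            gain = arch.fast_gain * rng.uniform(0.8, 1.2)
            baseline = f0 * (1.0 + c_slow * s_t)
            if np.any(baseline <= 0):
                raise ValueError(
                    f"archetype {arch.name!r} yields non-positive baseline"
                )
            noise = rng.lognormal(
                -0.5 * truth.fluo_noise**2, truth.fluo_noise, n_frames
            )
            F_rows.append(baseline * (1.0 + gain * trans_t) * noise)
            coords.append(rng.normal(arch.center, arch.spread))
            labels.append(arch.name)

    return FluorescenceSet(
        F=np.asarray(F_rows),
        coords=np.asarray(coords),
        frame_rate=fr,
        cell_archetype=np.asarray(labels),
    )


def build_manifest(truth, schedule, bouts, resp_events) -> dict:
    return {
        "seed": truth.seed,
        "generator": truth.generator,
        "generator_params": {
            k: v for k, v in truth.generator_params.items()
            if isinstance(v, (int, float, str, list, tuple))
        },
        "o2": dataclasses.asdict(truth.o2),
        "archetypes": [dataclasses.asdict(a) for a in truth.archetypes],
        "fs": truth.fs,
        "po2_fs": truth.po2_fs,
        "po2_fs_note": "brain-pO2 sampling rate not printed in the assay; 10 Hz default",
        "frame_rate": truth.frame_rate,
        "swim_snr": truth.swim_snr,
        "resp_snr": truth.resp_snr,
        "po2_noise_sd": truth.po2_noise_sd,
        "resp_rates": dict(truth.resp_rates),
        "fluo_noise": truth.fluo_noise,
        "schedule": [dataclasses.asdict(e) for e in schedule.epochs],
        "mixing_tau": schedule.mixing_tau,
        "bouts": bouts.to_dict(orient="list"),
        "resp_events": list(map(float, resp_events)),
    }


def true_po2(
    truth: GroundTruth, bouts: pd.DataFrame, schedule: Paradigm
) -> np.ndarray:
    """Noiseless brain pO2 implied by the ground-truth behavior."""
    dt = 1.0 / truth.po2_fs
    u = rasterize_vigor(bouts, schedule.duration, dt, smooth_s=2.0)
    return simulate_po2(schedule, u, truth.o2, dt)[0]


def make_experiment(
    truth: GroundTruth | None = None, schedule: Paradigm | None = None
) -> SyntheticExperiment:
    """Full synthetic experiment: behavior, channels, pO2 and fluorescence.

    Fluorescence is driven by the true (noiseless) brain pO2; the stored
    recording channels carry electrode measurement noise.
    """
    truth = truth or GroundTruth()
    schedule = schedule or default_paradigm()
    recording, bouts, manifest = synthesize_recording(truth, schedule)
    rng_fluo = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(5)[3])
    fluo = synthesize_fluorescence(
        truth, bouts, true_po2(truth, bouts, schedule), schedule, rng=rng_fluo
    )
    return SyntheticExperiment(
        recording=recording,
        bouts=bouts,
        resp_events=np.asarray(manifest["resp_events"]),
        fluo=fluo,
        manifest=manifest,
    )
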