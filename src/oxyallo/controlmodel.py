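"""Normative delayed control of brain oxygen.

Brain oxygen x(t) (mg/L) is replenished from the environment at uptake
rate alpha and consumed by swimming u(t) with a motor-to-oxygen delay tau:

    dx/dt = alpha (x_env - x(t)) - beta u(t - tau)

The animal is modelled as minimizing the infinite-horizon quadratic cost

    J = \\int gamma (x - x_set)^2 + (u - u_base)^2 dt

trading off hypoxic deviation from a setpoint ``x_set`` against deviation
from a baseline swim rate ``u_base`` (fish should neither stop swimming
nor thrash).

Analytic law
------------
Because the delayed system is a scalar linear ODE, the classical predictor
reduction applies exactly: the tau-ahead prediction

    z(t) = x(t + tau)
         = e^{-alpha tau} x(t) + x_env (1 - e^{-alpha tau})
           - beta \\int_0^tau e^{-alpha theta} u(t - theta) dtheta

satisfies the *delay-free* dynamics dz/dt = alpha(x_env - z) - beta u(t),
so the optimal controller is the scalar affine LQR applied to z.  Solving
the algebraic Riccati equation gives

    K = sqrt(alpha^2 + beta^2 gamma) - alpha        (integral-kernel gain)

and the optimal feedback, written in the delayed coordinates, is

    u*(t) = -{ (K/beta) e^{-alpha tau} (x_set - x(t))
               + K \\int_0^tau e^{-alpha theta} u(t - theta) dtheta } + C

with the constant

    C = u_base - (K/beta) [ (1 - e^{-alpha tau})(x_set - x_env) + h_k / s ],

where h_k = alpha (x_set - x_env) + beta u_base and
s = sqrt(alpha^2 + beta^2 gamma).  C decreases as the environment level
x_env falls: deeper environmental hypoxia lowers the natural swim rate.
The swim-history integral is the predictive component; dropping it leaves
a purely reactive controller that is strictly suboptimal whenever tau > 0.

A numerical optimal-control oracle (:meth:`DelayedOxygenControl.solve_oracle`)
solves the same problem by backward Riccati recursion on the discrete-time
system augmented with the delay buffer, and is used to validate the
analytic gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ControlSystem",
    "ControllerLaw",
    "OracleLaw",
    "ControlTrace",
    "DelayedOxygenControl",
    "derive_law",
    "solve_oracle",
    "simulate_closed_loop",
    "behavior_bridge",
]


@dataclass(frozen=True)
class ControlSystem:
    """Parameters of the delayed oxygen plant and its cost functional."""

    alpha: float = 0.1  # 1/s, oxygen uptake rate (~10 s recovery)
    beta: float = 0.2  # (mg/L)/swim-unit/s, consumption per unit swim rate
    tau: float = 2.0  # s, motor-to-oxygen delay
    x_env: float = 8.0  # mg/L, environment (bath) level
    x_set: float = 8.0  # mg/L, desired oxygen level
    u_base: float = 1.0  # swim-units, baseline CPG swim rate
    gamma: float = 1.0  # weight on the oxygen term of the cost

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0 or self.tau < 0:
            raise ValueError("beta and tau must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def h_k(self) -> float:
        """Operating-point imbalance alpha (x_set - x_env) + beta u_base."""
        return self.alpha * (self.x_set - self.x_env) + self.beta * self.u_base


@dataclass(frozen=True)
class ControllerLaw:
    """The analytic delayed-feedback law u*(t)."""

    K: float
    C: float
    alpha: float
    beta: float
    tau: float
    x_set: float

    def control(self, x: float, u_history: np.ndarray, dt: float) -> float:
        """Evaluate u*(t) from the current state and the delay buffer.

        ``u_history`` holds u(t - dt), ..., u(t - tau) (most recent first);
        the delay integral uses the trapezoidal rule on [0, tau], taking
        u(t - 0) ~ u(t - dt) for the open endpoint.
        """
        d = int(round(self.tau / dt))
        if d == 0:
            integral = 0.0
        else:
            theta = np.arange(d + 1) * dt
            u_vals = np.concatenate([[u_history[0]], u_history[:d]])
            integral = np.trapezoid(np.exp(-self.alpha * theta) * u_vals, dx=dt)
        state_term = (
            (self.K / self.beta) * np.exp(-self.alpha * self.tau) * (self.x_set - x)
            if self.beta > 0
            else 0.0
        )
        return float(-(state_term + self.K * integral) + self.C)


def derive_law(sys: ControlSystem) -> ControllerLaw:
    """Optimal law via the predictor reduction (see module docstring)."""
    s = np.sqrt(sys.alpha**2 + sys.beta**2 * sys.gamma)
    K = s - sys.alpha
    if sys.beta == 0:
        # swimming is costless to oxygen: the cost decouples and u = u_base
        return ControllerLaw(K=0.0, C=sys.u_base, alpha=sys.alpha, beta=sys.beta,
                             tau=sys.tau, x_set=sys.x_set)
    ea = np.exp(-sys.alpha * sys.tau)
    C = sys.u_base - (K / sys.beta) * (
        (1.0 - ea) * (sys.x_set - sys.x_env) + sys.h_k / s
    )
    return ControllerLaw(K=float(K), C=float(C), alpha=sys.alpha, beta=sys.beta,
                         tau=sys.tau, x_set=sys.x_set)


@dataclass
class OracleLaw:
    """Stationary affine feedback from the discrete-time Riccati recursion.

    u_k = -(f_x x_k + sum_i f_i u_{k-i}) + c  over the delay buffer.
    """

    f_x: float
    f_u: np.ndarray  # weights on u(t-dt) ... u(t-tau)
    c: float
    dt: float
    converged: bool
    iterations: int

    def control(self, x: float, u_history: np.ndarray, dt: float) -> float:
        if not np.isclose(dt, self.dt):
            raise ValueError("oracle law was solved at a different dt")
        d = len(self.f_u)
        acc = self.f_x * x
        if d:
            acc += float(np.dot(self.f_u, u_history[:d]))
        return float(-acc + self.c)


def solve_oracle(
    sys: ControlSystem,
    dt: float = 0.05,
    max_iter: int = 200_000,
    tol: float = 1e-11,
) -> OracleLaw:
    """Numerically optimal feedback by backward Riccati recursion.

    The state is augmented with the tau/dt-length delay buffer and a
    constant-1 coordinate that carries the affine terms; the backward
    recursion is iterated until the feedback row is stationary.  The value
    function's constant offset diverges for x_env != x_set (the running
    cost has a nonzero floor); only the feedback row is required to
    converge.
    """
    d = int(round(sys.tau / dt))
    if not np.isclose(d * dt, sys.tau):
        raise ValueError("dt must divide tau")
    n = 1 + d + 1  # x, delay buffer, constant
    A = np.zeros((n, n))
    B = np.zeros((n, 1))
    # x_{k+1} = (1 - alpha dt) x_k + alpha dt x_env - beta dt u_{k-d}
    A[0, 0] = 1.0 - sys.alpha * dt
    A[0, n - 1] = sys.alpha * dt * sys.x_env
    if d > 0:
        A[0, d] = -sys.beta * dt  # oldest buffer slot holds u_{k-d}
        for i in range(1, d):
            A[i + 1, i] = 1.0  # buffer shift
        B[1, 0] = 1.0  # u_k enters the newest slot
    else:
        B[0, 0] = -sys.beta * dt
    A[n - 1, n - 1] = 1.0

    # stage cost dt * [gamma (x - x_set)^2 + (u - u_base)^2]
    Q = np.zeros((n, n))
    Q[0, 0] = sys.gamma
    Q[0, n - 1] = Q[n - 1, 0] = -sys.gamma * sys.x_set
    Q[n - 1, n - 1] = sys.gamma * sys.x_set**2 + sys.u_base**2
    Q *= dt
    N = np.zeros((n, 1))
    N[n - 1, 0] = -sys.u_base * dt
    R = np.array([[dt]])

    P = Q.copy()
    F_prev = np.zeros((1, n))
    converged = False
    it = 0
    # information flows from x back through the delay buffer only after
    # ~d backward steps, so the feedback row is constant (and meaningless)
    # for the first d iterations; don't test stationarity before that
    min_iter = 2 * d + 50
    for it in range(1, max_iter + 1):
        BtP = B.T @ P
        F = np.linalg.solve(R + BtP @ B, BtP @ A + N.T)
        ABF = A - B @ F
        P = Q + F.T @ R @ F - N @ F - (N @ F).T + ABF.T @ P @ ABF
        P = 0.5 * (P + P.T)
        # the (const, const) entry accumulates the running cost floor;
        # freeze it so P stays bounded (it does not affect the policy)
        P[n - 1, n - 1] = min(P[n - 1, n - 1], 1e12)
        if it > min_iter and np.max(np.abs(F - F_prev)) < tol:
            converged = True
            break
        F_prev = F
    F = F.ravel()
    return OracleLaw(
        f_x=float(F[0]),
        f_u=F[1 : d + 1].copy() if d > 0 else np.zeros(0),
        c=float(-F[-1]),
        dt=dt,
        converged=converged,
        iterations=it,
    )


@dataclass
class ControlTrace:
    """Closed-loop trajectory with realized quadratic cost."""

    t: np.ndarray
    x: np.ndarray
    u: np.ndarray
    cost: float
    diverged: bool = False


def simulate_closed_loop(
    sys: ControlSystem,
    law,
    duration: float = 600.0,
    dt: float = 0.05,
    x0: float | None = None,
    clip_u: bool = False,
    x_env: np.ndarray | None = None,
) -> ControlTrace:
    """Euler-integrate the plant under a feedback law.

    ``law`` is anything with ``control(x, u_history, dt)`` (analytic,
    oracle, or ablated).  The delay buffer is initialized at ``u_base``.
    ``clip_u`` enforces u >= 0 (swim rates cannot be negative); leave off
    when comparing against the unclipped optimal laws.  ``x_env`` may be a
    per-step array for time-varying environments.
    """
    d = int(round(sys.tau / dt))
    if not np.isclose(d * dt, sys.tau):
        raise ValueError("dt must divide tau")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    env = np.full(n, sys.x_env) if x_env is None else np.asarray(x_env, dtype=float)
    if env.size != n:
        raise ValueError("x_env array length mismatch")

    x = np.empty(n)
    u = np.empty(n)
    x[0] = sys.x_env if x0 is None else x0
    # u_history[0] = u(t - dt), ..., u_history[d-1] = u(t - d dt)
    u_history = np.full(max(d, 1), sys.u_base)
    cost = 0.0
    diverged = False
    for k in range(n):
        uk = law.control(x[k], u_history, dt)
        if clip_u:
            uk = max(uk, 0.0)
        u[k] = uk
        cost += dt * (sys.gamma * (x[k] - sys.x_set) ** 2 + (uk - sys.u_base) ** 2)
        u_delayed = u_history[d - 1] if d > 0 else uk
        if k + 1 < n:
            x[k + 1] = x[k] + dt * (sys.alpha * (env[k] - x[k]) - sys.beta * u_delayed)
            if not np.isfinite(x[k + 1]) or abs(x[k + 1]) > 1e6:
                diverged = True
                x[k + 1 :] = x[k]
                u[k + 1 :] = uk
                break
        if d > 0:
            u_history = np.concatenate([[uk], u_history[:-1]])
    return ControlTrace(t=t, x=x, u=u, cost=float(cost), diverged=diverged)


@dataclass
class ReactiveAblation:
    """The analytic law with its swim-history (predictive) integral removed."""

    law: ControllerLaw

    def control(self, x: float, u_history: np.ndarray, dt: float) -> float:
        if self.law.beta == 0:
            return self.law.C
        state_term = (
            (self.law.K / self.law.beta)
            * np.exp(-self.law.alpha * self.law.tau)
            * (self.law.x_set - x)
        )
        return float(-state_term + self.law.C)


def behavior_bridge(
    u: np.ndarray,
    dt: float,
    seed: int | None = 0,
    bin_s: float = 1.0,
    rate_scale: float = 1.0,
) -> np.ndarray:
    """Thin a continuous swim rate into discrete bout onsets.

    Per 1-s bin, a bout occurs with probability proportional to the bin-mean
    of u (clipped to [0, 1]); the onset is jittered uniformly in the bin.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("u must be non-negative; clip before bridging")
    rng = np.random.default_rng(seed)
    per_bin = int(round(bin_s / dt))
    n_bins = u.size // per_bin
    onsets = []
    for b in range(n_bins):
        p = float(np.clip(u[b * per_bin : (b + 1) * per_bin].mean()
                          * rate_scale * bin_s, 0.0, 1.0))
        if rng.uniform() < p:
            onsets.append(b * bin_s + rng.uniform(0.0, 0.5 * bin_s))
    return np.asarray(onsets)


def simulate_stochastic_behavior(
    sys: ControlSystem,
    law,
    duration: float = 2400.0,
    dt: float = 0.1,
    bin_s: float = 1.0,
    seed: int | None = 0,
    consumption_smooth_s: float = 2.0,
    rate_noise: float = 0.1,
    env_noise_sd: float = 0.1,
    env_noise_tau: float = 30.0,
) -> tuple[np.ndarray, ControlTrace]:
    """Closed-loop behavior generation: the controller's rate is thinned
    into discrete bouts, and both the plant and the controller's own
    swim-history integral see the *realized* bouts (efference copies of
    actual actions), not the underlying rate.

    Returns (bout onset times, ControlTrace of x and the realized vigor
    drive).  This is the generative process whose behavior the logistic
    history-kernel models are fitted to.

    The environment level fluctuates around ``x_env`` as an
    Ornstein-Uhlenbeck process (sd ``env_noise_sd`` mg/L, correlation time
    ``env_noise_tau``), emulating the spontaneous bath/brain pO2
    fluctuations seen in real preparations; per-bin motor noise
    (``rate_noise``) perturbs the thinning rate.
    """
    d = int(round(sys.tau / dt))
    per_bin = int(round(bin_s / dt))
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    # exponential spreading of each bout's oxygen cost (tissues keep
    # consuming after the movement): kernel integrates to 1
    kern_len = int(6 * consumption_smooth_s / dt) + 1
    kern = np.exp(-np.arange(kern_len) * dt / consumption_smooth_s)
    kern /= kern.sum() * dt

    x = np.empty(n)
    u_real = np.zeros(n + kern_len)
    x[0] = sys.x_env
    u_hist = np.full(max(d, 1), sys.u_base)  # realized vigor, newest first
    onsets: list[float] = []
    u_rate = np.empty(n)
    env = sys.x_env
    a_env = np.exp(-dt / env_noise_tau)
    sd_step = env_noise_sd * np.sqrt(1.0 - a_env**2)
    for k in range(n):
        u_rate[k] = max(law.control(x[k], u_hist, dt), 0.0)
        if k % per_bin == 0:
            # per-bin motor noise keeps the thinning rate proportional to u
            # on average while avoiding a deterministic zero-rate region
            noisy = u_rate[k] + rate_noise * rng.standard_normal()
            p = float(np.clip(noisy * bin_s, 0.0, 1.0))
            if rng.uniform() < p:
                onsets.append(k * dt + rng.uniform(0, 0.4 * bin_s))
                u_real[k : k + kern_len] += kern
        if k + 1 < n:
            env = sys.x_env + a_env * (env - sys.x_env) \
                + sd_step * rng.standard_normal()
            u_delayed = u_hist[d - 1] if d > 0 else u_real[k]
            x[k + 1] = max(
                x[k] + dt * (sys.alpha * (env - x[k])
                             - sys.beta * u_delayed),
                0.0,
            )
        if d > 0:
            u_hist = np.concatenate([[u_real[k]], u_hist[:-1]])
    trace = ControlTrace(t=np.arange(n) * dt, x=x, u=u_real[:n], cost=np.nan)
    return np.asarray(onsets), trace


def controller_glm_dataset(
    sys: ControlSystem | None = None,
    duration: float = 3000.0,
    seed: int | None = 0,
    po2_fs: float = 10.0,
    po2_noise_sd: float = 1.0,
):
    """Reference behavioral dataset for the predictive/reactive model
    comparison: closed-loop controller behavior plus the electrode-style
    pO2 measurement (raw noise ``po2_noise_sd`` mg/L at ``po2_fs``).

    Returns (bout table, measured raw pO2 at po2_fs, ControlTrace).
    """
    import pandas as pd  # local import keeps module deps light

    sys = sys or ControlSystem()
    law = derive_law(sys)
    onsets, trace = simulate_stochastic_behavior(
        sys, law, duration=duration, seed=seed
    )
    bouts = pd.DataFrame(
        {"onset_s": onsets, "offset_s": onsets + 0.2,
         "vigor": np.ones(onsets.size)}
    )
    rng = np.random.default_rng(None if seed is None else seed + 7919)
    n = int(round(duration * po2_fs))
    po2 = np.interp(np.arange(n) / po2_fs, trace.t, trace.x)
    po2 = np.maximum(po2 + po2_noise_sd * rng.standard_normal(n), 0.0)
    return bouts, po2, trace


class DelayedOxygenControl:
    """Model object bundling the plant, its analytic solution and the oracle.

    Examples
    --------
    >>> model = DelayedOxygenControl(ControlSystem(x_env=4.0))
    >>> law = model.solve()
    >>> trace = model.simulate(law, duration=300.0)
    """

    def __init__(self, system: ControlSystem | None = None):
        self.system = system or ControlSystem()

    def solve(self) -> ControllerLaw:
        return derive_law(self.system)

    def solve_oracle(self, dt: float = 0.05, **kwargs) -> OracleLaw:
        return solve_oracle(self.system, dt=dt, **kwargs)

    def reactive_ablation(self) -> ReactiveAblation:
        return ReactiveAblation(self.solve())

    def simulate(self, law=None, duration: float = 600.0, dt: float = 0.05,
                 **kwargs) -> ControlTrace:
        return simulate_closed_loop(
            self.system, law or self.solve(), duration=duration, dt=dt, **kwargs
        )
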