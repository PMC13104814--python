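"""Logistic history-kernel models of swim actions.

The probability of a swim action in a 1-s bin is modelled as

    P(swim(t)) = 1 / (1 + exp(-y)),
    y = sum_{s=1..9} alpha_s swim(t-s) + sum_{s=0..8} beta_s pO2(t-s) + beta

The *predictive* variant uses both the swim-history kernel alpha (the
animal's own recent actions, from which self-generated oxygen debt can be
anticipated) and the oxygen kernel beta; the *reactive* variant uses the
oxygen history alone.  Goodness of fit is the pseudo variance explained
r^2 = 1 - ln(L_M)/ln(L_0) against the offset-only null.  Fits are
maximum-likelihood logistic regressions (IRLS); on detected separation
the fit is repeated with a tiny ridge and flagged.  Regressors are
z-scored per condition, so kernels are reported in standardized units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .paradigm import Paradigm

__all__ = [
    "GlmDesign",
    "SwimGlmResults",
    "SwimHistoryGLM",
    "build_design",
    "fit_glm",
    "pseudo_r2",
]

SWIM_LAGS = range(1, 10)  # t-1 ... t-9
O2_LAGS = range(0, 9)  # t ... t-8


@dataclass
class GlmDesign:
    """Binned binary swim series and lagged regressors per condition."""

    frames: dict  # condition -> DataFrame (response 'swim', lagged columns)
    bin_s: float = 1.0

    def conditions(self) -> list[str]:
        return list(self.frames)


def build_design(
    bouts: pd.DataFrame,
    po2: np.ndarray,
    po2_fs: float,
    schedule: Paradigm,
    bin_s: float = 1.0,
    occupancy: bool = False,
    standardize: bool = True,
) -> GlmDesign:
    """Bin behavior and oxygen at 1 s and build the lagged design.

    ``swim(t)`` is 1 iff at least one bout onset falls in the bin (or, with
    ``occupancy=True``, iff any bout overlaps the bin); pO2 bins average the
    (already smoothed) trace.  Rows whose history window crosses a
    condition boundary or the recording start are dropped; conditions are
    modelled separately.
    """
    po2 = np.asarray(po2, dtype=float)
    n_bins = int(schedule.duration / bin_s)
    edges = np.arange(n_bins + 1) * bin_s
    onsets = bouts["onset_s"].values if len(bouts) else np.array([])
    if occupancy and len(bouts):
        swim = np.zeros(n_bins, dtype=int)
        for a, b in bouts[["onset_s", "offset_s"]].values:
            swim[int(a / bin_s) : int(b / bin_s) + 1] = 1
        swim = swim[:n_bins]
    else:
        swim = (np.histogram(onsets, bins=edges)[0] > 0).astype(int)

    t_po2 = np.arange(po2.size) / po2_fs
    po2_bin = np.array(
        [po2[(t_po2 >= e0) & (t_po2 < e1)].mean() for e0, e1 in
         zip(edges[:-1], edges[1:])]
    )
    if np.any(~np.isfinite(po2_bin)):
        raise ValueError("NaN in binned pO2 (trace shorter than the schedule?)")

    bin_label = schedule.label_at(edges[:-1] + bin_s / 2)
    max_lag = max(SWIM_LAGS)
    frames: dict[str, pd.DataFrame] = {}
    for cond in dict.fromkeys(bin_label):  # preserve order
        rows = {"swim": [], "t_bin": []}
        for s in SWIM_LAGS:
            rows[f"swim_lag{s}"] = []
        for s in O2_LAGS:
            rows[f"po2_lag{s}"] = []
        for tb in range(n_bins):
            if bin_label[tb] != cond or tb < max_lag:
                continue
            if np.any(bin_label[tb - max_lag : tb + 1] != cond):
                continue  # history crosses a condition boundary
            rows["swim"].append(swim[tb])
            rows["t_bin"].append(tb)
            for s in SWIM_LAGS:
                rows[f"swim_lag{s}"].append(swim[tb - s])
            for s in O2_LAGS:
                rows[f"po2_lag{s}"].append(po2_bin[tb - s])
        df = pd.DataFrame(rows)
        if standardize:  # z-score regressors within condition
            for col in df.columns:
                if col in ("swim", "t_bin"):
                    continue
                sd = df[col].std(ddof=0)
                df[col] = (df[col] - df[col].mean()) / sd if sd > 0 else 0.0
        frames[cond] = df
    return GlmDesign(frames=frames, bin_s=bin_s)


def pseudo_r2(llf: float, llf_null: float) -> float:
    """Pseudo variance explained 1 - ln(L_M)/ln(L_0)."""
    if not (np.isfinite(llf) and np.isfinite(llf_null)):
        raise ValueError("likelihoods must be finite")
    if llf_null == 0:
        raise ValueError("perfectly predictable null; pseudo-r2 undefined")
    return 1.0 - llf / llf_null


@dataclass
class SwimGlmResults:
    """Fitted kernels, likelihoods, and pseudo variance explained."""

    variant: str
    condition: str | None
    params: pd.Series
    bse: pd.Series
    llf: float
    llf_null: float
    n_obs: int
    converged: bool
    ridged: bool  # separation detected; tiny-ridge refit

    @property
    def pseudo_r2(self) -> float:
        return pseudo_r2(self.llf, self.llf_null)

    @property
    def swim_kernel(self) -> np.ndarray:
        return np.array(
            [self.params.get(f"swim_lag{s}", 0.0) for s in SWIM_LAGS]
        )

    @property
    def o2_kernel(self) -> np.ndarray:
        return np.array([self.params.get(f"po2_lag{s}", 0.0) for s in O2_LAGS])

    @property
    def offset(self) -> float:
        return float(self.params["const"])

    def summary(self) -> str:
        lines = [
            f"Swim-history logistic GLM ({self.variant}"
            + (f", {self.condition}" if self.condition else "")
            + ")",
            f"  n bins: {self.n_obs}   converged: {self.converged}"
            + ("   [ridge refit: separation]" if self.ridged else ""),
            f"  ln L = {self.llf:.3f}   ln L0 = {self.llf_null:.3f}"
            f"   pseudo-r2 = {self.pseudo_r2:.4f}",
            "  kernel (standardized units):",
        ]
        for name, val, se in zip(self.params.index, self.params, self.bse):
            lines.append(f"    {name:>10s}  {val:+.4f}  (se {se:.4f})")
        return "\n".join(lines)


class SwimHistoryGLM:
    """Logistic model of binned swim actions for one condition.

    Parameters
    ----------
    design : one condition's frame from :func:`build_design`
    variant : 'predictive' (swim + oxygen history) or 'reactive'
        (oxygen history only)
    """

    def __init__(self, design: pd.DataFrame, variant: str = "predictive",
                 condition: str | None = None):
        if variant not in ("predictive", "reactive"):
            raise ValueError(f"unknown variant {variant!r}")
        if len(design) < 30:
            raise ValueError("need at least 30 usable bins")
        y = design["swim"].values
        if y.min() == y.max():
            raise ValueError("degenerate response: swim series is constant")
        self.variant = variant
        self.condition = condition
        self.y = y
        cols = [f"po2_lag{s}" for s in O2_LAGS]
        if variant == "predictive":
            cols = [f"swim_lag{s}" for s in SWIM_LAGS] + cols
        self.X = sm.add_constant(design[cols], has_constant="add")

    @staticmethod
    def _ridge_irls(X, y, alpha=1e-6, maxiter=200, tol=1e-10):
        """Ridge-penalized IRLS; near-MLE for tiny alpha, finite under
        separation."""
        beta = np.zeros(X.shape[1])
        ll_old = -np.inf
        for _ in range(maxiter):
            eta = np.clip(X @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1 - mu), 1e-10)
            z = eta + (y - mu) / w
            A = (X * w[:, None]).T @ X + 2 * alpha * np.eye(X.shape[1])
            beta = np.linalg.solve(A, (X * w[:, None]).T @ z)
            p = np.clip(1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30))),
                        1e-12, 1 - 1e-12)
            ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
                       - alpha * beta @ beta)
            if abs(ll - ll_old) < tol * max(abs(ll), 1.0):
                break
            ll_old = ll
        p = np.clip(1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30))),
                    1e-12, 1 - 1e-12)
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return beta, llf

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> SwimGlmResults:
        model = sm.GLM(self.y, self.X, family=sm.families.Binomial())
        ridged = False
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                res = model.fit(maxiter=maxiter, tol=tol)
            separated = any(
                "separation" in str(w.message).lower() for w in caught
            )
            params = res.params
            bse = res.bse
            llf = float(res.llf)
            converged = bool(res.converged)
            if separated or not np.isfinite(llf) or not np.all(
                np.isfinite(np.asarray(params))
            ):
                raise PerfectSeparationError
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            ridged = True
            beta, llf = self._ridge_irls(self.X.values, self.y)
            params = pd.Series(beta, index=self.X.columns)
            bse = pd.Series(np.nan, index=self.X.columns)
            converged = True
        null = sm.GLM(self.y, np.ones((self.y.size, 1)),
                      family=sm.families.Binomial()).fit()
        return SwimGlmResults(
            variant=self.variant,
            condition=self.condition,
            params=pd.Series(np.asarray(params), index=self.X.columns),
            bse=pd.Series(np.asarray(bse), index=self.X.columns),
            llf=llf,
            llf_null=float(null.llf),
            n_obs=int(self.y.size),
            converged=converged,
            ridged=ridged,
        )


def fit_glm(design: GlmDesign | pd.DataFrame, variant: str = "predictive",
            condition: str | None = None) -> SwimGlmResults:
    """Fit one variant on one condition (or a bare design frame)."""
    frame = design
    if isinstance(design, GlmDesign):
        if condition is None:
            raise ValueError("condition required with a full GlmDesign")
        frame = design.frames[condition]
    return SwimHistoryGLM(frame, variant=variant, condition=condition).fit()
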