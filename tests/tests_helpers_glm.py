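"""Shared generator utilities for the logistic history-kernel tests."""

import numpy as np
import pandas as pd

from oxyallo.behaviorglm import O2_LAGS, SWIM_LAGS, build_design
from oxyallo.paradigm import Epoch, Paradigm


def one_epoch(duration):
    return Paradigm(epochs=(Epoch("normoxia", 0.0, duration, 8.0),))


def simulate_history_glm(a, b, offset, n_bins, seed=0, po2_rho=0.95):
    """Sequentially sample swim bins from known kernels; returns
    (swim series, pO2 series at 1 Hz)."""
    rng = np.random.default_rng(seed)
    po2 = np.empty(n_bins)
    po2[0] = 0.0
    for t in range(1, n_bins):  # slow AR(1) oxygen fluctuation
        po2[t] = po2_rho * po2[t - 1] + rng.standard_normal() * 0.3
    swim = np.zeros(n_bins, dtype=int)
    for t in range(n_bins):
        y = offset
        for s in SWIM_LAGS:
            if t - s >= 0:
                y += a[s - 1] * swim[t - s]
        for s in O2_LAGS:
            if t - s >= 0:
                y += b[s] * po2[t - s]
        swim[t] = rng.uniform() < 1.0 / (1.0 + np.exp(-y))
    return swim, po2 + 6.0  # shift to a physiological level


def design_from_series(swim, po2, standardize=False):
    """Build the lagged design frame directly from binned series."""
    n_bins = swim.size
    onsets = np.flatnonzero(swim) + 0.5
    bouts = pd.DataFrame(
        {"onset_s": onsets, "offset_s": onsets + 0.2,
         "vigor": np.ones(onsets.size)}
    )
    design = build_design(bouts, po2, po2_fs=1.0,
                          schedule=one_epoch(float(n_bins)),
                          standardize=standardize)
    return design.frames["normoxia"]
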