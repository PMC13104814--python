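"""Experimental paradigm: a schedule of bath-oxygen epochs.

The standard assay perfuses the recording chamber with normoxic water
(8 mg/L dissolved O2) for 20 minutes and then switches to hypoxic water
(4 mg/L) for 20 minutes.  The chamber does not equilibrate instantly; bath
O2 relaxes toward the new perfusate level with a first-order mixing time
constant (default 90 s, so the 8->4 mg/L transition is ~95% complete about
5 minutes after the switch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_LABELS = ("normoxia", "hypoxia", "hyperoxia")


@dataclass(frozen=True)
class Epoch:
    """A contiguous stretch of the paradigm with one target bath O2 level."""

    label: str
    start: float  # s
    end: float  # s
    bath_o2: float  # mg/L, perfusate target

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown epoch label {self.label!r}")
        if not (self.end > self.start >= 0):
            raise ValueError("epoch must satisfy 0 <= start < end")
        if not (np.isfinite(self.bath_o2) and self.bath_o2 > 0):
            raise ValueError("bath O2 level must be positive and finite")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Paradigm:
    """Ordered, contiguous, non-overlapping epochs plus bath mixing kinetics."""

    epochs: tuple[Epoch, ...]
    mixing_tau: float = 90.0  # s, first-order bath equilibration

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("paradigm needs at least one epoch")
        if self.mixing_tau <= 0:
            raise ValueError("mixing_tau must be positive")
        for a, b in zip(self.epochs[:-1], self.epochs[1:]):
            if not np.isclose(a.end, b.start):
                raise ValueError("epochs must be contiguous and ordered")

    @property
    def duration(self) -> float:
        return self.epochs[-1].end

    @property
    def start(self) -> float:
        return self.epochs[0].start

    def label_at(self, t: np.ndarray | float) -> np.ndarray:
        """Epoch label for each time point (last epoch extends to the right)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        edges = np.array([e.start for e in self.epochs[1:]])
        idx = np.searchsorted(edges, t, side="right")
        labels = np.array([e.label for e in self.epochs])
        return labels[idx]

    def target_at(self, t: np.ndarray | float) -> np.ndarray:
        """Perfusate (target) bath O2 level at each time point, mg/L."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        edges = np.array([e.start for e in self.epochs[1:]])
        idx = np.searchsorted(edges, t, side="right")
        levels = np.array([e.bath_o2 for e in self.epochs])
        return levels[idx]

    def bath_trace(self, t: np.ndarray) -> np.ndarray:
        """Bath O2 relaxing first-order toward the epoch target.

        Solved exactly epoch by epoch (the target is piecewise constant),
        starting equilibrated at the first epoch's level.
        """
        t = np.asarray(t, dtype=float)
        out = np.empty_like(t)
        level = self.epochs[0].bath_o2
        for ep in self.epochs:
            mask = (t >= ep.start) & (t < ep.end) if ep is not self.epochs[-1] else (
                t >= ep.start
            )
            dt_ep = t[mask] - ep.start
            out[mask] = ep.bath_o2 + (level - ep.bath_o2) * np.exp(
                -dt_ep / self.mixing_tau
            )
            level = ep.bath_o2 + (level - ep.bath_o2) * np.exp(
                -ep.duration / self.mixing_tau
            )
        out[t < self.epochs[0].start] = self.epochs[0].bath_o2
        return out

    def epoch(self, label: str) -> Epoch:
        """First epoch with the given label."""
        for ep in self.epochs:
            if ep.label == label:
                return ep
        raise KeyError(f"no epoch labelled {label!r}")

    def last_minutes(self, label: str, minutes: float = 5.0) -> tuple[float, float]:
        """Window covering the last `minutes` of the first epoch with `label`."""
        ep = self.epoch(label)
        lo = max(ep.start, ep.end - minutes * 60.0)
        return lo, ep.end


def default_paradigm(
    normoxia_level: float = 8.0,
    hypoxia_level: float = 4.0,
    epoch_minutes: float = 20.0,
    mixing_tau: float = 90.0,
) -> Paradigm:
    """The standard 40-min normoxia (8 mg/L) -> hypoxia (4 mg/L) assay."""
    half = epoch_minutes * 60.0
    return Paradigm(
        epochs=(
            Epoch("normoxia", 0.0, half, normoxia_level),
            Epoch("hypoxia", half, 2 * half, hypoxia_level),
        ),
        mixing_tau=mixing_tau,
    )
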