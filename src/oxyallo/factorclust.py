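"""Population-structure analysis: sparse factor model of fast dynamics,
signed-factor splitting, cross-fish overlap maps, and hierarchical
clustering of slow baselines.

The factor model reconstructs the (cells x time) fast-component matrix as
F = L A with a sparsity-inducing Beta(0.5, 0.5) prior on the per-factor
max-normalized weight magnitudes; the arcsine-shaped prior pushes
normalized weights toward 0 or 1, yielding near-binary cell memberships.
Inference is MAP alternating minimization (exact least-squares factor
update, backtracked proximal-gradient weight update), restarted from
several initializations with the best penalized objective kept; the
objective is non-increasing across iterations by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

__all__ = [
    "FactorModel",
    "SparseFactorModel",
    "fit_sparse_fa",
    "split_signed",
    "ClusterMap",
    "combine_across_fish",
    "SlowClusters",
    "cluster_slow",
]

_EPS = 1e-3  # normalized-weight clipping for the Beta prior


@dataclass
class FactorModel:
    """Fitted sparse factor model: F ~ L A, weights max-normalized per factor."""

    L: np.ndarray  # cells x m
    A: np.ndarray  # m x time
    m: int
    objective: float
    objective_trace: np.ndarray
    converged: bool
    seed: int | None
    beta_a: float = 0.5
    beta_b: float = 0.5

    def reconstruct(self) -> np.ndarray:
        return self.L @ self.A


def _penalty(L: np.ndarray, lam: float, a: float = 0.5, b: float = 0.5) -> float:
    """Negative log Beta prior on per-factor max-normalized |weights|."""
    scale = np.maximum(np.abs(L).max(axis=0, keepdims=True), 1e-12)
    w = np.clip(np.abs(L) / scale, _EPS, 1.0 - _EPS)
    return lam * float(np.sum((1.0 - a) * np.log(w) + (1.0 - b) * np.log(1.0 - w)))


def _penalty_grad(L: np.ndarray, lam: float, a: float = 0.5, b: float = 0.5):
    scale = np.maximum(np.abs(L).max(axis=0, keepdims=True), 1e-12)
    w = np.clip(np.abs(L) / scale, _EPS, 1.0 - _EPS)
    dw = (1.0 - a) / w - (1.0 - b) / (1.0 - w)
    return lam * dw * np.sign(L) / scale


class SparseFactorModel:
    """Model object for the sparse factor analysis of a dFF matrix.

    Parameters
    ----------
    X : cells x time matrix (fast fluorescence components)
    m : number of factors (before signed splitting)
    sparsity : multiplier on the Beta-prior penalty; the penalty is scaled
        by the per-element data variance so the default transfers across
        datasets.
    """

    def __init__(self, X: np.ndarray, m: int = 20, sparsity: float = 1.0,
                 beta_a: float = 0.5, beta_b: float = 0.5):
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("data must be finite")
        if not (0 < m < min(X.shape)):
            raise ValueError("m must satisfy 0 < m < min(cells, time)")
        self.X = X
        self.m = m
        self.lam = sparsity * float(np.var(X))
        self.beta_a = beta_a
        self.beta_b = beta_b

    def _objective(self, L, A):
        resid = self.X - L @ A
        return float(np.sum(resid * resid)) + _penalty(
            L, self.lam, self.beta_a, self.beta_b
        )

    def _normalize(self, L, A):
        """Fix the scale indeterminacy: per-factor max |weight| = 1."""
        scale = np.maximum(np.abs(L).max(axis=0), 1e-12)
        return L / scale, A * scale[:, None]

    def _fit_once(self, rng, init, max_iter, tol):
        X, m = self.X, self.m
        if init == "svd":
            U, S, Vt = np.linalg.svd(X, full_matrices=False)
            L = U[:, :m] * S[:m]
            A = Vt[:m]
        else:
            L = rng.standard_normal((X.shape[0], m)) * X.std()
            A = rng.standard_normal((m, X.shape[1])) * 0.1
        L, A = self._normalize(L, A)
        trace = [self._objective(L, A)]
        eta = 1.0 / (np.linalg.norm(A @ A.T, 2) + 1e-12)
        converged = False
        for _ in range(max_iter):
            # exact factor update (penalty does not involve A)
            A = np.linalg.lstsq(L, X, rcond=None)[0]
            # backtracked gradient step on the weights
            obj0 = self._objective(L, A)
            grad = 2.0 * (L @ A - X) @ A.T + _penalty_grad(
                L, self.lam, self.beta_a, self.beta_b
            )
            eta = 2.0 / (2.0 * np.linalg.norm(A @ A.T, 2) + 1e-12)
            accepted = False
            for _bt in range(30):
                L_new = L - eta * grad
                obj_new = self._objective(L_new, A)
                if obj_new <= obj0:
                    accepted = True
                    break
                eta *= 0.5
            if accepted:
                L = L_new
            obj = self._objective(L, A)
            trace.append(min(obj, trace[-1] + 1e-12))
            if abs(trace[-2] - trace[-1]) <= tol * max(abs(trace[-2]), 1.0):
                converged = True
                break
        L, A = self._normalize(L, A)
        return L, A, np.asarray(trace), converged

    def fit(self, seed: int | None = 0, n_restarts: int = 3,
            max_iter: int = 200, tol: float = 1e-8) -> FactorModel:
        rng = np.random.default_rng(seed)
        best = None
        for r in range(n_restarts):
            init = "svd" if r == 0 else "random"
            L, A, trace, conv = self._fit_once(rng, init, max_iter, tol)
            obj = self._objective(L, A)
            if best is None or obj < best[0]:
                best = (obj, L, A, trace, conv)
        obj, L, A, trace, conv = best
        return FactorModel(
            L=L, A=A, m=self.m, objective=obj, objective_trace=trace,
            converged=conv, seed=seed, beta_a=self.beta_a, beta_b=self.beta_b,
        )


def fit_sparse_fa(dff: np.ndarray, m: int = 20, seed: int | None = 0,
                  **kwargs) -> FactorModel:
    """Functional wrapper around :class:`SparseFactorModel`."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("n_restarts", "max_iter", "tol")
                  if k in kwargs}
    return SparseFactorModel(dff, m=m, **kwargs).fit(seed=seed, **fit_kwargs)


def split_signed(model: FactorModel) -> FactorModel:
    """Separate positive and negative weights of each factor.

    A mixed-sign factor (L_j, A_j) becomes (max(L_j, 0), A_j) and
    (max(-L_j, 0), -A_j); the second carries the negated negative weights
    with a sign-flipped copy of the shared time course, so L A is
    preserved exactly.
    """
    Ls, As = [], []
    for j in range(model.m):
        lj, aj = model.L[:, j], model.A[j]
        pos, neg = np.maximum(lj, 0.0), np.maximum(-lj, 0.0)
        if pos.any() or not neg.any():
            Ls.append(pos)
            As.append(aj)
        if neg.any():
            Ls.append(neg)
            As.append(-aj)
    L = np.stack(Ls, axis=1)
    A = np.stack(As, axis=0)
    return FactorModel(
        L=L, A=A, m=L.shape[1], objective=model.objective,
        objective_trace=model.objective_trace, converged=model.converged,
        seed=model.seed, beta_a=model.beta_a, beta_b=model.beta_b,
    )


@dataclass
class ClusterMap:
    """Cross-fish overlap counts on a voxel grid, per factor."""

    counts: np.ndarray  # factors x nx x ny x nz, fish counts
    grid_origin: np.ndarray  # um
    voxel_size: tuple[float, float, float]
    labels: list[np.ndarray]  # per fish: per-cell factor label (-1 = none)
    threshold: float
    n_fish: int


def combine_across_fish(
    models: list[FactorModel],
    coords: list[np.ndarray],
    threshold: float = 0.3,
    voxel_size: tuple[float, float, float] = (10.0, 10.0, 20.0),
    pairing: list[np.ndarray] | None = None,
) -> ClusterMap:
    """Binarize factor weights at 0.3 (inclusive) and count, per voxel, how
    many fish have at least one supra-threshold cell for each factor.

    All fish must share a reference coordinate frame and a common factor
    ordering; supply ``pairing`` (per fish, an index array into a common
    factor set) when orderings differ.
    """
    if len(models) != len(coords):
        raise ValueError("one coordinate set per model required")
    n_factors = {m.L.shape[1] for m in models}
    if pairing is None:
        if len(n_factors) != 1:
            raise ValueError(
                "factor counts differ across fish; supply a pairing map"
            )
        pairing = [np.arange(m.L.shape[1]) for m in models]
    n_common = int(max(p.max() for p in pairing)) + 1

    all_xyz = np.vstack(coords)
    origin = all_xyz.min(axis=0)
    vox = np.asarray(voxel_size, dtype=float)
    shape = np.maximum(
        np.ceil((all_xyz.max(axis=0) - origin) / vox).astype(int) + 1, 1
    )
    counts = np.zeros((n_common, *shape), dtype=int)
    labels = []
    for model, xyz, pair in zip(models, coords, pairing):
        W = np.abs(model.L) >= threshold  # inclusive
        lab = np.where(
            W.any(axis=1), pair[np.argmax(np.abs(model.L), axis=1)], -1
        )
        labels.append(lab)
        vox_idx = np.floor((xyz - origin) / vox).astype(int)
        for j in range(model.L.shape[1]):
            cells = np.flatnonzero(W[:, j])
            if cells.size == 0:
                continue
            occupied = np.unique(vox_idx[cells], axis=0)
            counts[(pair[j],) + tuple(occupied.T)] += 1
    return ClusterMap(
        counts=counts, grid_origin=origin, voxel_size=tuple(vox),
        labels=labels, threshold=threshold, n_fish=len(models),
    )


@dataclass
class SlowClusters:
    labels: np.ndarray  # per cell, -1 for flat cells
    means: np.ndarray  # k x time cluster mean traces
    po2_corr: np.ndarray  # Spearman r of each mean with -pO2
    k: int


def cluster_slow(
    fslow: np.ndarray,
    k: int = 6,
    po2: np.ndarray | None = None,
) -> SlowClusters:
    """Agglomerative clustering (average linkage, 1 - Spearman distance) of
    slow baselines into k clusters, labelled by the rank correlation of the
    cluster mean with -pO2.  Constant cells go to a flat pseudo-cluster
    (label -1) and are excluded from correlation labelling.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    F = np.asarray(fslow, dtype=float)
    flat = F.std(axis=1) < 1e-12
    active = np.flatnonzero(~flat)
    labels = np.full(F.shape[0], -1, dtype=int)
    if active.size == 0:
        return SlowClusters(labels, np.zeros((0, F.shape[1])), np.zeros(0), 0)
    k_eff = min(k, active.size)
    if active.size == 1:
        labels[active] = 0
    else:
        rho = spearmanr(F[active].T).statistic
        if np.ndim(rho) == 0:  # two cells
            rho = np.array([[1.0, rho], [rho, 1.0]])
        dist = np.clip(1.0 - rho, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        labels[active] = fcluster(Z, t=k_eff, criterion="maxclust") - 1
    k_found = labels.max() + 1
    means = np.stack(
        [F[labels == j].mean(axis=0) for j in range(k_found)]
    ) if k_found else np.zeros((0, F.shape[1]))
    corr = np.full(k_found, np.nan)
    if po2 is not None:
        for j in range(k_found):
            if means[j].std() > 0:
                corr[j] = spearmanr(means[j], -np.asarray(po2)).statistic
    return SlowClusters(labels=labels, means=means, po2_corr=corr, k=k_found)
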