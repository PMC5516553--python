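"""Non-hierarchical k-means with cubic-clustering-criterion model selection.

The engine fits Lloyd's k-means from k-means++ starts over a small range of
candidate cluster counts (k = 2..5 by default), scores each solution with
Sarle's cubic clustering criterion (CCC; SAS Technical Report A-108, 1983),
and selects the candidate whose CCC is a local peak.  The CCC compares the
observed proportion of variance explained, R^2 = 1 - WSS/TSS, against its
expectation under a null in which the data fill a uniform hyperbox whose
edge lengths are the singular values of the (centered) feature matrix:

    CCC = ln[(1 - E(R^2)) / (1 - R^2)] * sqrt(n p* / 2) / (0.001 + E(R^2))^1.2

with the effective dimensionality p* estimated from the number of scaled
singular values exceeding the per-cluster edge length of the partitioned
hyperbox.  Values near 0 indicate a partition no better than the uniform
null; local peaks across k indicate candidate cluster counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, FeatureMatrix

ArrayLike = Union[np.ndarray, FeatureMatrix]


@dataclass
class ClusterSolution:
    """One fitted k-means partition."""

    k: int
    ids: List[str]
    labels: np.ndarray  # cluster index per row
    centroids: np.ndarray
    wss: float
    tss: float
    ccc: Optional[float] = None

    @property
    def r2(self) -> float:
        return 1.0 - self.wss / self.tss if self.tss > 0 else 0.0

    @property
    def assignments(self) -> Dict[str, int]:
        return dict(zip(self.ids, (int(c) for c in self.labels)))

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class CCCProfile:
    """CCC across candidate k with the selected model."""

    k_values: List[int]
    ccc_values: List[float]
    selected_k: int
    selection_kind: str  # "interior_peak" or "boundary_max"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k_values, "ccc": self.ccc_values,
             "selected": [k == self.selected_k for k in self.k_values]}
        )


def _as_array(X: ArrayLike) -> Tuple[np.ndarray, List[str], bool]:
    if isinstance(X, FeatureMatrix):
        return X.values, list(X.ids), X.standardized
    arr = np.asarray(X, dtype=float)
    col_means = arr.mean(axis=0)
    looks_standardized = bool(np.all(np.abs(col_means) < 1e-6))
    return arr, [str(i) for i in range(arr.shape[0])], looks_standardized


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.integers(n)]
    d2 = np.sum((X - centroids[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j] = X[rng.integers(n)]
            continue
        centroids[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((X - centroids[j]) ** 2, axis=1))
    return centroids


def _lloyd(
    X: np.ndarray, centroids: np.ndarray, max_iter: int = 300
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations; WSS is non-increasing across iterations."""
    k = centroids.shape[0]
    labels = np.full(X.shape[0], -1, dtype=int)
    prev_wss = np.inf
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        # Repair empty clusters: reseed to the point farthest from its
        # current centroid (deterministic).
        for j in range(k):
            if not np.any(new_labels == j):
                current = d2[np.arange(X.shape[0]), new_labels]
                far = int(np.argmax(current))
                centroids[j] = X[far]
                d2[:, j] = ((X - centroids[j]) ** 2).sum(axis=1)
                new_labels = d2.argmin(axis=1)
        wss = float(d2[np.arange(X.shape[0]), new_labels].sum())
        if wss > prev_wss + 1e-8:  # pragma: no cover - monotonicity guard
            raise AssertionError("k-means WSS increased across an iteration")
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        prev_wss = wss
        for j in range(k):
            centroids[j] = X[labels == j].mean(axis=0)
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    wss = float(d2[np.arange(X.shape[0]), labels].sum())
    return labels, centroids, wss


def kmeans(X: ArrayLike, k: int, restarts: int = 50, seed: int = 0) -> ClusterSolution:
    """Best-of-``restarts`` Lloyd k-means, deterministic given ``seed``."""
    arr, ids, standardized = _as_array(X)
    n = arr.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, n={n}]")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if not standardized:
        warnings.warn("feature matrix does not look standardized; proceeding", stacklevel=2)
    rng = np.random.default_rng(seed)
    best: Optional[Tuple[np.ndarray, np.ndarray, float]] = None
    for _ in range(restarts):
        init = _kmeanspp_init(arr, k, rng)
        labels, centroids, wss = _lloyd(arr, init.copy())
        if best is None or wss < best[2]:
            best = (labels, centroids, wss)
    labels, centroids, wss = best
    tss = float(((arr - arr.mean(axis=0)) ** 2).sum())
    return ClusterSolution(k=k, ids=ids, labels=labels, centroids=centroids, wss=wss, tss=tss)


def _scaled_singular_values(X: np.ndarray) -> np.ndarray:
    """Square roots of the eigenvalues of the covariance of centered X."""
    Xc = X - X.mean(axis=0)
    v = np.linalg.eigvalsh(Xc.T @ Xc / (X.shape[0] - 1))[::-1]
    v = np.clip(v, 0.0, None)
    return np.sqrt(v)


def expected_r2(X: np.ndarray, q: int) -> Tuple[float, int]:
    """E(R^2) under the uniform-hyperbox null and the dimensionality p* used.

    Two-pass estimate: a first pass over all p dimensions locates the
    dimensions whose edge length exceeds the per-cluster cut (u_j >= 1);
    p* = min(#such dimensions, q-1); the second pass recomputes the cut from
    the top p* edges only.
    """
    n, p = X.shape
    s = _scaled_singular_values(X)
    s = s[s > 1e-12]
    p_eff = s.size
    if p_eff == 0:
        raise ValueError("degenerate (zero-variance) feature matrix")
    c = (np.prod(s) / q) ** (1.0 / p_eff)
    u = s / c
    p_star = min(int(np.sum(u >= 1.0)), q - 1)
    if p_star >= 1:
        c = (np.prod(s[:p_star]) / q) ** (1.0 / p_star)
        u = s / c
        b = np.sum(1.0 / (n + u[:p_star])) + np.sum(u[p_star:] ** 2 / (n + u[p_star:]))
    else:
        p_star = p_eff
        b = np.sum(1.0 / (n + u))
    er2 = 1.0 - (b / np.sum(u**2)) * ((n - q) ** 2 / n) * (1.0 + 4.0 / n)
    return float(er2), p_star


def ccc_from_expected(r2: float, er2: float, n: int, p_star: int) -> float:
    """Sarle's closed form given R^2, E(R^2), n and p*."""
    if r2 >= 1:
        raise ValueError("CCC is undefined at R^2 = 1 (log singularity)")
    return float(
        np.log((1.0 - er2) / (1.0 - r2))
        * np.sqrt(n * p_star / 2.0)
        / (0.001 + er2) ** 1.2
    )


def compute_ccc(X: ArrayLike, r2: float, q: int) -> float:
    """Cubic clustering criterion for a q-cluster partition with given R^2."""
    if not 0 <= r2 < 1:
        raise ValueError(f"R^2 must lie in [0, 1), got {r2}")
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    arr, _, _ = _as_array(X)
    er2, p_star = expected_r2(arr, q)
    return ccc_from_expected(r2, er2, arr.shape[0], p_star)


def select_k(k_values: Sequence[int], ccc_values: Sequence[float]) -> CCCProfile:
    """Local-peak rule over the CCC curve.

    An interior peak (CCC above both neighbors) wins; among several, the one
    with the largest CCC, ties toward smaller k.  With no interior peak, the
    global maximum is reported as a boundary maximum.
    """
    ks = list(k_values)
    cs = [float(c) for c in ccc_values]
    if len(ks) != len(cs):
        raise ValueError("k and CCC lists differ in length")
    finite = [i for i, c in enumerate(cs) if np.isfinite(c)]
    if len(finite) < 2:
        raise ValueError("need at least two candidate k values with finite CCC")
    peaks = [
        i for i in range(1, len(cs) - 1)
        if np.isfinite(cs[i]) and cs[i] > cs[i - 1] and cs[i] > cs[i + 1]
    ]
    if peaks:
        best = max(cs[i] for i in peaks)
        idx = min(i for i in peaks if cs[i] == best)
        kind = "interior_peak"
    else:
        best = max(cs[i] for i in finite)
        idx = min(i for i in finite if cs[i] == best)
        kind = "boundary_max"
    return CCCProfile(k_values=ks, ccc_values=cs, selected_k=ks[idx], selection_kind=kind)


def run_cluster_scan(
    X: ArrayLike,
    k_range: Sequence[int] = (2, 3, 4, 5),
    restarts: int = 50,
    seed: int = 0,
) -> Tuple[List[ClusterSolution], CCCProfile]:
    """Fit every k in ``k_range``, score with CCC, and select by local peak."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    arr, _, _ = _as_array(X)
    child_seeds = np.random.SeedSequence(seed).spawn(len(ks))
    solutions: List[ClusterSolution] = []
    for k, ss in zip(ks, child_seeds):
        sol = kmeans(X, k, restarts=restarts, seed=int(ss.generate_state(1)[0] % (2**31)))
        sol.ccc = compute_ccc(arr, sol.r2, k)
        solutions.append(sol)
    if len(ks) == 1:
        profile = CCCProfile(
            k_values=ks, ccc_values=[solutions[0].ccc],
            selected_k=ks[0], selection_kind="boundary_max",
        )
    else:
        profile = select_k(ks, [s.ccc for s in solutions])
    return solutions, profile


def label_clusters(
    solution: ClusterSolution, features: FeatureMatrix
) -> Tuple[Dict[int, str], pd.DataFrame]:
    """Name the clusters of a 4-cluster solution by their clinical profile.

    TD is the cluster with the highest mean motor phenotype ratio, RDP the
    fastest-progressing among the rest, YO the youngest-onset among the
    remainder, NTD the last.  For k != 4 generic names C1..Ck are returned.
    The per-cluster means of the deciding variables are returned as evidence.
    """
    cols = {name: i for i, name in enumerate(features.columns)}
    means = np.vstack([
        features.raw[solution.labels == j].mean(axis=0) for j in range(solution.k)
    ])
    evidence = pd.DataFrame(
        means[:, [cols["motor_phenotype"], cols["progression_rate"], cols["age_onset"]]],
        columns=["motor_phenotype", "progression_rate", "age_onset"],
        index=[f"cluster_{j}" for j in range(solution.k)],
    )
    if solution.k != 4:
        return {j: f"C{j + 1}" for j in range(solution.k)}, evidence

    remaining = list(range(4))
    td = max(remaining, key=lambda j: means[j, cols["motor_phenotype"]])
    remaining.remove(td)
    rdp = max(remaining, key=lambda j: means[j, cols["progression_rate"]])
    remaining.remove(rdp)
    yo = min(remaining, key=lambda j: means[j, cols["age_onset"]])
    remaining.remove(yo)
    ntd = remaining[0]
    labels = {td: "TD", rdp: "RDP", yo: "YO", ntd: "NTD"}
    evidence["label"] = [labels[j] for j in range(4)]
    return labels, evidence
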