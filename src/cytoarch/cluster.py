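"""Hierarchical clustering with multiscale-bootstrap cluster support.

Columns of an unfolded view are clustered with correlation distance
(1 - Pearson r) and average linkage (UPGMA).  Cluster support is assessed
by bootstrap resampling of the rows: the ordinary bootstrap probability
(BP) of a dendrogram node is the fraction of resampled clusterings that
contain the identical leaf set, and the approximately unbiased (AU)
probability corrects BP's bias by resampling at several sample sizes
n' = r * n, fitting

    z(tau) = Phi^-1(1 - BP(tau)) = v * tau + c / tau,   tau = sqrt(n / n')

by weighted least squares, and reporting AU = 1 - Phi(v - c).  AU > 0.95
marks a cluster as highly supported.  Defaults follow the standard
multiscale design: ten scales r in {0.5, ..., 1.4} with 1000 bootstrap
replicates per scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

DEFAULT_SCALES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)
AU_HIGH_SUPPORT = 0.95


def correlation_distance(X) -> np.ndarray:
    """1 - Pearson correlation between columns; symmetric, zero diagonal."""
    A = np.asarray(X, dtype=float)
    if A.shape[0] < 3:
        raise ValueError("at least 3 rows required")
    sd = A.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance column")
    d = 1.0 - np.corrcoef(A, rowvar=False)
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


@dataclass
class Dendrogram:
    """UPGMA merge tree over labelled leaves."""

    merge: np.ndarray  # scipy linkage matrix, (n-1) x 4
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_leafsets(self) -> list[frozenset[int]]:
        """Leaf-index set beneath each internal node, in merge order."""
        return _leafsets(self.merge, self.n_leaves)

    def node_heights(self) -> np.ndarray:
        return self.merge[:, 2].copy()

    def leafset_names(self, node: int) -> frozenset[str]:
        return frozenset(self.labels[i] for i in self.node_leafsets()[node])

    def find_node(self, leaves: set[str]) -> int | None:
        target = frozenset(self.labels.index(x) for x in leaves)
        for i, ls in enumerate(self.node_leafsets()):
            if ls == target:
                return i
        return None


def _leafsets(Z: np.ndarray, n: int) -> list[frozenset[int]]:
    sets: list[frozenset[int]] = []
    for a, b in Z[:, :2].astype(int):
        left = frozenset([a]) if a < n else sets[a - n]
        right = frozenset([b]) if b < n else sets[b - n]
        sets.append(left | right)
    return sets


def average_linkage(distances: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """UPGMA merge sequence from a square distance matrix."""
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    Z = linkage(squareform(D, checks=False), method="average")
    return Dendrogram(Z, labels if labels is not None else [str(i) for i in range(n)])


@dataclass
class ClusterSupport:
    """Per-node bootstrap support for an observed dendrogram."""

    scales: np.ndarray  # row fractions r
    tau: np.ndarray  # sqrt(n / n')
    n_boot: int
    bp_by_scale: np.ndarray  # (n_nodes, n_scales) observed frequencies
    au: np.ndarray
    bp: np.ndarray  # frequency at the scale closest to r = 1
    v: np.ndarray
    c: np.ndarray
    fit_rss: np.ndarray
    flags: list[str] = field(default_factory=list)  # "", "degenerate", "undefined"

    def table(self, dendrogram: Dendrogram) -> pd.DataFrame:
        rows = []
        heights = dendrogram.node_heights()
        for i, ls in enumerate(dendrogram.node_leafsets()):
            rows.append(
                {
                    "node": i,
                    "leaves": "|".join(sorted(dendrogram.labels[j] for j in ls)),
                    "height": heights[i],
                    "au": self.au[i],
                    "bp": self.bp[i],
                    "v": self.v[i],
                    "c": self.c[i],
                    "fit_rss": self.fit_rss[i],
                    "flag": self.flags[i],
                    "highly_supported": bool(
                        np.isfinite(self.au[i]) and self.au[i] > AU_HIGH_SUPPORT
                    ),
                }
            )
        return pd.DataFrame(rows)


def _bootstrap_counts_one_scale(
    X: np.ndarray,
    node_sets: list[frozenset[int]],
    idx: np.ndarray,
    chunk: int = 250,
) -> np.ndarray:
    """Count, per observed node, replicates whose tree contains its leaf set.

    Per-replicate column covariances are accumulated through row-multiplicity
    counts and two BLAS matmuls against precomputed per-row outer products,
    which is algebraically identical to resampling the rows directly.
    """
    n_boot, n_prime = idx.shape
    n, p = X.shape
    counts = np.zeros(len(node_sets), dtype=int)
    wanted = {ls: i for i, ls in enumerate(node_sets)}
    P = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    for start in range(0, n_boot, chunk):
        sub = idx[start : start + chunk]
        W = np.zeros((sub.shape[0], n))
        for b in range(sub.shape[0]):
            W[b] = np.bincount(sub[b], minlength=n)
        S = W @ X  # (c, p) resampled column sums
        C2 = (W @ P).reshape(-1, p, p)  # resampled sum of outer products
        mean = S / n_prime
        cov = C2 / n_prime - mean[:, :, None] * mean[:, None, :]
        var = np.einsum("bjj->bj", cov)
        sd = np.sqrt(np.maximum(var, 0.0))
        sd = np.where(sd == 0, np.nan, sd)
        with np.errstate(invalid="ignore"):
            dist = 1.0 - cov / (sd[:, :, None] * sd[:, None, :])
        for b in range(dist.shape[0]):
            D = dist[b]
            bad = np.isnan(D)
            if bad.any():
                D = np.where(bad, 2.0, D)  # uninformative columns: max distance
            np.fill_diagonal(D, 0.0)
            D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
            Z = linkage(squareform(D, checks=False), method="average")
            for ls in _leafsets(Z, p):
                j = wanted.get(ls)
                if j is not None:
                    counts[j] += 1
    return counts


def bootstrap_support(
    X,
    n_boot: int = 1000,
    scales=DEFAULT_SCALES,
    seed: int = 0,
    labels: list[str] | None = None,
) -> tuple[Dendrogram, np.ndarray, np.ndarray]:
    """Multiscale bootstrap frequencies for the observed column dendrogram.

    For each scale r, ceil(r * n) rows are resampled with replacement
    ``n_boot`` times and the columns re-clustered; a node's BP at that scale
    is the fraction of replicate trees containing its exact leaf set.  Index
    draws come from one seeded generator, consumed scale by scale in the
    order given, so the stream is reproducible.

    Returns (dendrogram, bp_by_scale, n_prime_per_scale).
    """
    A = np.asarray(X, dtype=float)
    n = A.shape[0]
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    n_primes = np.array([int(np.ceil(r * n)) for r in scales])
    if n_primes.min() < 3:
        raise ValueError("smallest scale leaves fewer than 3 rows")
    dend = average_linkage(correlation_distance(A), labels)
    node_sets = dend.node_leafsets()
    rng = np.random.default_rng(seed)
    bp = np.zeros((len(node_sets), len(scales)))
    for si, n_prime in enumerate(n_primes):
        idx = rng.integers(0, n, size=(n_boot, int(n_prime)))
        counts = _bootstrap_counts_one_scale(A, node_sets, idx)
        bp[:, si] = counts / n_boot
    return dend, bp, n_primes


def au_probability(
    bp_by_scale: np.ndarray, tau: np.ndarray, n_boot: int
) -> tuple[float, float, float, float, str]:
    """Fit the signed-distance/curvature model to one node's BP curve.

    Returns (au, v, c, fit_rss, flag).  Frequencies are clipped to
    [1/(n_boot+1), 1 - 1/(n_boot+1)] so that boundary scales remain usable,
    then every scale enters a weighted least-squares fit of
    z = Phi^-1(1 - BP) = v * tau + c / tau with weights
    n_boot * phi(z)^2 / (BP (1 - BP)); AU = 1 - Phi(v - c).  All-zero or
    all-one curves short-circuit to AU 0 or 1 with a degeneracy flag; fewer
    than three scales leaves AU undefined.
    """
    bp = np.asarray(bp_by_scale, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.all(bp >= 1.0 - 1e-12):
        return 1.0, -np.inf, np.inf, 0.0, "degenerate"
    if np.all(bp <= 1e-12):
        return 0.0, np.inf, -np.inf, 0.0, "degenerate"
    if bp.size < 3:
        return np.nan, np.nan, np.nan, np.nan, "undefined"
    lo, hi = 1.0 / (n_boot + 1), 1.0 - 1.0 / (n_boot + 1)
    bp_u = np.clip(bp, lo, hi)
    t_u = tau
    z = norm.isf(bp_u)  # Phi^-1(1 - BP)
    w = n_boot * norm.pdf(z) ** 2 / (bp_u * (1.0 - bp_u))
    design = np.column_stack([t_u, 1.0 / t_u])
    wsqrt = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * wsqrt[:, None], z * wsqrt, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    resid = z - design @ coef
    rss = float(np.sum(w * resid**2))
    au = float(1.0 - norm.cdf(v - c))
    return au, v, c, rss, ""


def attach_support(
    bp_by_scale: np.ndarray, scales, n: int, n_boot: int
) -> ClusterSupport:
    """Fit AU for every node from its multiscale BP curve."""
    scales = np.asarray(scales, dtype=float)
    n_primes = np.array([int(np.ceil(r * n)) for r in scales])
    tau = np.sqrt(n / n_primes)
    one = int(np.argmin(np.abs(n_primes - n)))
    n_nodes = bp_by_scale.shape[0]
    au = np.empty(n_nodes)
    v = np.empty(n_nodes)
    c = np.empty(n_nodes)
    rss = np.empty(n_nodes)
    flags = []
    for i in range(n_nodes):
        au[i], v[i], c[i], rss[i], flag = au_probability(
            bp_by_scale[i], tau, n_boot
        )
        flags.append(flag)
    return ClusterSupport(
        scales=scales,
        tau=tau,
        n_boot=n_boot,
        bp_by_scale=bp_by_scale.copy(),
        au=au,
        bp=bp_by_scale[:, one].copy(),
        v=v,
        c=c,
        fit_rss=rss,
        flags=flags,
    )


def pvcluster(
    X,
    n_boot: int = 1000,
    scales=DEFAULT_SCALES,
    seed: int = 0,
    labels: list[str] | None = None,
) -> tuple[Dendrogram, ClusterSupport]:
    """Observed UPGMA tree over columns plus AU/BP support for every node."""
    A = np.asarray(X, dtype=float)
    dend, bp, _ = bootstrap_support(A, n_boot=n_boot, scales=scales, seed=seed, labels=labels)
    support = attach_support(bp, scales, A.shape[0], n_boot)
    return dend, support


def to_newick(dendrogram: Dendrogram, support: ClusterSupport | None = None) -> str:
    """Newick serialization with "AU|BP" percentage node labels."""
    n = dendrogram.n_leaves
    Z = dendrogram.merge

    def label(node: int) -> str:
        if support is None:
            return ""
        au = support.au[node]
        au_s = f"{au * 100:.0f}" if np.isfinite(au) else "NA"
        return f"{au_s}|{support.bp[node] * 100:.0f}"

    def build(idx: int, parent_height: float) -> str:
        if idx < n:
            return f"{dendrogram.labels[idx]}:{parent_height:.6g}"
        node = idx - n
        a, b = int(Z[node, 0]), int(Z[node, 1])
        h = Z[node, 2]
        inner = f"({build(a, h)},{build(b, h)})"
        blen = parent_height - h
        return f"{inner}{label(node)}:{blen:.6g}"

    root = 2 * n - 2
    a, b = int(Z[-1, 0]), int(Z[-1, 1])
    h = Z[-1, 2]
    root_label = label(root - n)
    return f"({build(a, h)},{build(b, h)}){root_label};"
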