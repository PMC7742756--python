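"""Sample-level methylation-profile analyses and plot-ready tables.

Profiles are per-sample vectors of methylation ratios over complete-case
sites (non-missing in every library).  Samples are compared with the
Pearson correlation distance d = 1 - r and clustered with Ward's
minimum-variance criterion applied to those distances as-is (the
"ward.D" behaviour; the variant that squares dissimilarities first,
"ward.D2", is selectable).  The agglomeration is implemented directly via
the Lance-Williams recurrence so merge order and index-based tie-breaking
are deterministic and the unsquared variant is available; dendrograms
export as Newick.

Also provided: column-centred PCA with a fixed sign convention, and
Manhattan / QQ / volcano tables so figures are reproducible in any
plotting stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cgmap import SiteMatrix

__all__ = [
    "profile_matrix",
    "correlation_distance",
    "ward_cluster",
    "Dendrogram",
    "cut_tree",
    "pca",
    "manhattan_table",
    "qq_table",
    "volcano_table",
    "mean_methylation",
]


def profile_matrix(matrix: SiteMatrix) -> pd.DataFrame:
    """samples x sites ratio matrix over complete-case sites."""
    r = matrix.ratios()
    complete = r.notna().all(axis=1)
    return r.loc[complete].T  # samples as rows


def correlation_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Pearson(r) between sample profiles (range [0, 2])."""
    if profiles.shape[0] < 2 or profiles.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 sites")
    sd = profiles.std(axis=1, ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance profile for sample(s): {flat}")
    corr = np.corrcoef(profiles.to_numpy())
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


@dataclass
class Dendrogram:
    """Merge list in scipy linkage convention.

    Row k = (a, b, height, size): clusters a and b (ids < n_leaves are
    leaves) merge at ``height`` into cluster ``n_leaves + k``.
    """

    merges: np.ndarray  # (n-1, 4)
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        n = self.n_leaves
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + k] = h
        return nodes[n + len(self.merges) - 1] + ";"


def ward_cluster(distances: pd.DataFrame, variant: str = "ward.D") -> Dendrogram:
    """Agglomerative Ward clustering of a distance matrix.

    ``ward.D`` applies the Lance-Williams Ward update to the
    dissimilarities as given; ``ward.D2`` applies it to their squares and
    reports square-rooted heights.  Ties in the minimum inter-cluster
    distance are broken by the smallest (i, j) cluster indices.
    """
    if variant not in ("ward.D", "ward.D2"):
        raise ValueError(f"unknown ward variant {variant!r}")
    labels = list(distances.index)
    n = len(labels)
    d = distances.to_numpy(dtype=float).copy()
    if variant == "ward.D2":
        d = d**2
    active = {i: (i, 1) for i in range(n)}  # slot -> (cluster id, size)
    big = math.inf
    work = d.copy()
    np.fill_diagonal(work, big)
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        slots = sorted(active)
        # lowest-index tie-break over the condensed upper triangle
        best = (big, -1, -1)
        for ai in range(len(slots)):
            i = slots[ai]
            row = work[i]
            for bj in range(ai + 1, len(slots)):
                j = slots[bj]
                if row[j] < best[0]:
                    best = (row[j], i, j)
        dist, i, j = best
        ci, ni = active[i]
        cj, nj = active[j]
        height = math.sqrt(dist) if variant == "ward.D2" else dist
        merges[step] = (min(ci, cj), max(ci, cj), height, ni + nj)
        # Lance-Williams Ward update for every other active cluster k
        for k in slots:
            if k in (i, j):
                continue
            nk = active[k][1]
            tot = ni + nj + nk
            dk = (
                (ni + nk) / tot * work[i, k]
                + (nj + nk) / tot * work[j, k]
                - nk / tot * dist
            )
            work[i, k] = work[k, i] = dk
        active[i] = (next_id, ni + nj)
        next_id += 1
        del active[j]
        work[j, :] = big
        work[:, j] = big
    return Dendrogram(merges, labels)


def cut_tree(dendrogram: Dendrogram, n_clusters: int) -> dict[str, int]:
    """Cluster labels from the first ``n_leaves - n_clusters`` merges."""
    n = dendrogram.n_leaves
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters out of range")
    parent = list(range(2 * n - 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for k in range(n - n_clusters):
        a, b, _, _ = dendrogram.merges[k]
        root = n + k
        parent[find(int(a))] = root
        parent[find(int(b))] = root
    roots = {}
    out = {}
    for i, label in enumerate(dendrogram.labels):
        r = find(i)
        out[label] = roots.setdefault(r, len(roots))
    return out


def pca(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Column-centred PCA of sample profiles.

    Returns (scores, loadings, variance fractions); variance fractions
    sum to 1 over the min(n_samples - 1, n_sites) retained components.
    Sign convention: the largest-magnitude loading of each component is
    positive.
    """
    X = profiles.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(X.shape[0] - 1, X.shape[1])
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    for comp in range(k):
        j = np.argmax(np.abs(Vt[comp]))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1.0
            U[:, comp] *= -1.0
    scores = pd.DataFrame(
        U * s, index=profiles.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    loadings = pd.DataFrame(
        Vt.T, index=profiles.columns, columns=scores.columns
    )
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    return scores, loadings, frac


def manhattan_table(
    results: pd.DataFrame, chrom_lengths: dict[str, int] | None = None
) -> pd.DataFrame:
    """Cumulative genome coordinate + -log10(p) for Manhattan plotting."""
    if results.empty:
        return pd.DataFrame(columns=["chrom", "pos", "cum_pos", "neglog10p"])
    chroms = list(dict.fromkeys(results["chrom"]))
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(results.loc[results.chrom == c, "pos"].max()) for c in chroms
        }
    offsets, off = {}, 0
    for c in chroms:
        offsets[c] = off
        off += chrom_lengths.get(c, int(results.loc[results.chrom == c, "pos"].max()))
    out = results[["chrom", "pos", "neglog10p"]].copy()
    out["cum_pos"] = out["pos"] + out["chrom"].map(offsets)
    return out[["chrom", "pos", "cum_pos", "neglog10p"]]


def qq_table(results: pd.DataFrame) -> pd.DataFrame:
    """Observed vs expected -log10(p) under the uniform null, (i - 0.5)/n."""
    if results.empty:
        return pd.DataFrame(columns=["expected", "observed"])
    p = np.sort(results["p"].dropna().to_numpy())
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, 5e-324, 1.0))
    return pd.DataFrame({"expected": expected, "observed": observed})


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """FE - SE methylation difference vs significance."""
    if results.empty:
        return pd.DataFrame(columns=["meth_diff", "neglog10p"])
    return results[["meth_diff", "neglog10p"]].copy()


def mean_methylation(matrix: SiteMatrix) -> pd.Series:
    """Per-sample mean of per-site ratios over complete-case sites."""
    return profile_matrix(matrix).mean(axis=1)
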