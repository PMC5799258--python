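"""Community-level comparison: Bray-Curtis distances, one-way and pairwise
PERMANOVA, non-metric multidimensional scaling, and UPGMA clustering.

PERMANOVA follows the one-way pseudo-F construction on a distance matrix:

    SS_total  = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    F = ((SS_total - SS_within)/(a-1)) / (SS_within/(N-a))

with significance from whole-label permutations and the (b+1)/(m+1)
p-value estimator, so p is never exactly zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .tables_io import RelAbundanceTable


@dataclass
class CommunityDistance:
    """Symmetric pairwise distance matrix over samples."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)

    def submatrix(self, sample_ids: list[str]) -> "CommunityDistance":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CommunityDistance(list(sample_ids), self.d[np.ix_(idx, idx)].copy())

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def read_distance(path: str | Path) -> CommunityDistance:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CommunityDistance([str(s) for s in frame.columns], frame.to_numpy())


def bray_curtis(r: RelAbundanceTable) -> CommunityDistance:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) between sample
    columns; in [0,1] for relative abundances."""
    condensed = pdist(r.values.T, metric="braycurtis")
    return CommunityDistance(list(r.sample_ids), squareform(condensed))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    factor: str
    groups: dict[str, int]  # label -> size
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int


def _ss_within(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> float:
    # sum_g (1/n_g) sum_{i<j in g} d2_ij, via x' D2 x = 2 * within-group pair sum
    quad = (onehot * (d2 @ onehot)).sum(axis=0)
    return float((quad / (2.0 * sizes)).sum())


def permanova(dm: CommunityDistance, labels: list[str], m: int = 9999,
              seed: int = 0, factor: str = "group") -> PermanovaResult:
    """One-way PERMANOVA with seeded whole-label permutations."""
    if len(labels) != dm.n:
        raise ValueError("one label per sample required")
    if m < 99:
        raise ValueError("at least 99 permutations required")
    uniq, codes = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    small = [str(u) for u, s in zip(uniq, sizes) if s < 2]
    if small:
        raise ValueError(f"group(s) with fewer than 2 samples: {', '.join(small)}")
    off = dm.d[~np.eye(dm.n, dtype=bool)]
    if np.ptp(off) < 1e-15:
        raise ValueError("constant distance matrix: pseudo-F undefined")

    N = dm.n
    d2 = dm.d ** 2
    ss_total = d2.sum() / (2.0 * N)
    onehot = np.zeros((N, a))
    onehot[np.arange(N), codes] = 1.0
    sizes_f = sizes.astype(float)

    def f_stat(oh: np.ndarray) -> float:
        ss_w = _ss_within(d2, oh, sizes_f)
        if ss_w <= 0:
            raise ValueError("zero within-group sum of squares: pseudo-F undefined")
        return ((ss_total - ss_w) / (a - 1)) / (ss_w / (N - a))

    f_obs = f_stat(onehot)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(m):
        perm = rng.permutation(N)
        if f_stat(onehot[perm]) >= f_obs:
            b += 1
    return PermanovaResult(
        factor=factor,
        groups={str(u): int(s) for u, s in zip(uniq, sizes)},
        pseudo_F=f_obs,
        p_value=(b + 1) / (m + 1),
        n_permutations=m,
        seed=seed)


def pairwise_permanova(dm: CommunityDistance, labels: list[str], m: int = 9999,
                       seed: int = 0, factor: str = "group") -> list[PermanovaResult]:
    """One PERMANOVA per unordered pair of groups, each on that pair's
    sub-matrix.  Raw p-values are reported (no multiple-testing correction
    by default); see :func:`bonferroni` for an optional adjustment."""
    labels = list(labels)
    uniq = sorted(set(labels))
    results = []
    pair_seeds = np.random.SeedSequence(seed).generate_state(
        len(list(itertools.combinations(uniq, 2)))) % (2 ** 31)
    for k, (g1, g2) in enumerate(itertools.combinations(uniq, 2)):
        keep = [s for s, lab in zip(dm.sample_ids, labels) if lab in (g1, g2)]
        sub_labels = [lab for lab in labels if lab in (g1, g2)]
        sub = dm.submatrix(keep)
        results.append(permanova(sub, sub_labels, m=m, seed=int(pair_seeds[k]),
                                 factor=f"{factor}:{g1}-vs-{g2}"))
    return results


def bonferroni(results: list[PermanovaResult]) -> list[float]:
    k = len(results)
    return [min(1.0, r.p_value * k) for r in results]


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NmdsResult:
    sample_ids: list[str]
    coords: np.ndarray  # samples x dims
    stress: float  # Kruskal stress-1 of the best restart
    n_restarts: int
    converged: bool
    seed: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{k + 1}" for k in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.sample_ids, columns=cols)


def classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson metric scaling used as the deterministic first NMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def kruskal_stress(dm: CommunityDistance, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a fixed configuration: monotone (isotonic)
    disparities fitted to the embedded distances in observed-rank order."""
    d_obs = squareform(dm.d, checks=False)
    d_hat = pdist(np.asarray(coords, dtype=float))
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    disparities = iso.fit_transform(d_obs, d_hat)
    denom = (d_hat ** 2).sum()
    if denom == 0:
        raise ValueError("degenerate configuration: all points coincide")
    return float(np.sqrt(((d_hat - disparities) ** 2).sum() / denom))


def nmds(dm: CommunityDistance, dims: int = 2, n_restarts: int = 20,
         max_iter: int = 300, tol: float = 1e-7, seed: int = 0) -> NmdsResult:
    """Non-metric MDS minimizing Kruskal stress-1 by majorization.

    Initialization is classical metric scaling plus ``n_restarts - 1``
    seeded random starts; the best (lowest-stress) solution is returned, so
    best stress is non-increasing in the number of restarts.
    """
    if dm.n < dims + 2:
        raise ValueError(f"need at least {dims + 2} samples for {dims}-D NMDS")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    off = dm.d[~np.eye(dm.n, dtype=bool)]
    if np.ptp(off) < 1e-15:
        raise ValueError("degenerate distance matrix: all distances equal")

    rng = np.random.default_rng(seed)
    inits = [classical_mds(dm.d, dims)]
    inits += [rng.standard_normal((dm.n, dims)) for _ in range(n_restarts - 1)]

    best: tuple[float, np.ndarray, int] | None = None
    for init in inits:
        coords, stress, n_iter = smacof(
            dm.d, metric=False, n_components=dims, init=init, n_init=1,
            max_iter=max_iter, eps=tol, normalized_stress=True,
            return_n_iter=True)
        if best is None or stress < best[0]:
            best = (float(stress), coords, n_iter)
    stress, coords, n_iter = best
    return NmdsResult(sample_ids=list(dm.sample_ids), coords=coords,
                      stress=stress, n_restarts=n_restarts,
                      converged=n_iter < max_iter, seed=seed)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class UpgmaTree:
    """Rooted ultrametric dendrogram from average-linkage agglomeration."""

    newick: str
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]  # height = d/2

    def cophenetic(self) -> dict[frozenset, float]:
        """Leaf-pair -> cophenetic distance (2x the merge height)."""
        out: dict[frozenset, float] = {}
        for left, right, height in self.merges:
            for a in left:
                for b in right:
                    out[frozenset((a, b))] = 2.0 * height
        return out


def upgma(dm: CommunityDistance) -> UpgmaTree:
    """UPGMA (average-linkage) clustering of the distance matrix.

    Ties between candidate merges are broken by lexicographic order of the
    clusters' smallest member ids, making the tree deterministic.  Each merge
    sits at height d/2 so leaf-to-root path lengths are equal (ultrametric).
    """
    if dm.n < 2:
        raise ValueError("UPGMA needs at least 2 samples")
    # cluster state: members (sorted tuple), height, newick fragment
    clusters: dict[int, tuple[tuple[str, ...], float, str]] = {
        i: ((sid,), 0.0, sid) for i, sid in enumerate(dm.sample_ids)}
    dist: dict[frozenset, float] = {}
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            dist[frozenset((i, j))] = float(dm.d[i, j])

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    next_id = dm.n
    while len(clusters) > 1:
        def sort_key(pair: frozenset) -> tuple:
            i, j = sorted(pair)
            reps = sorted((clusters[i][0][0], clusters[j][0][0]))
            return (dist[pair], reps[0], reps[1])

        best = min(dist, key=sort_key)
        i, j = sorted(best)
        d_ij = dist[best]
        height = d_ij / 2.0
        (mem_i, h_i, nw_i), (mem_j, h_j, nw_j) = clusters[i], clusters[j]
        n_i, n_j = len(mem_i), len(mem_j)
        merged = tuple(sorted(mem_i + mem_j))
        newick = f"({nw_i}:{height - h_i:.10g},{nw_j}:{height - h_j:.10g})"
        merges.append((mem_i, mem_j, height))

        for k in list(clusters):
            if k in (i, j):
                continue
            d_new = (n_i * dist[frozenset((i, k))] + n_j * dist[frozenset((j, k))]) \
                / (n_i + n_j)
            dist[frozenset((next_id, k))] = d_new
        for key in [p for p in dist if i in p or j in p]:
            del dist[key]
        del clusters[i], clusters[j]
        clusters[next_id] = (merged, height, newick)
        next_id += 1

    (_, _, newick) = next(iter(clusters.values()))
    return UpgmaTree(newick=newick + ";", merges=merges)
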