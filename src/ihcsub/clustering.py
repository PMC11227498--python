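"""Agglomerative Ward clustering of the grade matrix and deterministic
labeling of the three clusters as Classical / Transitional / Basal-like.

Merge heights are the Ward criterion itself: the increase in total
within-cluster sum of squares (dESS) caused by the merge, maintained
with the Lance-Williams recurrence.  Ties in merge cost are broken by
the lexicographically smallest pair of cluster representatives (a
cluster is represented by the smallest original case index it
contains), which makes the merge sequence deterministic across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .allred import GradeMatrix, composite_scores
from .cohort import Pattern
from .errors import DegenerateClusteringError, FieldRangeError


@dataclass(frozen=True)
class Merge:
    """One agglomeration step.  ``left``/``right`` are node ids: leaves
    are 0..n-1, the i-th merge creates node n+i."""

    left: int
    right: int
    height: float
    size: int


@dataclass(frozen=True)
class Dendrogram:
    leaf_ids: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise FieldRangeError(
                f"{n} leaves require {n - 1} merges, got {len(self.merges)}"
            )
        heights = [m.height for m in self.merges]
        if any(h < -1e-12 for h in heights):
            raise FieldRangeError("negative merge height")
        if any(b < a - 1e-9 - 1e-9 * abs(a)
               for a, b in zip(heights, heights[1:])):
            raise FieldRangeError("Ward merge heights must be non-decreasing")
        if self.merges and self.merges[-1].size != n:
            raise FieldRangeError("root size must equal the number of leaves")

    @property
    def n(self) -> int:
        return len(self.leaf_ids)


def standardize_columns(values: np.ndarray | GradeMatrix) -> np.ndarray:
    """Center each column to mean 0 and scale to unit sample sd (n-1
    denominator).  Zero-variance columns map to all-zeros."""
    if isinstance(values, GradeMatrix):
        values = values.values
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise FieldRangeError("standardization needs an n x p matrix with n >= 2")
    centered = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    out = np.zeros_like(centered)
    nz = sd > 0
    out[:, nz] = centered[:, nz] / sd[nz]
    return out


def ward_linkage(points: np.ndarray, leaf_ids: Sequence[str] | None = None) -> Dendrogram:
    """Agglomerative Ward clustering of row vectors under Euclidean
    geometry.

    At each step the pair of clusters whose merge minimally increases
    the total within-cluster sum of squares is merged; the merge height
    is that increase.  Cluster-to-cluster costs are maintained with the
    Lance-Williams recurrence, initialized at ||x_i - x_j||^2 / 2 for
    singletons.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise FieldRangeError("ward_linkage requires at least 2 points")
    if leaf_ids is None:
        leaf_ids = tuple(str(i) for i in range(n))
    else:
        leaf_ids = tuple(leaf_ids)
        if len(leaf_ids) != n:
            raise FieldRangeError("leaf_ids length must match point count")

    sq = (x ** 2).sum(axis=1)
    d = (sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)) / 2.0  # dESS of singleton pairs
    np.clip(d, 0.0, None, out=d)
    np.fill_diagonal(d, np.inf)

    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=np.int64)
    reps = np.arange(n)          # smallest original index in each cluster
    node_of = np.arange(n)       # dendrogram node id at each slot
    merges: list[Merge] = []

    for step in range(n - 1):
        dm = np.where(active[:, None] & active[None, :], d, np.inf)
        m = dm.min()
        ii, jj = np.where(dm <= m)
        # deterministic tie-break: smallest (rep_i, rep_j) with rep_i < rep_j
        best = None
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            pair = (min(reps[a], reps[b]), max(reps[a], reps[b]))
            if best is None or pair < best[0]:
                best = (pair, int(a), int(b))
        _pair, i, j = best
        ni, nj = sizes[i], sizes[j]
        merges.append(Merge(left=int(node_of[i]), right=int(node_of[j]),
                            height=float(m), size=int(ni + nj)))
        # Lance-Williams update for Ward on dESS values
        k = active.copy()
        k[i] = k[j] = False
        nk = sizes[k]
        d_new = ((ni + nk) * d[i, k] + (nj + nk) * d[j, k] - nk * d[i, j]) \
            / (ni + nj + nk)
        d[i, k] = d_new
        d[k, i] = d_new
        active[j] = False
        sizes[i] = ni + nj
        reps[i] = min(reps[i], reps[j])
        node_of[i] = n + step
        d[j, :] = np.inf
        d[:, j] = np.inf

    return Dendrogram(leaf_ids=leaf_ids, merges=tuple(merges))


def cut_k(dendrogram: Dendrogram, k: int) -> list[int]:
    """Cut the dendrogram into k clusters by removing the k-1 highest
    merges.  Returns one integer label per leaf; labels are numbered by
    first-occurring leaf (label 0 contains leaf 0)."""
    n = dendrogram.n
    if not (1 <= k <= n):
        raise FieldRangeError(f"k={k} outside 1..{n}")
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    # merges are emitted in non-decreasing height order: keep the first n-k
    for idx, merge in enumerate(dendrogram.merges[: n - k]):
        node = n + idx
        parent[find(merge.left)] = node
        parent[find(merge.right)] = node

    labels: dict[int, int] = {}
    out = []
    for leaf in range(n):
        root = find(leaf)
        if root not in labels:
            labels[root] = len(labels)
        out.append(labels[root])
    return out


@dataclass(frozen=True)
class PatternAssignment:
    """Case -> pattern map plus per-cluster mean composite scores."""

    assignment: dict[str, Pattern]
    cluster_means: dict[Pattern, float]
    cluster_sizes: dict[Pattern, int]


def label_patterns(labels: Sequence[int], matrix: GradeMatrix) -> PatternAssignment:
    """Name exactly three clusters from their mean composite score:
    highest -> Basal-like, lowest -> Classical, middle -> Transitional.
    Ties go to the smaller cluster as Basal-like (the minority pattern).
    """
    labels = list(labels)
    if len(labels) != matrix.n:
        raise FieldRangeError("labels length must match the grade matrix")
    uniq = sorted(set(labels))
    if len(uniq) != 3:
        raise DegenerateClusteringError(
            f"pattern labeling is defined for exactly 3 clusters, got {len(uniq)}"
        )
    comps = composite_scores(matrix)
    stats = []
    for lab in uniq:
        mask = np.array([l == lab for l in labels])
        stats.append((float(comps[mask].mean()), int(mask.sum()), lab))
    if len({s[0] for s in stats}) == 1:
        raise DegenerateClusteringError(
            "all clusters share the same mean composite score; "
            "no basal/classical ordering exists"
        )
    # ascending mean; among ties the larger cluster sorts first, so the
    # smaller of two tied top clusters ends up Basal-like
    stats.sort(key=lambda s: (s[0], -s[1], s[2]))
    pattern_of_label = {
        stats[0][2]: Pattern.CLASSICAL,
        stats[1][2]: Pattern.TRANSITIONAL,
        stats[2][2]: Pattern.BASAL_LIKE,
    }
    assignment = {
        case_id: pattern_of_label[lab]
        for case_id, lab in zip(matrix.case_ids, labels)
    }
    means = {pattern_of_label[lab]: mean for mean, _sz, lab in stats}
    sizes = {pattern_of_label[lab]: sz for _m, sz, lab in stats}
    return PatternAssignment(assignment=assignment, cluster_means=means,
                             cluster_sizes=sizes)


def cluster_cohort(matrix: GradeMatrix, *, k: int = 3,
                   standardize: bool = True) -> tuple[Dendrogram, list[int]]:
    """Standardize (optionally), run Ward linkage, and cut at k."""
    points = standardize_columns(matrix) if standardize else matrix.values.astype(float)
    dendrogram = ward_linkage(points, leaf_ids=matrix.case_ids)
    return dendrogram, cut_k(dendrogram, k)


def to_newick(dendrogram: Dendrogram) -> str:
    """Render the merge tree as a Newick string with branch lengths
    (parent height minus child height; leaves sit at height 0)."""
    n = dendrogram.n
    height = {i: 0.0 for i in range(n)}
    text = {i: _escape_newick(dendrogram.leaf_ids[i]) for i in range(n)}
    for idx, m in enumerate(dendrogram.merges):
        node = n + idx
        height[node] = m.height
        bl_l = max(m.height - height[m.left], 0.0)
        bl_r = max(m.height - height[m.right], 0.0)
        text[node] = f"({text[m.left]}:{bl_l:.10g},{text[m.right]}:{bl_r:.10g})"
    root = n + len(dendrogram.merges) - 1 if dendrogram.merges else 0
    return text[root] + ";"


def _escape_newick(label: str) -> str:
    if any(ch in label for ch in "();:,' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label
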