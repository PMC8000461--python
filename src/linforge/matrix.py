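"""Complete similarity matrices inferred from LINs + recorded ANI values.

Only one precise ANI is computed per added genome, yet every pairwise cell
can be filled: two genomes whose LINs first differ at position p diverged in
a recorded event — the moment the later branch's founder was assigned a fresh
number at p. That founder's recorded ANI (against a genome carrying the other
branch's number whenever the record spans the two branches) is propagated to
every cross-branch pair. When no usable record exists the threshold of the
last shared position is the fallback. A direct record between the two genomes
always wins.

The propagation rule makes the "merging" behaviour explicit: all pairs across
two branches collapse onto the handful of ANI values recorded at their
divergence events, which is the price paid for doing n-1 alignments instead
of n(n-1)/2.

Also here: complete-linkage clustering of a similarity matrix (on distance
100 - ANI) with Newick export, and the Mantel permutation test with Pearson
correlation for comparing two matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .scheme import LINScheme
from .store import Store


@dataclass
class SimilarityMatrix:
    """Symmetric labelled matrix of pairwise similarities.

    ``kind`` is "ani" (percent, diagonal 100) or "jaccard" (fraction,
    diagonal 1).
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "ani"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        self.values = v

    @property
    def diagonal_value(self) -> float:
        return 100.0 if self.kind == "ani" else 1.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def save(self, path: str | Path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index_label="genome")

    @classmethod
    def load(cls, path: str | Path, kind: str = "ani", sep: str = "\t") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(labels=list(df.index), values=df.to_numpy(), kind=kind)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


def _first_diff(a: list[int], b: list[int]) -> int | None:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i
    return None


class _Inferrer:
    """Shared state for inferring many pairs from one store snapshot."""

    def __init__(self, store: Store, scheme: LINScheme):
        self.scheme = scheme
        self.lins = store.lins(scheme.name)
        self.order = {g.genome_id: g.insertion_order for g in store.genomes()}
        self.direct: dict[frozenset, float] = {}
        self.record_of: dict[str, tuple[str, float]] = {}
        for rec in store.ani_records():
            self.direct[frozenset((rec.query_id, rec.subject_id))] = rec.ani
            self.record_of[rec.query_id] = (rec.subject_id, rec.ani)

    def _branch_founder(self, prefix: list[int], number: int, position: int) -> str:
        """Earliest genome whose LIN carries ``number`` at ``position`` under ``prefix``."""
        best = None
        for gid, lin in self.lins.items():
            if lin[position] == number and lin[:position] == prefix:
                if best is None or self.order[gid] < self.order[best]:
                    best = gid
        return best

    def infer(self, x: str, y: str) -> float:
        """Pairwise ANI: direct record, else divergence-event propagation."""
        if x == y:
            return 100.0
        key = frozenset((x, y))
        if key in self.direct:
            return self.direct[key]
        lin_x, lin_y = self.lins[x], self.lins[y]
        if len(lin_x) != len(lin_y):
            raise ValueError("LINs of unequal length cannot be compared")
        p = _first_diff(lin_x, lin_y)
        if p is None:
            # identical LINs without a direct record: both reach the top
            # threshold of the scheme relative to their shared lineage
            return self._founder_fallback(lin_x, len(self.scheme) - 1)
        prefix = lin_x[:p]
        fx = self._branch_founder(prefix, lin_x[p], p)
        fy = self._branch_founder(prefix, lin_y[p], p)
        # the later-created branch's founding event recorded the divergence
        later = fx if self.order[fx] > self.order[fy] else fy
        rec = self.record_of.get(later)
        if rec is not None:
            # the founding record either spans the two branches (its subject
            # carries the other branch's number at p) or was taken against a
            # third branch under the same prefix; either way it is the stored
            # measurement of this divergence event and lies in the same
            # threshold bracket, so its value is propagated
            return rec[1]
        # founder had no ANI computation (first genome / novel): last shared threshold
        return self.scheme.threshold(p - 1) if p > 0 else 0.0

    def _founder_fallback(self, lin: list[int], position: int) -> float:
        for gid, other in self.lins.items():
            if other == lin and gid in self.record_of:
                return self.record_of[gid][1]
        return self.scheme.threshold(position)


def infer_pairwise(x: str, y: str, store: Store, scheme: LINScheme | None = None) -> float:
    """Infer one pairwise ANI value from the store's LINs and ANI records."""
    scheme = scheme or store.grouping_scheme
    return _Inferrer(store, scheme).infer(x, y)


def full_matrix(store: Store, scheme: LINScheme | None = None) -> SimilarityMatrix:
    """All-against-all ANI from n-1 recorded computations plus inference."""
    scheme = scheme or store.grouping_scheme
    genomes = [g.genome_id for g in store.genomes()]
    if not genomes:
        raise ValueError("store holds no genomes")
    inf = _Inferrer(store, scheme)
    n = len(genomes)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = inf.infer(genomes[i], genomes[j])
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(labels=genomes, values=values, kind="ani")


def complete_linkage(matrix: SimilarityMatrix) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering with complete linkage on 100 - ANI (or 1 - J).

    Returns the SciPy linkage matrix and the deterministic leaf order
    (dendrogram order; ties resolved by input label order, which SciPy's
    deterministic agglomeration preserves).
    """
    dist = matrix.diagonal_value - matrix.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if condensed.size == 0:
        return np.empty((0, 4)), list(matrix.labels)
    linkage = hierarchy.linkage(condensed, method="complete")
    leaves = hierarchy.leaves_list(linkage)
    return linkage, [matrix.labels[i] for i in leaves]


def cut_clusters(linkage: np.ndarray, labels: list[str], height: float) -> dict[str, int]:
    """Flat clusters of a linkage at the given distance threshold."""
    if linkage.size == 0:
        return {labels[0]: 1}
    assignment = hierarchy.fcluster(linkage, t=height, criterion="distance")
    return dict(zip(labels, (int(c) for c in assignment)))


def to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage as a Newick tree with branch lengths."""
    if linkage.size == 0:
        return f"{labels[0]};"
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def mantel(
    m1: SimilarityMatrix,
    m2: SimilarityMatrix,
    permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test: Pearson r of the two upper triangles plus permutation p.

    The p-value counts simultaneous row/column permutations of ``m2`` whose
    correlation meets or exceeds the observed one, with the +1/+1 convention:
    p = (1 + #{r_perm >= r_obs}) / (permutations + 1).
    """
    if m1.labels != m2.labels:
        raise ValueError("matrices must share labels in the same order")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    v1 = m1.upper_triangle()
    v2 = m2.upper_triangle()
    if np.std(v1) == 0 or np.std(v2) == 0:
        warnings.warn("constant matrix: Mantel correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(m1.labels)
    iu = np.triu_indices(n, k=1)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        permuted = m2.values[np.ix_(perm, perm)][iu]
        r_perm = float(np.corrcoef(v1, permuted)[0, 1])
        if r_perm >= r_obs:
            hits += 1
    p = (1 + hits) / (permutations + 1)
    return r_obs, p


def heatmap(matrix: SimilarityMatrix, path: str | Path, order: list[str] | None = None) -> None:
    """Save a clustered (or caller-ordered) heatmap image of the matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if order is None:
        _, order = complete_linkage(matrix)
    idx = [matrix.labels.index(g) for g in order]
    vals = matrix.values[np.ix_(idx, idx)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(vals, cmap="RdYlBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="ANI (%)" if matrix.kind == "ani" else "Jaccard")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
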