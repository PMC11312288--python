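"""Comparison of microglial population signatures.

A *signature* is a vector of per-gene expression summaries (here log2
fold-changes against each study's own control) on a shared gene panel; a
:class:`SignatureSet` stacks ``n`` population signatures over ``n'`` panel
genes. Populations are compared through two n x n matrices:

* the **distance matrix** ``D`` with ``d_ij = sqrt(sum_k (i_k - j_k)^2)``,
  the Euclidean distance between signature vectors — the closer two
  populations, the more similar their regulation; and
* the **cross-correlation matrix** ``C`` with ``c_ij = |cos theta| =
  |i . j| / (||i|| ||j||)``, the magnitude of the cosine of the angle
  between the vectors, so every entry lies in [0, 1]: 0 means no linear
  relationship, 1 means the profiles are equivalent up to scale. The
  modulus makes anti-correlated profiles score as similar; pass
  ``signed=True`` for the signed cosine as a sensitivity analysis.

``D`` is embedded into Cartesian coordinates by classical (Torgerson)
multidimensional scaling and summarised by average-linkage hierarchical
clustering with a deterministic lexicographic tie-break.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class SignatureSet:
    """Populations x genes matrix of signature values.

    ``values`` rows are populations (>= 2, unique names), columns are the
    shared gene panel (>= 1, unique names); entries must be finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate population names")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate gene names")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 populations")
        if self.values.shape[1] < 1:
            raise ValueError("need at least 1 gene attribute")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("signature matrix contains non-finite values")

    @property
    def populations(self) -> list[str]:
        return [str(x) for x in self.values.index]

    @property
    def genes(self) -> list[str]:
        return [str(x) for x in self.values.columns]


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal Euclidean distance matrix with labels."""

    labels: list[str]
    d: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class CorrelationMatrix:
    """Symmetric |cos theta| matrix; unit diagonal, entries in [0, 1]."""

    labels: list[str]
    c: np.ndarray
    signed: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.c, index=self.labels, columns=self.labels)


@dataclass
class MDSEmbedding:
    """Classical-MDS coordinates with eigenvalues and residual stress."""

    labels: list[str]
    coordinates: np.ndarray  # n x k
    eigenvalues: np.ndarray  # k, non-increasing
    stress: float


@dataclass
class DendrogramSpec:
    """Average-linkage agglomeration in scipy linkage-matrix layout.

    ``merges`` rows are ``(id_a, id_b, height, size)``; leaves carry ids
    ``0..n-1`` in ``labels`` order and merge ``m`` creates id ``n + m``.
    """

    labels: list[str]
    merges: np.ndarray  # (n-1) x 4
    leaf_order: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def build_signature(deg: pd.DataFrame, panel: Sequence[str]) -> pd.Series:
    """Project a DEG table onto ``panel``: log2fc values in panel order."""
    missing = [g for g in panel if g not in deg.index]
    if missing:
        raise KeyError(f"panel genes missing from DEG table: {missing}")
    return deg.loc[list(panel), "log2fc"].copy()


def align_gene_panels(sets: Sequence[SignatureSet]) -> SignatureSet:
    """Merge collections onto their case-insensitive common gene panel.

    Gene symbols are matched after case-folding; the merged panel is the
    intersection across all sets, in deterministic case-folded sorted
    order, spelled as in the first set. Populations are concatenated.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 signature sets to align")
    folded_maps = []
    for s in sets:
        folded = [g.casefold() for g in s.genes]
        if len(set(folded)) != len(folded):
            dupes = sorted({g for g in folded if folded.count(g) > 1})
            raise ValueError(f"duplicate gene symbols after case-folding: {dupes}")
        folded_maps.append(dict(zip(folded, s.genes)))
    common = set(folded_maps[0])
    for m in folded_maps[1:]:
        common &= set(m)
    if not common:
        raise ValueError("gene panels share no symbol (case-insensitive intersection is empty)")
    panel_folded = sorted(common)
    panel = [folded_maps[0][g] for g in panel_folded]

    pops: list[str] = []
    for s in sets:
        pops.extend(s.populations)
    if len(set(pops)) != len(pops):
        raise ValueError("duplicate population names across signature sets")

    blocks = []
    for s, m in zip(sets, folded_maps):
        cols = [m[g] for g in panel_folded]
        block = s.values[cols].copy()
        block.columns = panel
        blocks.append(block)
    return SignatureSet(values=pd.concat(blocks, axis=0))


def distance_matrix(sig: SignatureSet) -> DistanceMatrix:
    """Pairwise Euclidean distances between population signatures."""
    x = sig.values.to_numpy(dtype=float)
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    d = np.sqrt(np.clip(d2, 0.0, None))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=sig.populations, d=d)


def correlation_matrix(sig: SignatureSet, signed: bool = False) -> CorrelationMatrix:
    """Cosine cross-correlation ``c_ij = |i.j| / (||i|| ||j||)``.

    A zero-magnitude signature has no direction, so it is rejected by
    name rather than silently mapped to "no relationship".
    """
    x = sig.values.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=1)
    zero = np.asarray(norms == 0).nonzero()[0]
    if zero.size:
        names = [sig.populations[i] for i in zero]
        raise ValueError(f"zero-magnitude signature vector(s): {names}")
    c = (x @ x.T) / np.outer(norms, norms)
    c = np.clip(0.5 * (c + c.T), -1.0, 1.0)
    if not signed:
        c = np.abs(c)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(labels=sig.populations, c=c, signed=signed)


def classical_mds(dm: DistanceMatrix, k: int = 2) -> MDSEmbedding:
    """Torgerson classical multidimensional scaling of ``dm`` into k dims.

    Double-centres ``-0.5 * d^2``, eigendecomposes, and builds coordinates
    from the top-k eigenpairs (negative eigenvalues contribute zero
    coordinates). Each axis's sign is fixed by forcing its largest-
    magnitude coordinate positive, so the embedding is reproducible.
    Stress is the relative residual ``sqrt(sum (d - d_hat)^2 / sum d^2)``
    (0 for an all-zero distance matrix).
    """
    d = np.asarray(dm.d, dtype=float)
    n = d.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(0.5 * (b + b.T))
    order = np.argsort(evals)[::-1][:k]
    lam = evals[order]
    coords = evecs[:, order] * np.sqrt(np.clip(lam, 0.0, None))
    for axis in range(k):
        i = int(np.argmax(np.abs(coords[:, axis])))
        if coords[i, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    diff = coords[:, None, :] - coords[None, :, :]
    dhat = np.sqrt((diff**2).sum(axis=-1))
    denom = float((d**2).sum())
    stress = float(np.sqrt(((d - dhat) ** 2).sum() / denom)) if denom > 0 else 0.0
    return MDSEmbedding(labels=list(dm.labels), coordinates=coords, eigenvalues=lam, stress=stress)


def hierarchical_cluster(dm: DistanceMatrix) -> DendrogramSpec:
    """Average-linkage agglomerative clustering of a distance matrix.

    Uses the Lance–Williams update for average linkage. Ties in the
    minimum inter-cluster distance are broken deterministically by the
    lexicographically smallest pair of cluster representative labels
    (a cluster is represented by its smallest member label).
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 populations to cluster")
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for jj in range(i + 1, n):
            dist[(i, jj)] = float(dm.d[i, jj])
    active: dict[int, tuple[str, int]] = {i: (labels[i], 1) for i in range(n)}  # id -> (rep, size)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = np.zeros((n - 1, 4))

    def pair_key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    for step in range(n - 1):
        best = None
        for (a, b), d_ab in dist.items():
            reps = tuple(sorted((active[a][0], active[b][0])))
            cand = (d_ab, reps, pair_key(a, b))
            if best is None or cand < best:
                best = cand
        d_ab, _, (a, b) = best  # type: ignore[misc]
        na, nb = active[a][1], active[b][1]
        new_id = n + step
        merges[step] = (a, b, d_ab, na + nb)
        for other in list(active):
            if other in (a, b):
                continue
            da = dist.pop(pair_key(a, other))
            db = dist.pop(pair_key(b, other))
            dist[pair_key(new_id, other)] = (na * da + nb * db) / (na + nb)
        del dist[pair_key(a, b)]
        rep = min(active[a][0], active[b][0])
        members[new_id] = members[a] + members[b]
        del active[a], active[b]
        active[new_id] = (rep, na + nb)

    def expand(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = int(merges[node - n, 0]), int(merges[node - n, 1])
        def smallest_rep(x: int) -> str:
            return min(labels[i] for i in members[x])
        first, second = (a, b) if smallest_rep(a) <= smallest_rep(b) else (b, a)
        return expand(first) + expand(second)

    leaf_order = [labels[i] for i in expand(2 * n - 2)]
    return DendrogramSpec(labels=labels, merges=merges, leaf_order=leaf_order)


def cut_clusters(spec: DendrogramSpec, k: int) -> dict[str, int]:
    """Flat clustering with ``k`` clusters: undo the last ``k - 1`` merges."""
    n = len(spec.labels)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = int(spec.merges[step, 0]), int(spec.merges[step, 1])
        new_id = n + step
        parent[find(a)] = new_id
        parent[find(b)] = new_id
    roots: dict[int, int] = {}
    out = {}
    for i, lab in enumerate(spec.labels):
        r = find(i)
        out[lab] = roots.setdefault(r, len(roots))
    return out


def to_newick(spec: DendrogramSpec) -> str:
    """Newick string of the dendrogram; leaf-to-leaf path length equals merge height."""
    n = len(spec.labels)

    def height(node: int) -> float:
        return 0.0 if node < n else float(spec.merges[node - n, 2])

    def render(node: int) -> str:
        if node < n:
            return spec.labels[node]
        a, b = int(spec.merges[node - n, 0]), int(spec.merges[node - n, 1])
        h = height(node)
        return "({}:{:.10g},{}:{:.10g})".format(
            render(a), (h - height(a)) / 2.0, render(b), (h - height(b)) / 2.0
        )

    return render(2 * n - 2) + ";"


def correlation_long_format(cm: CorrelationMatrix) -> pd.DataFrame:
    """Heatmap-ready long format: one row per (population_i, population_j, c)."""
    rows = [
        {"population_i": a, "population_j": b, "c": float(cm.c[i, jj])}
        for i, a in enumerate(cm.labels)
        for jj, b in enumerate(cm.labels)
    ]
    return pd.DataFrame(rows)
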