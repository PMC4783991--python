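"""Distance-based phylogeny: Tamura-Nei (1993) distances, Saitou-Nei
neighbor joining, and a small-parsimony count of independent gene-loss
events on the resulting tree.

Gap handling is pairwise deletion: a site enters a pair's distance only
when both sequences carry an unambiguous base there.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import SequenceRecord

_BASES = ("A", "C", "G", "T")
FUNCTIONAL = "functional"
DISABLED = "disabled"


class DistanceError(ValueError):
    pass


def tn93_distance(a: str, b: str) -> float:
    """Tamura-Nei (1993) distance between two aligned sequences.

    Uses empirical base frequencies pooled over the comparable sites of the
    pair and distinguishes the purine (A<->G) and pyrimidine (C<->T)
    transition classes from transversions. Sites where either sequence has
    a gap or N are skipped (pairwise deletion). Returns ``math.inf`` when a
    logarithm argument is non-positive (saturation); raises
    :class:`DistanceError` when no comparable sites remain.
    """
    if len(a) != len(b):
        raise DistanceError("sequences must be aligned to equal length")
    pairs = [(x, y) for x, y in zip(a, b) if x in _BASES and y in _BASES]
    L = len(pairs)
    if L == 0:
        raise DistanceError("no comparable sites between the two sequences")

    counts = {base: 0 for base in _BASES}
    p1 = p2 = q = 0
    for x, y in pairs:
        counts[x] += 1
        counts[y] += 1
        if x != y:
            pair = {x, y}
            if pair == {"A", "G"}:
                p1 += 1
            elif pair == {"C", "T"}:
                p2 += 1
            else:
                q += 1
    freqs = {base: counts[base] / (2 * L) for base in _BASES}
    gA, gC, gG, gT = (freqs[b] for b in _BASES)
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = p1 / L, p2 / L, q / L

    k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2.0 * gC * gT / gY if gY > 0 else 0.0
    k3 = 2.0 * (gR * gY - (gA * gG * gY / gR if gR > 0 else 0.0)
                - (gC * gT * gR / gY if gY > 0 else 0.0))

    d = 0.0
    # Purine-transition term (vanishes in the limit of absent purine pairs).
    if P1 > 0 or Q > 0:
        if k1 > 0:
            w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
            if w1 <= 0:
                return math.inf
            d -= k1 * math.log(w1)
        elif P1 > 0:
            return math.inf
    if P2 > 0 or Q > 0:
        if k2 > 0:
            w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
            if w2 <= 0:
                return math.inf
            d -= k2 * math.log(w2)
        elif P2 > 0:
            return math.inf
    if Q > 0:
        if gR <= 0 or gY <= 0:
            return math.inf
        w3 = 1.0 - Q / (2.0 * gR * gY)
        if w3 <= 0:
            return math.inf
        d -= k3 * math.log(w3)
    return max(d, 0.0)


def p_distance(a: str, b: str) -> float:
    """Raw proportion of differing comparable sites (pairwise deletion)."""
    pairs = [(x, y) for x, y in zip(a, b) if x in _BASES and y in _BASES]
    if not pairs:
        raise DistanceError("no comparable sites between the two sequences")
    return sum(1 for x, y in pairs if x != y) / len(pairs)


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise DistanceError("matrix shape does not match ids")
        if not np.allclose(np.diag(m), 0.0):
            raise DistanceError("nonzero diagonal")
        if not np.allclose(m, m.T):
            raise DistanceError("matrix not symmetric")
        if (m < 0).any():
            raise DistanceError("negative distances")

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord] | Mapping[str, str],
                     metric=tn93_distance) -> "DistanceMatrix":
        if isinstance(records, Mapping):
            items = list(records.items())
        else:
            items = [(r.id, r.seq) for r in records]
        ids = tuple(rid for rid, _ in items)
        n = len(ids)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = metric(items[i][1], items[j][1])
        return cls(ids=ids, matrix=m)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


@dataclasses.dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = dataclasses.field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child, _ in self.children for leaf in child.leaves()]

    def leaf_names(self) -> set[str]:
        return {leaf.name for leaf in self.leaves()}

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return self.name or ""
        inner = ",".join(
            f"{child._newick()}:{bl:.10g}" for child, bl in self.children
        )
        return f"({inner}){self.name or ''}"


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; the returned root is the final
    unresolved (trifurcating) node.

    Ties in the Q matrix are broken toward the lowest index pair, so the
    topology is deterministic. A negative branch length is clamped to zero
    with the deficit moved to its sibling branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise DistanceError("neighbor joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    D = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                qv = (r - 2) * D[i, j] - R[i] - R[j]
                if best is None or qv < best[0] - 1e-12:
                    best = (qv, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        li, lj = _redistribute_negative(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])

        # Reuse slot i for the new node; retire slot j.
        for k in active:
            if k not in (i, j):
                D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode(children=[
        (nodes[i], max(li, 0.0)), (nodes[j], max(lj, 0.0)), (nodes[k], max(lk, 0.0)),
    ])
    return root


def _redistribute_negative(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def min_independent_losses(tree: TreeNode, calls: Mapping[str, str]) -> int:
    """Minimum number of state changes for the binary functional/disabled
    character on the tree, with the root constrained to the functional
    (ancestral) state — the quantitative form of "the gene was disabled
    many times independently".

    Small-parsimony dynamic programme (unit change costs, arbitrary node
    degrees); with the root forced functional every optimal labeling spends
    one change per independent loss.
    """
    states = (FUNCTIONAL, DISABLED)

    def cost(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            if node.name not in calls:
                raise KeyError(f"no functionality status for leaf {node.name!r}")
            observed = calls[node.name]
            if observed not in states:
                raise ValueError(f"unknown status {observed!r} for leaf {node.name!r}")
            return {s: (0.0 if s == observed else math.inf) for s in states}
        child_costs = [cost(child) for child, _ in node.children]
        return {
            s: sum(
                min(cc[t] + (0.0 if s == t else 1.0) for t in states)
                for cc in child_costs
            )
            for s in states
        }
    total = cost(tree)[FUNCTIONAL]
    if math.isinf(total):  # pragma: no cover - unreachable with valid calls
        raise ValueError("no feasible labeling")
    return int(total)
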