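"""Progressive multiple alignment, neighbor joining and bootstrap support.

The MSA is a CLUSTALW-style progressive aligner: a guide tree from NJ on
pairwise alignment distances (1 - identity), then profile merges along the
guide tree with average sum-of-pairs affine-gap scoring. It deliberately
omits sequence weighting and iterative refinement; the tree stage then uses
p-distances and Saitou-Nei neighbor joining, with support from column
bootstrap (resampling alignment columns with replacement and counting how
often each original bipartition recurs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment import GAP_CODE, Profile, encode, global_align, profile_align
from .errors import ParameterError, ValidationError
from .records import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedFamily:
    """A multiple alignment: ordered row ids and equal-length gapped rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or not self.ids:
            raise ValidationError("ids and rows must be non-empty and parallel")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("alignment row ids must be unique")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValidationError("alignment rows must all have the same length")

    @classmethod
    def from_ungapped(cls, records: Sequence[ProteinRecord]) -> "AlignedFamily":
        """Treat equal-length sequences as already aligned, column for column."""
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise ValidationError("from_ungapped requires equal-length sequences")
        return cls(tuple(r.id for r in records), tuple(r.sequence for r in records))

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.ids.index(row_id)]
        except ValueError:
            raise ValidationError(f"row {row_id!r} not in alignment") from None

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace("-", "")

    def column_map(self, row_id: str) -> list[Optional[int]]:
        """Per column: the row's 0-based residue index, or None at a gap."""
        out: list[Optional[int]] = []
        k = 0
        for ch in self.row(row_id):
            if ch == "-":
                out.append(None)
            else:
                out.append(k)
                k += 1
        return out

    def encoded(self) -> np.ndarray:
        """(n_rows, width) symbol-code matrix."""
        return np.vstack([encode(r) for r in self.rows])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")


def progressive_msa(
    records: Sequence[ProteinRecord],
    matrix: str = "PAM250",
    gap_open: float = 10.0,
    gap_extend: float = 0.1,
) -> AlignedFamily:
    """Progressive profile alignment along an NJ guide tree.

    Deterministic: pairwise guide distances are 1 - identity from affine-gap
    global alignments, the guide tree is NJ with fixed tie-breaks, and merges
    happen in postorder. Row order of the result matches the input order.
    """
    if not records:
        raise ParameterError("progressive_msa needs at least one record")
    if len(records) == 1:
        warnings.warn("progressive_msa called with a single record; returned as-is")
        return AlignedFamily((records[0].id,), (records[0].sequence,))
    profiles = {r.id: Profile.from_record(r) for r in records}
    if len(records) == 2:
        _, merged = profile_align(
            profiles[records[0].id], profiles[records[1].id], matrix, gap_open, gap_extend
        )
    else:
        n = len(records)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                res = global_align(records[i], records[j], matrix, gap_open, gap_extend)
                dist[i, j] = dist[j, i] = 1.0 - res.identity
        guide = nj_tree(dist, [r.id for r in records])
        merged = _merge_along(guide.root, profiles, matrix, gap_open, gap_extend)
    by_id = dict(zip(merged.ids, merged.rows))
    fam = AlignedFamily(
        tuple(r.id for r in records), tuple(by_id[r.id] for r in records)
    )
    for r in records:
        if fam.ungapped(r.id) != r.sequence:
            raise AssertionError(f"MSA corrupted sequence {r.id!r}")
    return fam


def _merge_along(node: "TreeNode", profiles, matrix, gap_open, gap_extend) -> Profile:
    if not node.children:
        return profiles[node.name]
    parts = [
        _merge_along(c, profiles, matrix, gap_open, gap_extend) for c in node.children
    ]
    merged = parts[0]
    for nxt in parts[1:]:
        _, merged = profile_align(merged, nxt, matrix, gap_open, gap_extend)
    return merged


def alignment_sp_score(
    fam: AlignedFamily,
    matrix: str = "PAM250",
    gap_open: float = 10.0,
    gap_extend: float = 0.1,
) -> float:
    """Average sum-of-pairs affine-gap score of an existing alignment.

    For two rows this is exactly the pairwise scoring of that alignment (each
    maximal gap run costs ``gap_open + (k-1)*gap_extend``).
    """
    from .alignment import load_matrix

    mat = load_matrix(matrix)
    n = len(fam.rows)
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += _pair_score(fam.rows[i], fam.rows[j], mat, gap_open, gap_extend)
            pairs += 1
    return total / pairs if pairs else 0.0


def _pair_score(a: str, b: str, mat: np.ndarray, gap_open: float, gap_extend: float) -> float:
    ea, eb = encode(a), encode(b)
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(ea, eb):
        if x == GAP_CODE and y == GAP_CODE:
            continue
        if x == GAP_CODE:
            score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == GAP_CODE:
            score -= gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += mat[x, y]
            in_gap_a = in_gap_b = False
    return score


def p_distance_matrix(fam: AlignedFamily) -> np.ndarray:
    """Pairwise mismatch fractions over columns without a gap in either row."""
    arr = fam.encoded()
    n = arr.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != GAP_CODE) & (arr[j] != GAP_CODE)
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValidationError(
                    f"rows {fam.ids[i]!r} and {fam.ids[j]!r} share no gap-free columns"
                )
            d = float(np.count_nonzero(arr[i][ok] != arr[j][ok])) / comparable
            dist[i, j] = dist[j, i] = d
    return dist


class TreeNode:
    """Node of an (unrooted, stored rooted at a trifurcation) phylogeny."""

    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name=None, length=0.0, children=None, support=None):
        self.name = name
        self.length = length
        self.support = support
        self.children = children if children is not None else []

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths and optional bootstrap supports."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def splits(self) -> set[frozenset]:
        """Canonical nontrivial bipartitions (side not containing the anchor leaf)."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: set[frozenset] = set()

        def visit(node: TreeNode) -> frozenset:
            if not node.children:
                return frozenset([node.name])
            side = frozenset().union(*(visit(c) for c in node.children))
            if node is not self.root and 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side if anchor not in side else all_leaves - side)
            return side

        visit(self.root)
        return out

    def annotate_supports(self, support: dict[frozenset, float]) -> None:
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)

        def visit(node: TreeNode) -> frozenset:
            if not node.children:
                return frozenset([node.name])
            side = frozenset().union(*(visit(c) for c in node.children))
            if node is not self.root and 2 <= len(side) <= len(all_leaves) - 2:
                key = side if anchor not in side else all_leaves - side
                node.support = support.get(key, 0.0)
            return side

        visit(self.root)

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:.4f}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def nj_tree(dist: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q-criterion is joined at each step (ties broken by
    the smallest index pair); negative branch lengths are clamped to zero with
    the deficit transferred to the sister edge. On an additive matrix this
    recovers the generating topology and branch lengths exactly.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    n = dist.shape[0]
    if n != len(labels):
        raise ValidationError("labels must match matrix dimension")
    if n < 2:
        raise ParameterError("neighbor joining needs at least 2 taxa")
    nodes = [TreeNode(name=lab) for lab in labels]
    d = dist.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.unravel_index(np.argmin(q), q.shape)  # first occurrence: smallest (i, j)
        ai, aj = sorted((best[0], best[1]))
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # distances from the new node to every other active node
        others = [k for k in active if k != i and k != j]
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in others:
            d[u, k] = d[k, u] = max(0.0, (d[i, k] + d[j, k] - dij) / 2.0)
        nodes.append(new)
        active = others + [u]

    if len(active) == 2:
        i, j = active
        root = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = nodes[j].length = d[i, j] / 2.0
        return PhyloTree(root)

    i, j, k = active
    li = max(0.0, (d[i, j] + d[i, k] - d[j, k]) / 2.0)
    lj = max(0.0, (d[i, j] + d[j, k] - d[i, k]) / 2.0)
    lk = max(0.0, (d[i, k] + d[j, k] - d[i, j]) / 2.0)
    nodes[i].length, nodes[j].length, nodes[k].length = li, lj, lk
    return PhyloTree(TreeNode(children=[nodes[i], nodes[j], nodes[k]]))


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def bootstrap_support(
    fam: AlignedFamily, replicates: int = 2000, seed: int = 0
) -> PhyloTree:
    """NJ tree with column-bootstrap supports on every internal edge.

    Alignment columns are resampled with replacement ``replicates`` times; the
    support of an original bipartition is the fraction of replicate trees
    containing it. Fully seeded and reproducible.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    tree = nj_tree(p_distance_matrix(fam), list(fam.ids))
    orig_splits = tree.splits()
    counts = {s: 0 for s in orig_splits}
    arr = fam.encoded()
    n, width = arr.shape
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(0, width, size=width)
        sub = arr[:, cols]
        try:
            dmat = _p_distance_from_codes(sub)
        except ValidationError:
            continue  # replicate uninformative for some pair; supports nothing
        rep = nj_tree(dmat, list(fam.ids))
        for s in rep.splits():
            if s in counts:
                counts[s] += 1
    tree.annotate_supports({s: c / replicates for s, c in counts.items()})
    return tree


def _p_distance_from_codes(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    dist = np.zeros((n, n))
    gapfree = arr != GAP_CODE
    for i in range(n):
        for j in range(i + 1, n):
            ok = gapfree[i] & gapfree[j]
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValidationError("pair with no comparable columns")
            dist[i, j] = dist[j, i] = (
                float(np.count_nonzero(arr[i][ok] != arr[j][ok])) / comparable
            )
    return dist
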