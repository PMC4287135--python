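"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own algorithms: alignment scores come
from exhaustive enumeration of alignment paths, substitution rates from an
explicit double loop over pairs and sites, CDF distances from direct
step-function evaluation.
"""

from __future__ import annotations

import numpy as np


def exhaustive_align_score(
    a: str, b: str, mat_lookup, gap_open: float, gap_extend: float
) -> float:
    """Best affine-gap global alignment score by enumerating every path.

    ``mat_lookup(x, y)`` returns the substitution score. A maximal gap run of
    length k costs ``gap_open + (k-1)*gap_extend``.
    """
    la, lb = len(a), len(b)
    best = [-np.inf]

    def walk(i: int, j: int, last: str, score: float) -> None:
        if i == la and j == lb:
            if score > best[0]:
                best[0] = score
            return
        if i < la and j < lb:
            walk(i + 1, j + 1, "D", score + mat_lookup(a[i], b[j]))
        if i < la:  # gap in b
            cost = gap_extend if last == "B" else gap_open
            walk(i + 1, j, "B", score - cost)
        if j < lb:  # gap in a
            cost = gap_extend if last == "A" else gap_open
            walk(i, j + 1, "A", score - cost)

    walk(0, 0, "", 0.0)
    return float(best[0])


def _symbols_match(x: str, y: str, gap_policy: str) -> bool | None:
    """Match rule; None means the comparison is excluded."""
    if gap_policy == "exclude" and ("-" in (x, y)):
        return None
    if x == "X" or y == "X":
        return False
    return x == y


def pairwise_rate_oracle(
    rows1: list[str], rows2: list[str], gap_policy: str = "mismatch"
) -> tuple[list[int], float]:
    """Double loop over ordered cross-group pairs and sites."""
    l = len(rows1[0])
    m, n = len(rows1), len(rows2)
    s = [0] * l
    for i in range(l):
        for ra in rows1:
            for rb in rows2:
                verdict = _symbols_match(ra[i], rb[i], gap_policy)
                if verdict is None:
                    continue
                if not verdict:
                    s[i] += 1
    return s, sum(s) / (m * n * l)


def any_match_rate_oracle(
    rows1: list[str], rows2: list[str], gap_policy: str = "mismatch"
) -> tuple[list[int], float]:
    """Literal reading: count group-2 rows matching no group-1 symbol."""
    l = len(rows1[0])
    n = len(rows2)
    s = [0] * l
    for i in range(l):
        for rb in rows2:
            if gap_policy == "exclude" and rb[i] == "-":
                continue
            matched = any(
                _symbols_match(ra[i], rb[i], gap_policy) for ra in rows1
            )
            if not matched:
                s[i] += 1
    return s, sum(s) / (n * l)


def cdf_distance_oracle(scores, thresholds, boundary_values) -> float:
    """Direct step-function evaluation of the CDF at each threshold."""
    diffs = []
    for t, b in zip(thresholds, boundary_values):
        frac = sum(1 for s in scores if s <= t) / len(scores)
        diffs.append(frac - b)
    return sum(diffs) / len(diffs)


def window_oracle(genes, center_symbol: str, window_bp: int) -> set[str]:
    """Midpoint filter for neighborhood windows, written independently."""
    center = next(g for g in genes if g.symbol.upper() == center_symbol.upper())
    cmid = (center.start_bp + center.end_bp) / 2
    out = set()
    for g in genes:
        if g.symbol.upper() == center_symbol.upper():
            continue
        mid = (g.start_bp + g.end_bp) / 2
        if cmid - window_bp / 2 <= mid <= cmid + window_bp / 2:
            out.add(g.symbol.upper())
    return out


def random_additive_tree(labels: list[str], rng: np.random.Generator):
    """A random binary topology with random branch lengths.

    Returns ``(distance_matrix, splits)`` where the matrix holds leaf-to-leaf
    path lengths (hence additive) and splits are the nontrivial bipartitions,
    canonicalized as the side not containing the alphabetically first label.
    """
    n = len(labels)
    anchor = min(labels)
    splits: set[frozenset] = set()
    dist = {lab: {lab: 0.0} for lab in labels}

    def build(group: list[str]) -> dict[str, float]:
        # returns depth of each leaf below this subtree root
        if len(group) == 1:
            return {group[0]: 0.0}
        k = int(rng.integers(1, len(group)))
        left, right = group[:k], group[k:]
        dl = build(left)
        dr = build(right)
        bl = float(rng.uniform(0.1, 1.0))
        br = float(rng.uniform(0.1, 1.0))
        for side in (left, right):
            if 2 <= len(side) <= n - 2:
                s = frozenset(side)
                splits.add(s if anchor not in s else frozenset(labels) - s)
        for a in left:
            for b in right:
                d = dl[a] + bl + dr[b] + br
                dist[a][b] = dist[b][a] = d
        out = {a: d + bl for a, d in dl.items()}
        out.update({b: d + br for b, d in dr.items()})
        return out

    shuffled = list(labels)
    rng.shuffle(shuffled)
    build(shuffled)
    mat = np.array([[dist[a][b] for b in labels] for a in labels])
    return mat, splits
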