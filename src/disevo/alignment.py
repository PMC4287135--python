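"""Affine-gap global alignment of sequences and profiles (Gotoh DP).

One scoring engine serves both pairwise alignment and the profile-profile
merges of the progressive MSA, so a two-sequence MSA scores identically to the
pairwise optimum. A gap run of length k costs ``gap_open + (k-1)*gap_extend``
(the classic "opening 10, extension 0.1" convention). Traceback ties are
broken deterministically: match/mismatch is preferred over a gap in the first
input, which is preferred over a gap in the second.

Substitution matrices (BLOSUM62, PAM250, ...) are taken from Biopython's
``Bio.Align.substitution_matrices`` collection and mapped onto the internal
22-symbol alphabet (20 amino acids, 'X', gap); gap columns score zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ParameterError
from .records import AA20, ProteinRecord

#: Internal alphabet: 20 residues, unknown, gap.
SYMBOLS = AA20 + "X-"
GAP_CODE = len(SYMBOLS) - 1
_SYM_INDEX = {c: i for i, c in enumerate(SYMBOLS)}

_NEG = -1e300  # effectively -inf, but arithmetic-safe
_TOL = 1e-9


@lru_cache(maxsize=None)
def load_matrix(name: str) -> np.ndarray:
    """A substitution matrix as a 22x22 array over :data:`SYMBOLS`."""
    try:
        m = substitution_matrices.load(name)
    except FileNotFoundError:
        raise ParameterError(f"unknown substitution matrix {name!r}") from None
    out = np.zeros((len(SYMBOLS), len(SYMBOLS)))
    alpha = m.alphabet
    for i, a in enumerate(SYMBOLS[:-1]):
        for j, b in enumerate(SYMBOLS[:-1]):
            if a in alpha and b in alpha:
                out[i, j] = float(m[a, b])
    return out


def encode(seq: str) -> np.ndarray:
    """Symbol codes for a (possibly gapped) sequence."""
    try:
        return np.array([_SYM_INDEX[c] for c in seq], dtype=np.int16)
    except KeyError as exc:
        raise ParameterError(f"cannot encode symbol {exc.args[0]!r}") from None


def _affine_dp(S: np.ndarray, gap_open: float, gap_extend: float) -> tuple[float, str]:
    """Maximize an affine-gap global alignment over score matrix ``S``.

    ``S[i, j]`` scores pairing row-item i with column-item j. Returns the
    optimal score and the op string over {'D' diagonal, 'B' gap in the second
    input (consume a row item), 'A' gap in the first input (consume a column
    item)}.
    """
    la, lb = S.shape
    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)  # vertical: gap in b, consumes a
    Y = np.full((la + 1, lb + 1), _NEG)  # horizontal: gap in a, consumes b
    M[0, 0] = 0.0
    if la:
        X[1:, 0] = -gap_open - gap_extend * np.arange(la)
    if lb:
        Y[0, 1:] = -gap_open - gap_extend * np.arange(lb)
    jj = np.arange(1, lb + 1)
    for i in range(1, la + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = S[i - 1, :] + prev_best[:-1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - gap_open,
            X[i - 1, 1:] - gap_extend,
        )
        X[i, 0] = -gap_open - gap_extend * (i - 1)
        # horizontal state needs an in-row scan; linearize the gap cost so the
        # recurrence becomes a running maximum
        P = np.maximum(M[i], X[i])
        cand = P[:-1] - gap_open + jj * gap_extend
        z = np.maximum.accumulate(np.concatenate(([_NEG], cand)))
        Y[i, 1:] = z[1:] - jj * gap_extend

    # traceback, deterministic priority D > A > B (match > gap-in-a > gap-in-b)
    def pick(states: list[tuple[str, float]], target: float) -> str:
        for name, val in states:
            if val >= target - _TOL:
                return name
        raise AssertionError("traceback lost the optimal path")

    i, j = la, lb
    final = max(M[i, j], Y[i, j], X[i, j])
    state = pick([("M", M[i, j]), ("Y", Y[i, j]), ("X", X[i, j])], final)
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ops.append("D")
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = pick([("M", M[i, j]), ("Y", Y[i, j]), ("X", X[i, j])], target)
        elif state == "X":
            ops.append("B")
            target = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            state = pick(
                [
                    ("M", M[i, j] - gap_open),
                    ("Y", Y[i, j] - gap_open),
                    ("X", X[i, j] - gap_extend),
                ],
                target,
            )
        else:  # Y
            ops.append("A")
            target = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            state = pick(
                [
                    ("M", M[i, j] - gap_open),
                    ("Y", Y[i, j] - gap_extend),
                    ("X", X[i, j] - gap_open),
                ],
                target,
            )
    ops.reverse()
    return float(final), "".join(ops)


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    aligned_a: str
    aligned_b: str

    @property
    def identity(self) -> float:
        """Matches over alignment length, gap columns included in the denominator."""
        n = len(self.aligned_a)
        matches = sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )
        return matches / n if n else 0.0

    @property
    def coverage(self) -> float:
        """Fraction of first-sequence residues aligned against a residue."""
        total = sum(1 for x in self.aligned_a if x != "-")
        hit = sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-"
        )
        return hit / total if total else 0.0


def global_align(
    a: str | ProteinRecord,
    b: str | ProteinRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.1,
) -> AlignmentResult:
    """Optimal affine-gap global alignment of two protein sequences."""
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise ParameterError("cannot align an empty sequence")
    mat = load_matrix(matrix)
    ea, eb = encode(sa), encode(sb)
    S = mat[np.ix_(ea, eb)]
    score, ops = _affine_dp(S, gap_open, gap_extend)
    out_a: list[str] = []
    out_b: list[str] = []
    i = j = 0
    for op in ops:
        if op == "D":
            out_a.append(sa[i])
            out_b.append(sb[j])
            i += 1
            j += 1
        elif op == "B":
            out_a.append(sa[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(sb[j])
            j += 1
    return AlignmentResult(score=score, aligned_a="".join(out_a), aligned_b="".join(out_b))


class Profile:
    """A gapped alignment block: member rows plus per-column symbol counts."""

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        if len({len(r) for r in rows}) > 1:
            raise ParameterError("profile rows must have equal length")
        self.ids = list(ids)
        self.rows = list(rows)
        width = len(rows[0]) if rows else 0
        counts = np.zeros((width, len(SYMBOLS)))
        for row in rows:
            codes = encode(row)
            counts[np.arange(width), codes] += 1.0
        self.counts = counts

    @classmethod
    def from_record(cls, record: ProteinRecord) -> "Profile":
        return cls([record.id], [record.sequence])

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def size(self) -> int:
        return len(self.rows)


def profile_align(
    pa: Profile,
    pb: Profile,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.1,
) -> tuple[float, Profile]:
    """Merge two profiles by average sum-of-pairs affine-gap alignment.

    The column-pair score is the mean substitution score over all cross-profile
    residue pairs; pre-existing gap characters contribute zero.
    """
    mat = load_matrix(matrix)
    S = (pa.counts @ mat @ pb.counts.T) / (pa.size * pb.size)
    score, ops = _affine_dp(S, gap_open, gap_extend)
    rows_a = ["" for _ in pa.rows]
    rows_b = ["" for _ in pb.rows]
    i = j = 0
    for op in ops:
        if op == "D":
            for k, row in enumerate(pa.rows):
                rows_a[k] += row[i]
            for k, row in enumerate(pb.rows):
                rows_b[k] += row[j]
            i += 1
            j += 1
        elif op == "B":
            for k, row in enumerate(pa.rows):
                rows_a[k] += row[i]
            for k in range(len(pb.rows)):
                rows_b[k] += "-"
            i += 1
        else:
            for k in range(len(pa.rows)):
                rows_a[k] += "-"
            for k, row in enumerate(pb.rows):
                rows_b[k] += row[j]
            j += 1
    return score, Profile(pa.ids + pb.ids, rows_a + rows_b)
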