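"""Gapped disorder curves: per-residue flexibility in alignment coordinates.

Scores are computed on each ungapped sequence and then placed at their
residues' alignment columns, so indel positions appear as explicit gap
segments (horizontal bars in the classic plot). Cross-protein similarity of
two curves is the Pearson correlation over columns where both have values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .disorder import DisorderProfile
from .errors import ValidationError
from .phylo import AlignedFamily


@dataclass(frozen=True)
class GappedCurve:
    """Disorder scores in alignment coordinates; NaN marks gap columns."""

    protein_id: str
    values: np.ndarray  # length = alignment width; NaN at gaps
    gap_segments: tuple[tuple[int, int], ...]  # maximal gap runs, half-open

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("non-gap curve values must lie in [0, 1]")

    def ungapped(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def project_profile(fam: AlignedFamily, profile: DisorderProfile, row_id: str) -> GappedCurve:
    """Place a per-residue profile into its row's alignment columns."""
    row = fam.row(row_id)
    n_res = sum(1 for c in row if c != "-")
    if n_res != len(profile):
        raise ValidationError(
            f"profile length {len(profile)} does not match ungapped row length {n_res}"
        )
    values = np.full(len(row), np.nan)
    k = 0
    for col, ch in enumerate(row):
        if ch != "-":
            values[col] = profile.scores[k]
            k += 1
    segments: list[tuple[int, int]] = []
    start = None
    for col, ch in enumerate(row):
        if ch == "-" and start is None:
            start = col
        elif ch != "-" and start is not None:
            segments.append((start, col))
            start = None
    if start is not None:
        segments.append((start, len(row)))
    return GappedCurve(protein_id=profile.protein_id, values=values, gap_segments=tuple(segments))


def curve_similarity(a: GappedCurve, b: GappedCurve) -> tuple[float, int]:
    """Pearson r over mutually ungapped columns, plus the column count.

    With fewer than 3 shared columns the correlation is undefined and NaN is
    returned (flagged by the caller via the count).
    """
    if len(a.values) != len(b.values):
        raise ValidationError("curves must share one alignment width")
    both = np.isfinite(a.values) & np.isfinite(b.values)
    n = int(both.sum())
    if n < 3:
        return float("nan"), n
    x, y = a.values[both], b.values[both]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), n  # constant curve: correlation undefined
    r, _ = stats.pearsonr(x, y)
    return float(r), n
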