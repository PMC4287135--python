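"""Conservation-of-genomic-neighborhood (CGN) scoring and synteny pairing.

The CGN score of species X against the reference (human) neighborhood is

    CGN_X = C_X / M_HS

where M_HS is the number of genes in a fixed window around the reference gene
in the human genome and C_X the number of those genes also present in the
window around the ortholog in species X. A score above 0.5 means more than
half of the local gene neighbors are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .errors import ParameterError, ValidationError


class Gene(NamedTuple):
    symbol: str
    start_bp: int
    end_bp: int

    @property
    def midpoint(self) -> float:
        return (self.start_bp + self.end_bp) / 2.0


@dataclass(frozen=True)
class GeneNeighborhood:
    """Genes of one species on one chromosome, with bp spans."""

    species: str
    chromosome: str
    genes: Sequence[Gene]

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.start_bp < 0 or g.end_bp < 0:
                raise ValidationError(f"gene {g.symbol!r}: negative coordinate")
            if g.start_bp > g.end_bp:
                raise ValidationError(f"gene {g.symbol!r}: start_bp > end_bp")


@dataclass(frozen=True)
class CgnResult:
    species_x: str
    m_hs: int
    c_x: int
    score: float


def window_genes(
    nb: GeneNeighborhood, center_gene: str, window_bp: int = 2_000_000
) -> list[str]:
    """Symbols of genes whose midpoint lies within ``window_bp/2`` of the center.

    ``window_bp`` is the total span of the window (default 2 Mb, i.e. ±1 Mb);
    the interval is closed, so a gene exactly at the edge is included. The
    center gene itself is excluded. Symbols return uppercased, in positional
    order.
    """
    center_gene = center_gene.upper()
    centers = [g for g in nb.genes if g.symbol.upper() == center_gene]
    if not centers:
        raise ValidationError(
            f"center gene {center_gene!r} not found in {nb.species}/{nb.chromosome}"
        )
    cmid = centers[0].midpoint
    half = window_bp / 2.0
    hits = [
        g
        for g in nb.genes
        if abs(g.midpoint - cmid) <= half and g.symbol.upper() != center_gene
    ]
    hits.sort(key=lambda g: g.midpoint)
    return [g.symbol.upper() for g in hits]


def cgn_score(human_window: Sequence[str], other_window: Sequence[str], species_x: str = "") -> CgnResult:
    """Fraction of the human window's genes present in the other window."""
    human = {s.upper() for s in human_window}
    if not human:
        raise ParameterError("human window is empty; CGN score undefined")
    other = {s.upper() for s in other_window}
    common = human & other
    return CgnResult(
        species_x=species_x,
        m_hs=len(human),
        c_x=len(common),
        score=len(common) / len(human),
    )


def synteny_pairs(
    human_window: Sequence[tuple[str, float]],
    other_window: Sequence[tuple[str, float]],
) -> list[tuple[str, float, float]]:
    """Matched (symbol, human_position, other_position) triples for ribbon plots.

    One pair per shared symbol (first occurrence on each side), ordered by the
    human position; matching is case-insensitive.
    """
    other_pos: dict[str, float] = {}
    for sym, pos in other_window:
        other_pos.setdefault(sym.upper(), pos)
    seen: set[str] = set()
    pairs: list[tuple[str, float, float]] = []
    for sym, pos in sorted(human_window, key=lambda t: t[1]):
        key = sym.upper()
        if key in seen or key not in other_pos:
            continue
        seen.add(key)
        pairs.append((key, pos, other_pos[key]))
    return pairs
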