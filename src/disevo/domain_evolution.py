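"""Per-domain, group-vs-group substitution-rate statistics.

Domain boundaries annotated on one reference sequence are projected through
the multiple alignment onto every other row; within the projected column
interval, per-site substitution counts S_i are accumulated between two species
groups and normalized to the rate

    rate = sum_i S_i / (M * N * L)

with M and N the group sizes and L the number of alignment columns in the
region. In the default ``pairwise`` mode S_i counts the ordered cross-group
pairs whose symbols differ at column i (so the rate is a true [0, 1]
mismatch fraction and symmetric in the two groups); the literal ``any-match``
mode counts second-group sequences whose symbol matches no first-group symbol
at that column and normalizes by N*L. 'X' counts as a mismatch against every
symbol including 'X'; under the default ``mismatch`` gap policy a gap differs
from every residue and matches another gap, while ``exclude`` drops
gap-containing comparisons from the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import GAP_CODE, SYMBOLS
from .errors import ParameterError, ValidationError
from .phylo import AlignedFamily
from .records import DomainAnnotation

_X_CODE = SYMBOLS.index("X")


@dataclass(frozen=True)
class RegionProjection:
    """A reference domain mapped to a half-open alignment-column interval."""

    domain_name: str
    reference_id: str
    col_start: int  # 0-based, inclusive
    col_end: int  # 0-based, exclusive

    def __post_init__(self) -> None:
        if not (0 <= self.col_start < self.col_end):
            raise ValidationError(
                f"projection {self.domain_name!r}: empty or invalid column interval"
            )

    @property
    def n_columns(self) -> int:
        return self.col_end - self.col_start


@dataclass(frozen=True)
class SubstitutionRateResult:
    domain_name: str
    group1: str
    group2: str
    m: int
    n: int
    l: int
    per_site_counts: tuple[int, ...]
    rate: float
    mode: str = "pairwise"
    gap_policy: str = "mismatch"

    @property
    def sum_s(self) -> int:
        return int(sum(self.per_site_counts))


def project_domains(
    fam: AlignedFamily,
    reference_id: str,
    domains: Sequence[DomainAnnotation],
) -> list[RegionProjection]:
    """Map reference-domain residue intervals to minimal column intervals."""
    if reference_id not in fam.ids:
        raise ValidationError(f"reference {reference_id!r} not in alignment")
    colmap = fam.column_map(reference_id)
    ref_len = len(fam.ungapped(reference_id))
    residue_col = {res: col for col, res in enumerate(colmap) if res is not None}
    out: list[RegionProjection] = []
    for dom in domains:
        start, end = dom.interval
        if end > ref_len:
            raise ValidationError(
                f"domain {dom.domain_name!r} ({dom.start}-{dom.end}) exceeds reference "
                f"length {ref_len}"
            )
        cols = [residue_col[r] for r in range(start, end)]
        if not cols:
            raise ValidationError(f"domain {dom.domain_name!r} maps to zero columns")
        out.append(
            RegionProjection(
                domain_name=dom.domain_name,
                reference_id=reference_id,
                col_start=min(cols),
                col_end=max(cols) + 1,
            )
        )
    return out


def whole_alignment_region(fam: AlignedFamily, name: str = "whole") -> RegionProjection:
    """The full alignment as one region (used when no domain table is given)."""
    return RegionProjection(domain_name=name, reference_id="", col_start=0, col_end=fam.width)


def substitution_rate(
    fam: AlignedFamily,
    region: RegionProjection,
    group1: Sequence[str],
    group2: Sequence[str],
    mode: str = "pairwise",
    gap_policy: str = "mismatch",
    group1_label: str = "",
    group2_label: str = "",
) -> SubstitutionRateResult:
    """The normalized substitution rate of one region between two groups."""
    if mode not in ("pairwise", "any-match"):
        raise ParameterError(f"unknown mode {mode!r}")
    if gap_policy not in ("mismatch", "exclude"):
        raise ParameterError(f"unknown gap_policy {gap_policy!r}")
    if not group1 or not group2:
        raise ParameterError("both groups must be non-empty")
    if set(group1) & set(group2):
        raise ValidationError("groups must be disjoint")
    if region.col_end > fam.width:
        raise ValidationError("region exceeds alignment width")

    arr = fam.encoded()[:, region.col_start : region.col_end]
    idx = {rid: k for k, rid in enumerate(fam.ids)}
    try:
        g1 = arr[[idx[r] for r in group1]]
        g2 = arr[[idx[r] for r in group2]]
    except KeyError as exc:
        raise ValidationError(f"group member {exc.args[0]!r} not in alignment") from None

    m, n, l = g1.shape[0], g2.shape[0], region.n_columns
    n_sym = len(SYMBOLS)
    c1 = _column_counts(g1, n_sym)
    c2 = _column_counts(g2, n_sym)

    if mode == "pairwise":
        # matching pairs per column: equal symbols, except 'X' never matches;
        # gap-gap is a match under the 'mismatch' policy
        match_sym = np.ones(n_sym, dtype=bool)
        match_sym[_X_CODE] = False
        if gap_policy == "exclude":
            match_sym[GAP_CODE] = False
        matches = (c1[:, match_sym] * c2[:, match_sym]).sum(axis=1)
        total = m * n
        if gap_policy == "exclude":
            # drop residue-vs-gap comparisons from the counts too
            gap_pairs = (
                c1[:, GAP_CODE] * n + c2[:, GAP_CODE] * m - c1[:, GAP_CODE] * c2[:, GAP_CODE]
            )
            s = total - gap_pairs - matches
        else:
            s = total - matches
        denom = m * n * l
    else:
        present1 = c1 > 0
        present1[:, _X_CODE] = False
        if gap_policy == "exclude":
            present1[:, GAP_CODE] = False
        s = np.zeros(l)
        for col in range(l):
            unmatched = 0
            for b in range(n):
                sym = g2[b, col]
                if gap_policy == "exclude" and sym == GAP_CODE:
                    continue
                if sym == _X_CODE or not present1[col, sym]:
                    unmatched += 1
            s[col] = unmatched
        denom = n * l

    counts = tuple(int(v) for v in s)
    return SubstitutionRateResult(
        domain_name=region.domain_name,
        group1=group1_label,
        group2=group2_label,
        m=m,
        n=n,
        l=l,
        per_site_counts=counts,
        rate=float(sum(counts)) / denom,
        mode=mode,
        gap_policy=gap_policy,
    )


def _column_counts(g: np.ndarray, n_sym: int) -> np.ndarray:
    """(n_columns, n_symbols) occurrence counts for a group's sub-alignment."""
    l = g.shape[1]
    counts = np.zeros((l, n_sym), dtype=np.int64)
    for row in g:
        np.add.at(counts, (np.arange(l), row), 1)
    return counts


def rate_profile(
    fam: AlignedFamily,
    projections: Sequence[RegionProjection],
    groups: Mapping[str, str],
    group_pairs: Sequence[tuple[str, str]],
    mode: str = "pairwise",
    gap_policy: str = "mismatch",
) -> pd.DataFrame:
    """Domain x group-pair table of substitution rates (tidy long format).

    ``groups`` maps alignment row id -> group label. A pair with an empty
    group yields a flagged row (NaN rate), never a silent zero.
    """
    members: dict[str, list[str]] = {}
    for rid in fam.ids:
        if rid in groups:
            members.setdefault(groups[rid], []).append(rid)
    rows = []
    for proj in projections:
        for g1, g2 in group_pairs:
            ids1, ids2 = members.get(g1, []), members.get(g2, [])
            if not ids1 or not ids2:
                rows.append(
                    {
                        "domain": proj.domain_name,
                        "group1": g1,
                        "group2": g2,
                        "M": len(ids1),
                        "N": len(ids2),
                        "L": proj.n_columns,
                        "sum_S": np.nan,
                        "rate": np.nan,
                        "mode": mode,
                        "gap_policy": gap_policy,
                        "missing": True,
                    }
                )
                continue
            res = substitution_rate(
                fam,
                proj,
                ids1,
                ids2,
                mode=mode,
                gap_policy=gap_policy,
                group1_label=g1,
                group2_label=g2,
            )
            rows.append(
                {
                    "domain": proj.domain_name,
                    "group1": g1,
                    "group2": g2,
                    "M": res.m,
                    "N": res.n,
                    "L": res.l,
                    "sum_S": res.sum_s,
                    "rate": res.rate,
                    "mode": mode,
                    "gap_policy": gap_policy,
                    "missing": False,
                }
            )
    return pd.DataFrame(rows)
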