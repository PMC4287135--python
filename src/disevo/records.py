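"""Core typed records shared by every pipeline stage.

Coordinate convention: everything on disk is 1-based inclusive (the style of
domain tables such as "aa1-264"); everything internal is 0-based half-open.
:class:`DomainAnnotation` stores the on-disk numbers and exposes the internal
interval via :attr:`DomainAnnotation.interval`, so the two conversions compose
to the identity at the module boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError

#: The 20 standard amino acids, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in input sequences ('X' = unknown).
VALID_RESIDUES = frozenset(AA20) | {"X"}

#: Default ordered group labels, from the reference species outward.
DEFAULT_GROUP_ORDER = (
    "human",
    "primates",
    "Therapsida",
    "mammals",
    "amphibians",
    "fish",
    "insects",
    "nematodes",
)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, species, group label and residue string."""

    id: str
    sequence: str
    species: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record must have a non-empty id")
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_RESIDUES:
                raise ValidationError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """A named region on a reference sequence, 1-based inclusive on disk."""

    reference_id: str
    domain_name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"domain {self.domain_name!r}: invalid range {self.start}-{self.end}"
            )

    @property
    def interval(self) -> tuple[int, int]:
        """The region as a 0-based half-open ``(start, end)`` interval."""
        return self.start - 1, self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


def check_domains_disjoint(domains: Iterable[DomainAnnotation]) -> None:
    """Raise :class:`ValidationError` if two domains on one reference overlap."""
    by_ref: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        by_ref.setdefault(d.reference_id, []).append(d)
    for ref, ds in by_ref.items():
        ds = sorted(ds, key=lambda d: d.start)
        for a, b in zip(ds, ds[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"domains {a.domain_name!r} ({a.start}-{a.end}) and "
                    f"{b.domain_name!r} ({b.start}-{b.end}) overlap on {ref!r}"
                )


@dataclass(frozen=True)
class SpeciesGrouping:
    """Total mapping species -> ordered group label.

    ``order`` fixes the sequence of groups along the evolutionary axis
    (reference species first); every mapped group must appear in it.
    """

    mapping: Mapping[str, str]
    order: Sequence[str] = field(default=DEFAULT_GROUP_ORDER)

    def __post_init__(self) -> None:
        known = set(self.order)
        for sp, grp in self.mapping.items():
            if grp not in known:
                raise ValidationError(
                    f"species {sp!r} mapped to unknown group {grp!r}"
                )

    def group_of(self, species: str) -> str:
        try:
            return self.mapping[species]
        except KeyError:
            raise ValidationError(f"species {species!r} has no group") from None

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        """Consecutive group pairs in configured order, e.g. (human, primates)."""
        return list(zip(self.order, self.order[1:]))

    def assign(self, records: Iterable[ProteinRecord]) -> list[ProteinRecord]:
        """Return copies of ``records`` with ``group`` filled from the mapping."""
        return [
            ProteinRecord(r.id, r.sequence, r.species, self.group_of(r.species))
            for r in records
        ]
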