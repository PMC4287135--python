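"""Reading and writing of the pipeline's external formats.

FASTA headers follow a small dialect: ``>id|species`` or plain ``>id`` (the
split is on the first ``|``; everything after it is the species verbatim).
Domain, species and gene-neighborhood tables are plain TSV with headers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .genomic_neighborhood import Gene, GeneNeighborhood
from .records import (
    DomainAnnotation,
    ProteinRecord,
    SpeciesGrouping,
    check_domains_disjoint,
)

logger = logging.getLogger(__name__)


def _split_header(header: str) -> tuple[str, str]:
    if "|" in header:
        rec_id, species = header.split("|", 1)
        return rec_id.strip(), species.strip()
    return header.strip(), ""


def read_fasta(path: str | Path, species: dict[str, str] | None = None) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Residues are uppercased and a single terminal ``'*'`` stop is stripped.
    ``species`` optionally supplies species names (by record id) for headers
    without a ``|`` field.
    """
    path = Path(path)
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise FormatError(f"{path}: no FASTA entries found")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in entries:
        rec_id, sp = _split_header(entry.description)
        if not sp and species:
            sp = species.get(rec_id, "")
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if rec_id in seen:
            raise ValidationError(f"{path}: duplicate record id {rec_id!r}")
        seen.add(rec_id)
        records.append(ProteinRecord(id=rec_id, sequence=seq, species=sp))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records using the ``id|species`` header dialect (order preserved)."""
    entries = []
    for r in records:
        header = f"{r.id}|{r.species}" if r.species else r.id
        entries.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    SeqIO.write(entries, str(Path(path)), "fasta-2line")


def read_aligned_fasta(path: str | Path):
    """Read a gapped FASTA into an :class:`~disevo.phylo.AlignedFamily`."""
    from .phylo import AlignedFamily

    path = Path(path)
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise FormatError(f"{path}: no FASTA entries found")
    ids = tuple(_split_header(e.description)[0] for e in entries)
    rows = tuple(str(e.seq).upper() for e in entries)
    return AlignedFamily(ids, rows)


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a TSV of 1-based inclusive domain annotations, sorted by start.

    Columns: ``reference_id``, ``domain_name``, ``start``, ``end``. Overlapping
    domains on one reference are rejected. An empty table yields an empty list
    (downstream stages then default to whole-sequence regions).
    """
    df = _read_tsv(path, ["reference_id", "domain_name", "start", "end"])
    domains = [
        DomainAnnotation(
            reference_id=str(row.reference_id),
            domain_name=str(row.domain_name),
            start=int(row.start),
            end=int(row.end),
        )
        for row in df.itertuples(index=False)
    ]
    check_domains_disjoint(domains)
    return sorted(domains, key=lambda d: (d.reference_id, d.start))


def read_species_table(path: str | Path, order: Sequence[str] | None = None) -> SpeciesGrouping:
    """Read a TSV mapping ``species`` -> ``group`` into a :class:`SpeciesGrouping`."""
    df = _read_tsv(path, ["species", "group"])
    mapping = {str(r.species): str(r.group) for r in df.itertuples(index=False)}
    if order is not None:
        return SpeciesGrouping(mapping, tuple(order))
    return SpeciesGrouping(mapping)


def read_neighborhood_table(path: str | Path) -> list[GeneNeighborhood]:
    """Read a gene-neighborhood TSV into one neighborhood per (species, chromosome).

    Columns: ``species``, ``chromosome``, ``gene_symbol``, ``start_bp``,
    ``end_bp``. Symbols are uppercased for cross-species matching; a duplicate
    symbol on one chromosome keeps the first occurrence with a warning.
    """
    df = _read_tsv(path, ["species", "chromosome", "gene_symbol", "start_bp", "end_bp"])
    out: list[GeneNeighborhood] = []
    for (sp, chrom), sub in df.groupby(["species", "chromosome"], sort=True):
        genes: list[Gene] = []
        seen: set[str] = set()
        for row in sub.itertuples(index=False):
            start, end = int(row.start_bp), int(row.end_bp)
            sym = str(row.gene_symbol).upper()
            if start < 0 or end < 0:
                raise ValidationError(
                    f"{path}: gene {sym!r} has negative coordinate"
                )
            if start > end:
                raise ValidationError(
                    f"{path}: gene {sym!r} has start_bp > end_bp ({start} > {end})"
                )
            if sym in seen:
                logger.warning(
                    "%s: duplicate symbol %s on %s/%s; keeping first", path, sym, sp, chrom
                )
                continue
            seen.add(sym)
            genes.append(Gene(symbol=sym, start_bp=start, end_bp=end))
        out.append(GeneNeighborhood(species=str(sp), chromosome=str(chrom), genes=genes))
    return out


def write_neighborhood_table(neighborhoods: Iterable[GeneNeighborhood], path: str | Path) -> None:
    rows = [
        {
            "species": nb.species,
            "chromosome": nb.chromosome,
            "gene_symbol": g.symbol,
            "start_bp": g.start_bp,
            "end_bp": g.end_bp,
        }
        for nb in neighborhoods
        for g in nb.genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df
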