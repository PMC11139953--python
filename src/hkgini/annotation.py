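"""Gene annotation: GFF3 gene features, biotypes, pseudoautosomal duplicates.

GENCODE places a second copy of each pseudoautosomal (PAR) gene on chrY;
expression references built on GENCODE therefore carry duplicate gene
records whose IDs end in ``_PAR_Y``.  The pipeline keeps the chrX copy and
drops the chrY twin before any scoring.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, replace
from typing import Iterable, TextIO

__all__ = [
    "GeneRecord",
    "GeneCatalog",
    "parse_annotation",
    "deduplicate_par",
    "split_by_biotype",
]

PAR_Y_SUFFIX = "_PAR_Y"
_Y_NAMES = frozenset({"chrY", "Y"})
_X_NAMES = frozenset({"chrX", "X"})


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    biotype: str
    chromosome: str
    par_y_flag: bool = False

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


class GeneCatalog:
    """Ordered collection of gene records, unique by gene_id."""

    def __init__(self, records: Iterable[GeneRecord]):
        self._records: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.gene_id in self._records:
                raise ValueError(f"duplicate gene_id in catalog: {rec.gene_id}")
            self._records[rec.gene_id] = rec

    @property
    def gene_ids(self) -> list[str]:
        return list(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._records[gene_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneCatalog) and self._records == other._records

    # -- serialization -------------------------------------------------

    _TSV_COLUMNS = ("gene_id", "symbol", "biotype", "chromosome", "par_y_flag")

    def to_tsv(self, path_or_stream) -> None:
        close, fh = _open_text(path_or_stream, "w")
        try:
            fh.write("\t".join(self._TSV_COLUMNS) + "\n")
            for rec in self:
                fh.write(
                    f"{rec.gene_id}\t{rec.symbol}\t{rec.biotype}\t"
                    f"{rec.chromosome}\t{int(rec.par_y_flag)}\n"
                )
        finally:
            if close:
                fh.close()

    @classmethod
    def from_tsv(cls, path_or_stream) -> "GeneCatalog":
        close, fh = _open_text(path_or_stream, "r")
        try:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != cls._TSV_COLUMNS:
                raise ValueError(f"unexpected catalog header: {header}")
            records = []
            for line in fh:
                gid, sym, bio, chrom, flag = line.rstrip("\n").split("\t")
                records.append(GeneRecord(gid, sym, bio, chrom, bool(int(flag))))
        finally:
            if close:
                fh.close()
        return cls(records)


def _open_text(source, mode: str) -> tuple[bool, TextIO]:
    """Open a path (gzip-transparent) or pass a stream through."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return False, source
    path = str(source)
    if path.endswith(".gz"):
        return True, io.TextIOWrapper(gzip.open(path, mode + "b"))
    return True, open(path, mode)


def _parse_attributes(field: str, line_no: int) -> dict[str, str]:
    attrs = {}
    for chunk in field.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(
                f"malformed GFF3 attribute {chunk!r} on line {line_no}"
            )
        key, _, value = chunk.partition("=")
        attrs[key] = value
    return attrs


def parse_annotation(source) -> GeneCatalog:
    """Parse gene features from a GFF3 stream or path into a catalog.

    Only lines whose feature type is ``gene`` are read; each must carry
    ``gene_id``, ``gene_type`` and ``gene_name`` attributes.  The biotype
    is the verbatim ``gene_type`` string.  PAR-Y records are flagged
    either by the ``_PAR_Y`` gene-id suffix (GENCODE convention) or, for
    generic GFF3, by lying on chrY while an identically named record lies
    on chrX.
    """
    close, fh = _open_text(source, "r")
    records: list[GeneRecord] = []
    try:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"malformed GFF3 line {line_no}: expected 9 fields, "
                    f"got {len(fields)}"
                )
            if fields[2] != "gene":
                continue
            attrs = _parse_attributes(fields[8], line_no)
            for needed in ("gene_id", "gene_type", "gene_name"):
                if needed not in attrs:
                    raise ValueError(
                        f"line {line_no}: gene feature missing mandatory "
                        f"attribute {needed!r}"
                    )
            records.append(
                GeneRecord(
                    gene_id=attrs["gene_id"],
                    symbol=attrs["gene_name"],
                    biotype=attrs["gene_type"],
                    chromosome=fields[0],
                    par_y_flag=attrs["gene_id"].endswith(PAR_Y_SUFFIX),
                )
            )
    finally:
        if close:
            fh.close()

    # generic-GFF3 fallback: chrY record whose named twin sits on chrX
    x_symbols = {r.symbol for r in records if r.chromosome in _X_NAMES}
    flagged = [
        replace(r, par_y_flag=True)
        if (not r.par_y_flag and r.chromosome in _Y_NAMES and r.symbol in x_symbols)
        else r
        for r in records
    ]
    return GeneCatalog(flagged)


def deduplicate_par(catalog: GeneCatalog) -> tuple[GeneCatalog, int]:
    """Drop PAR-Y-flagged records, keeping the X-located twins.

    Returns the deduplicated catalog and the number of records removed.
    Idempotent; preserves gene order.
    """
    kept = [rec for rec in catalog if not rec.par_y_flag]
    return GeneCatalog(kept), len(catalog) - len(kept)


def split_by_biotype(catalog: GeneCatalog) -> tuple[list[str], list[str]]:
    """Partition gene ids into (protein_coding, non_coding), in catalog order.

    Membership is decided solely by biotype string equality with
    ``"protein_coding"``; every other biotype counts as non-coding.
    """
    coding = [r.gene_id for r in catalog if r.biotype == "protein_coding"]
    noncoding = [r.gene_id for r in catalog if r.biotype != "protein_coding"]
    return coding, noncoding
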