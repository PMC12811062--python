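"""Reading and writing the pipeline's plain-text formats.

Gene annotation comes in as GFF3 (1-based, inclusive coordinates — the
convention used throughout the package), insertion sites and count tables as
tab-delimited text with a header row. Counts are genes x samples; in the
simulator's noise-free mode they may be non-negative reals rather than
integers, and both round-trip through the same TSV functions.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


class ParseError(ValueError):
    """A text input could not be parsed (names the offending line)."""


class ValidationError(ValueError):
    """Parsed input violates a structural invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: locus tag, replicon, 1-based inclusive span."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SiteCount:
    """Reads mapped to one insertion position."""

    seq_id: str
    position: int
    count: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"site position must be >= 1, got {self.position}")
        if self.count < 0:
            raise ValidationError(f"site count must be >= 0, got {self.count}")
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(f"bad strand {self.strand!r}")


@dataclass
class CountTable:
    """Genes x samples read counts with ordered, unique identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_id in count table")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_id in count table")
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("negative count in count table")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            counts=frame.to_numpy(),
        )


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLUMNS = 9


def _parse_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(
    stream: IO[str] | str | os.PathLike,
    feature_types: Sequence[str] = ("gene",),
) -> list[GeneRecord]:
    """Parse GFF3 into GeneRecords for the selected feature types.

    The gene identifier is taken from ``locus_tag`` when present, else ``ID``.
    Coordinates are kept 1-based inclusive as in the file. Malformed lines
    raise :class:`ParseError` naming the line number; a repeated gene_id
    raises :class:`ValidationError`.
    """
    close = False
    if isinstance(stream, (str, os.PathLike)):
        stream = open(stream, "rt", encoding="utf-8")
        close = True
    wanted = set(feature_types)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF_COLUMNS:
                raise ParseError(
                    f"line {lineno}: expected {_GFF_COLUMNS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in wanted:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: strand must be + or -")
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("locus_tag") or attributes.get("ID")
            if not gene_id:
                raise ParseError(f"line {lineno}: feature has no locus_tag or ID")
            if gene_id in seen:
                raise ValidationError(f"duplicate gene_id {gene_id!r} (line {lineno})")
            seen.add(gene_id)
            try:
                records.append(
                    GeneRecord(
                        gene_id=gene_id,
                        seq_id=seq_id,
                        start=start,
                        end=end,
                        strand=strand,
                        name=attributes.get("Name") or attributes.get("gene"),
                    )
                )
            except ValidationError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            stream.close()
    return records


# ---------------------------------------------------------------------------
# Site -> gene aggregation

def trimmed_interval(gene: GeneRecord, edge_trim: float) -> tuple[int, int]:
    """The gene span after removing ``edge_trim`` of its length from each end.

    Rounding is toward the interior (ceil of the trimmed amount), so the
    retained interval never reaches into the trimmed fraction.
    """
    cut = math.ceil(edge_trim * gene.length)
    return gene.start + cut, gene.end - cut


def aggregate_sites(
    sites: Iterable[SiteCount],
    genes: Sequence[GeneRecord],
    edge_trim: float = 0.0,
    sample_id: str = "sample",
    multi_gene: str = "all",
) -> tuple[CountTable, int]:
    """Sum insertion-site reads into per-gene counts.

    A site belongs to every gene whose trimmed interval (on the same replicon)
    contains its position; with ``multi_gene="first"`` only the first gene in
    annotation order receives it. Strand is ignored: a transposon insertion
    disrupts the gene regardless of orientation. Returns a one-sample
    CountTable plus the total reads falling in no gene (intergenic).
    """
    if not 0.0 <= edge_trim < 0.5:
        raise ValidationError(f"edge_trim must be in [0, 0.5), got {edge_trim}")
    if multi_gene not in ("all", "first"):
        raise ValidationError("multi_gene must be 'all' or 'first'")

    trees: dict[str, IntervalTree] = {}
    order = {g.gene_id: i for i, g in enumerate(genes)}
    for gene in genes:
        lo, hi = trimmed_interval(gene, edge_trim)
        if lo > hi:  # trim consumed the whole gene
            continue
        # interval tree is half-open; genes are 1-based inclusive
        trees.setdefault(gene.seq_id, IntervalTree()).addi(lo, hi + 1, gene.gene_id)

    totals = dict.fromkeys(order, 0)
    intergenic = 0
    for site in sites:
        tree = trees.get(site.seq_id)
        hits = sorted((iv.data for iv in tree[site.position]), key=order.__getitem__) if tree else []
        if not hits:
            intergenic += site.count
            continue
        if multi_gene == "first":
            hits = hits[:1]
        for gene_id in hits:
            totals[gene_id] += site.count

    table = CountTable(
        gene_ids=[g.gene_id for g in genes],
        sample_ids=[sample_id],
        counts=np.array([[totals[g.gene_id]] for g in genes]),
    )
    return table, intergenic


# ---------------------------------------------------------------------------
# Count-table TSV

def read_count_table(stream: IO[str] | str | os.PathLike) -> CountTable:
    """Read a TSV count table (first column gene_id, one column per sample)."""
    try:
        frame = pd.read_csv(stream, sep="\t", index_col="gene_id", dtype={"gene_id": str})
    except (pd.errors.ParserError, ValueError, KeyError) as exc:
        raise ParseError(f"malformed count table: {exc}") from exc
    if frame.index.name != "gene_id":
        raise ParseError("count table must have a 'gene_id' first column")
    values = frame.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise ParseError("non-numeric count cell in count table")
    if values.size and np.isnan(values.astype(float)).any():
        raise ParseError("missing value in count table (ragged row?)")
    # store integers as integers so round-trips are exact
    if values.size and np.issubdtype(values.dtype, np.floating):
        if np.array_equal(values, np.round(values)):
            values = values.astype(np.int64)
    try:
        return CountTable.from_frame(pd.DataFrame(values, index=frame.index, columns=frame.columns))
    except ValidationError:
        raise


def write_count_table(table: CountTable, stream: IO[str] | str | os.PathLike) -> None:
    """Write a count table as TSV; inverse of :func:`read_count_table`."""
    frame = table.to_frame()
    frame.to_csv(stream, sep="\t", lineterminator="\n")


def read_site_table(stream: IO[str] | str | os.PathLike) -> list[SiteCount]:
    """Read insertion sites from TSV (seq_id, position, strand, count)."""
    try:
        frame = pd.read_csv(stream, sep="\t", dtype={"seq_id": str, "strand": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"malformed site table: {exc}") from exc
    needed = {"seq_id", "position", "count"}
    if not needed.issubset(frame.columns):
        raise ParseError(f"site table must have columns {sorted(needed)}")
    strands = frame["strand"] if "strand" in frame.columns else ["unknown"] * len(frame)
    return [
        SiteCount(seq_id=row.seq_id, position=int(row.position),
                  count=int(row.count), strand=str(strand))
        for row, strand in zip(frame.itertuples(), strands)
    ]
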