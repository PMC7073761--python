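"""Readers and writers for the formats the pipeline touches.

Coordinate convention
---------------------
All genomic intervals in this package are **1-based with an inclusive
end**, the convention used by genome browsers and by RepeatMasker
``.out`` files.  The length of an interval is therefore
``end - start + 1``.  This is enforced here, in one place
(:class:`GenomicInterval` / :func:`interval_length`); every other module
builds on these types.

Supported formats: aligned (gapped) FASTA, Newick trees (via dendropy),
RepeatMasker ``.out`` annotation, and plain TSV tables handled by pandas
elsewhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "Alignment",
    "GenomicInterval",
    "RepeatHit",
    "RepeatTrack",
    "parse_fasta_alignment",
    "write_fasta_alignment",
    "interval_length",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "read_newick",
    "write_newick",
    "sanitize_label",
]

VALID_BASES = frozenset("ACGTN-")

# Newick metacharacters that cannot appear in a leaf label even after
# whitespace sanitation.
_NEWICK_META = re.compile(r"[():;,\[\]']")


class SeqIOError(ValueError):
    """Malformed input file (FASTA / Newick / RepeatMasker)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named, possibly gapped DNA sequence over ``{A,C,G,T,N,-}``."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record has an empty id")
        if not self.seq:
            raise SeqIOError(f"sequence {self.id!r} is empty")
        bad = set(self.seq.upper()) - VALID_BASES
        if bad:
            raise SeqIOError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Alignment:
    """An ordered multiple sequence alignment; all rows equal length."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise SeqIOError("alignment has no records")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqIOError(f"duplicate sequence ids in alignment: {dup}")
        ref = len(self.records[0])
        for rec in self.records[1:]:
            if len(rec) != ref:
                raise SeqIOError(
                    f"alignment is ragged: {rec.id!r} has length {len(rec)}, "
                    f"expected {ref}"
                )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: int | str) -> SequenceRecord:
        if isinstance(key, str):
            for rec in self.records:
                if rec.id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based, inclusive-end interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end {self.end} precedes start {self.start}"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval: ``end - start + 1``."""
    return iv.end - iv.start + 1


@dataclass(frozen=True)
class RepeatHit:
    """One RepeatMasker hit on a gene locus (locus-relative coordinates)."""

    query: str
    interval: GenomicInterval
    strand: str  # "+" or "C" (RepeatMasker's reverse-strand code)
    repeat_name: str
    repeat_class: str
    score: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "C"):
            raise ValueError(f"strand must be '+' or 'C', got {self.strand!r}")
        if not self.repeat_name:
            raise ValueError("repeat_name must be non-empty")


@dataclass
class RepeatTrack:
    """All repeat hits on one gene locus, sorted by start coordinate."""

    gene_id: str
    hits: list[RepeatHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        for h in self.hits:
            if h.query != self.gene_id:
                raise ValueError(
                    f"hit query {h.query!r} does not match track gene "
                    f"{self.gene_id!r}"
                )
        self.hits = sorted(self.hits, key=lambda h: (h.interval.start, h.interval.end))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned multi-FASTA file into an :class:`Alignment`.

    Raises :class:`SeqIOError` on an empty file, duplicate ids, or rows
    of unequal length (the offending id is named).
    """
    records = [
        SequenceRecord(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SeqIOError(f"no records in FASTA file {path}")
    return Alignment(records=tuple(records))


def write_fasta_alignment(aln: Alignment, path: str | Path, width: int = 60) -> None:
    """Write an alignment as FASTA, wrapping sequence lines at *width*."""
    with open(path, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER_LINES = 3


def parse_repeatmasker_out(path: str | Path) -> list[RepeatTrack]:
    """Parse a RepeatMasker ``.out`` file into per-query repeat tracks.

    The standard layout is three header lines followed by
    whitespace-separated rows whose first 11 columns are::

        score  div  del  ins  query  qbegin  qend  qleft  strand  name  class

    One :class:`RepeatTrack` is returned per distinct query, hits sorted
    by start; the reverse-strand code ``C`` is preserved verbatim.
    """
    tracks: dict[str, list[RepeatHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if lineno <= _RM_HEADER_LINES and not stripped[0].isdigit():
                continue  # banner/header lines
            fields = stripped.split()
            if len(fields) < 11:
                raise SeqIOError(
                    f"{path}:{lineno}: expected >= 11 whitespace-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                score = float(fields[0])
                query = fields[4]
                qbegin = int(fields[5])
                qend = int(fields[6])
                strand = fields[8]
                name = fields[9]
                rclass = fields[10]
            except ValueError as exc:
                raise SeqIOError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if strand not in ("+", "C"):
                raise SeqIOError(
                    f"{path}:{lineno}: strand must be '+' or 'C', got {strand!r}"
                )
            hit = RepeatHit(
                query=query,
                interval=GenomicInterval(chrom=query, start=qbegin, end=qend),
                strand=strand,
                repeat_name=name,
                repeat_class=rclass,
                score=score,
            )
            tracks.setdefault(query, []).append(hit)
    return [RepeatTrack(gene_id=q, hits=hits) for q, hits in tracks.items()]


def write_repeatmasker_out(tracks: Iterable[RepeatTrack], path: str | Path) -> None:
    """Write repeat tracks in RepeatMasker ``.out`` layout (round-trips
    through :func:`parse_repeatmasker_out`)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query      position in query"
            "     matching repeat\n"
        )
        fh.write(
            "score   div. del. ins.  sequence   begin  end   (left)"
            "   strand repeat            class/family\n"
        )
        fh.write("\n")
        for track in tracks:
            for h in track.hits:
                fh.write(
                    f"{h.score:7.0f}  0.0  0.0  0.0  {h.query}  "
                    f"{h.interval.start}  {h.interval.end}  (0)  {h.strand}  "
                    f"{h.repeat_name}  {h.repeat_class}\n"
                )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def sanitize_label(label: str) -> str:
    """Whitespace in a leaf label becomes underscore; any remaining
    Newick metacharacter is an error (keeps downstream diffs bit-exact)."""
    clean = re.sub(r"\s+", "_", label.strip())
    if _NEWICK_META.search(clean):
        raise SeqIOError(
            f"leaf label {label!r} contains Newick metacharacters; rename it"
        )
    return clean


def read_newick(path: str | Path, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Read a Newick tree; internal-node labels are kept as support labels."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        taxon_namespace=taxon_namespace,
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as Newick with branch lengths; internal-node labels
    (support values) are emitted as-is."""
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if n_leaves < 2:
        raise SeqIOError("refusing to write a tree with fewer than 2 leaves")
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None:
            leaf.taxon.label = sanitize_label(leaf.taxon.label)
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            )
        )
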