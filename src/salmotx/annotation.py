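"""Annotation data model: exons, transcripts, loci and whole-genome containers.

Coordinates are stored exactly as GTF gives them: 1-based, inclusive on both
ends, strand in ``{+,-}``.  Any half-open arithmetic is local to a function
and never serialized, so round-trips through :func:`read_gtf` /
:func:`write_gtf` are lossless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from gffutils.feature import Feature, feature_from_line
from intervaltree import IntervalTree

BIOTYPES = {"protein_coding", "lncRNA", "pseudogene", "miRNA", "other", "unknown"}


class GtfParseError(ValueError):
    """A GTF record could not be interpreted; carries the offending line number."""


@dataclass(frozen=True)
class Exon:
    """A single exon, 1-based inclusive coordinates."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("exon contig must be non-empty")
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    """A stranded, multi-exon transcript.

    Exons are normalized to sorted order on construction; they must be
    non-overlapping and share one contig.
    """

    id: str
    contig: str
    strand: str
    exons: list[Exon]
    biotype: str = "unknown"
    locus_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        if self.biotype not in BIOTYPES:
            self.biotype = "other"
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for e in self.exons:
            if e.contig != self.contig:
                raise ValueError(f"transcript {self.id}: exon on different contig")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"transcript {self.id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals (1-based inclusive) between consecutive exons."""
        return [
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def junctions(self) -> set[tuple[int, int]]:
        """Splice junctions as (donor exon end, acceptor exon start) pairs."""
        return {(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])}


def tss(transcript: Transcript) -> int:
    """Transcription start site: first-exon start on "+", last-exon end on "-".

    Exon order is normalized at construction, so this is invariant to the
    order exons were supplied in.
    """
    if transcript.strand == "+":
        return transcript.exons[0].start
    return transcript.exons[-1].end


@dataclass
class Locus:
    """A gene locus grouping one or more same-strand transcripts."""

    id: str
    contig: str
    strand: str
    transcripts: list[Transcript]
    origin: str = "reference"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"locus {self.id} has no transcripts")
        for t in self.transcripts:
            if t.contig != self.contig or t.strand != self.strand:
                raise ValueError(
                    f"locus {self.id}: member {t.id} disagrees on contig/strand"
                )
            t.locus_id = self.id

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )

    @property
    def exon_union_length(self) -> int:
        """Length of the union of exons over all isoforms (TPM length convention)."""
        ivs = sorted((e.start, e.end) for t in self.transcripts for e in t.exons)
        total = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
        return total

    @property
    def biotype(self) -> str:
        types = {t.biotype for t in self.transcripts}
        if len(types) == 1:
            return next(iter(types))
        if "protein_coding" in types:
            return "protein_coding"
        return "other"


class GenomeAnnotation:
    """A collection of loci with an interval index for overlap queries."""

    def __init__(
        self,
        loci: Iterable[Locus],
        contigs: dict[str, int] | None = None,
    ) -> None:
        self.loci: dict[str, Locus] = {}
        self.transcripts: dict[str, Transcript] = {}
        self.contigs = dict(contigs) if contigs else {}
        self._exon_trees: dict[str, IntervalTree] = {}
        self._span_trees: dict[str, IntervalTree] = {}
        for locus in loci:
            if locus.id in self.loci:
                raise ValueError(f"duplicate locus id {locus.id}")
            self.loci[locus.id] = locus
            for t in locus.transcripts:
                if t.id in self.transcripts:
                    raise ValueError(f"duplicate transcript id {t.id}")
                self.transcripts[t.id] = t
                # trees are half-open internally; +1 converts back on query
                stree = self._span_trees.setdefault(t.contig, IntervalTree())
                stree.addi(t.start, t.end + 1, t.id)
                etree = self._exon_trees.setdefault(t.contig, IntervalTree())
                for e in t.exons:
                    etree.addi(e.start, e.end + 1, t.id)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[Locus]:
        return iter(self.loci.values())

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    def transcripts_overlapping(
        self, contig: str, start: int, end: int
    ) -> list[Transcript]:
        """Every transcript whose span overlaps [start, end] (1-based inclusive)."""
        tree = self._span_trees.get(contig)
        if tree is None:
            return []
        ids = {iv.data for iv in tree.overlap(start, end + 1)}
        return [self.transcripts[i] for i in sorted(ids)]

    def transcripts_with_exon_overlap(
        self, contig: str, start: int, end: int
    ) -> list[Transcript]:
        """Every transcript with at least one exon overlapping [start, end]."""
        tree = self._exon_trees.get(contig)
        if tree is None:
            return []
        ids = {iv.data for iv in tree.overlap(start, end + 1)}
        return [self.transcripts[i] for i in sorted(ids)]

    def contig_length(self, contig: str) -> int:
        if contig not in self.contigs:
            raise KeyError(
                f"length of contig {contig!r} unknown; supply `contigs` mapping"
            )
        return self.contigs[contig]


def genomic_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Bases strictly between two same-contig spans; 0 if they overlap or abut.

    Spans are 1-based inclusive ``(start, end)`` tuples; contig identity must
    be checked by the caller (pairing across contigs is a caller error).
    """
    (a1, a2), (b1, b2) = a, b
    if a1 > b1:
        a1, a2, b1, b2 = b1, b2, a1, a2
    return max(0, b1 - a2 - 1)


@dataclass
class SampleTable:
    """Sample ids with one tissue label each."""

    tissue_of: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.tissues) < 2:
            raise ValueError("at least 2 tissues required")

    @property
    def samples(self) -> list[str]:
        return list(self.tissue_of)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.tissue_of.values():
            seen.setdefault(t, None)
        return list(seen)

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s, t in self.tissue_of.items() if t == tissue]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleTable":
        tissue_of: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["sample", "tissue"]:
                raise ValueError("expected header: sample<TAB>tissue")
            for line in fh:
                if not line.strip():
                    continue
                sample, tissue = line.rstrip("\n").split("\t")[:2]
                tissue_of[sample] = tissue
        return cls(tissue_of)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\ttissue\n")
            for s, t in self.tissue_of.items():
                fh.write(f"{s}\t{t}\n")


def _merge_unassigned_into_loci(transcripts: Sequence[Transcript]) -> list[Locus]:
    """Group transcripts without a gene_id by single-linkage exon overlap.

    Same-strand transcripts whose exons overlap are merged into one locus
    (StringTie-like), so locus-level statistics are well defined even for
    assemblies that ship no gene_id attribute.
    """
    by_key: dict[tuple[str, str], list[Transcript]] = {}
    for t in transcripts:
        by_key.setdefault((t.contig, t.strand), []).append(t)
    loci: list[Locus] = []
    n = 0
    for (contig, strand), group in sorted(by_key.items()):
        tree = IntervalTree()
        for i, t in enumerate(group):
            for e in t.exons:
                tree.addi(e.start, e.end + 1, i)
        parent = list(range(len(group)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, t in enumerate(group):
            for e in t.exons:
                for iv in tree.overlap(e.start, e.end + 1):
                    ri, rj = find(i), find(iv.data)
                    if ri != rj:
                        parent[ri] = rj
        clusters: dict[int, list[Transcript]] = {}
        for i, t in enumerate(group):
            clusters.setdefault(find(i), []).append(t)
        for members in sorted(
            clusters.values(), key=lambda ms: min(m.start for m in ms)
        ):
            n += 1
            loci.append(
                Locus(
                    id=f"LOC.{contig}.{strand}.{n}",
                    contig=contig,
                    strand=strand,
                    transcripts=sorted(members, key=lambda m: m.id),
                    origin="assembled",
                )
            )
    return loci


def read_gtf(path: str | Path, origin: str = "reference") -> GenomeAnnotation:
    """Read a GTF file (Ensembl attribute dialect) into a :class:`GenomeAnnotation`.

    Exon records are grouped into transcripts by ``transcript_id`` and into
    loci by ``gene_id``; biotype comes from ``gene_biotype`` or
    ``transcript_biotype`` and defaults to ``unknown``.  Transcripts without
    a gene_id are clustered into loci by same-strand exon overlap.
    """
    exons: dict[str, list[Exon]] = {}
    meta: dict[str, tuple[str, str, str, str | None]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or not (
                fields[3].isdigit() and fields[4].isdigit()
            ):
                raise GtfParseError(f"line {lineno}: malformed GTF record")
            try:
                feat: Feature = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"line {lineno}: malformed GTF record: {exc}")
            if feat.featuretype != "exon":
                continue
            tid_vals = feat.attributes.get("transcript_id")
            if not tid_vals:
                raise GtfParseError(f"line {lineno}: exon without transcript_id")
            tid = tid_vals[0]
            if feat.strand not in {"+", "-"}:
                raise GtfParseError(
                    f"line {lineno}: strand must be + or -, got {feat.strand!r}"
                )
            exons.setdefault(tid, []).append(
                Exon(contig=feat.seqid, start=feat.start, end=feat.end)
            )
            if tid not in meta:
                biotype = (
                    feat.attributes.get("gene_biotype", [None])[0]
                    or feat.attributes.get("transcript_biotype", [None])[0]
                    or "unknown"
                )
                gid = feat.attributes.get("gene_id", [None])[0]
                meta[tid] = (feat.seqid, feat.strand, biotype, gid)
                order.append(tid)
    transcripts: list[Transcript] = []
    gene_of: dict[str, str | None] = {}
    for tid in order:
        contig, strand, biotype, gid = meta[tid]
        transcripts.append(
            Transcript(id=tid, contig=contig, strand=strand,
                       exons=exons[tid], biotype=biotype)
        )
        gene_of[tid] = gid
    by_gene: dict[str, list[Transcript]] = {}
    unassigned: list[Transcript] = []
    for t in transcripts:
        gid = gene_of[t.id]
        if gid is None:
            unassigned.append(t)
        else:
            by_gene.setdefault(gid, []).append(t)
    loci = [
        Locus(id=gid, contig=ms[0].contig, strand=ms[0].strand,
              transcripts=sorted(ms, key=lambda m: m.id), origin=origin)
        for gid, ms in by_gene.items()
    ]
    loci.extend(_merge_unassigned_into_loci(unassigned))
    return GenomeAnnotation(loci)


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write exon records in deterministic order (contig, start, transcript id)."""
    records: list[tuple[str, int, str, Feature]] = []
    for locus in annotation:
        for t in locus.transcripts:
            for e in t.exons:
                feat = Feature(
                    seqid=e.contig,
                    source="salmotx",
                    featuretype="exon",
                    start=e.start,
                    end=e.end,
                    score=".",
                    strand=t.strand,
                    frame=".",
                    attributes=(
                        f'gene_id "{locus.id}"; transcript_id "{t.id}"; '
                        f'gene_biotype "{t.biotype}";'
                    ),
                    dialect=_GTF_DIALECT,
                )
                records.append((e.contig, e.start, t.id, feat))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write("## GTF written by salmotx; 1-based inclusive coordinates\n")
        for *_key, feat in records:
            fh.write(str(feat) + "\n")


# GTF attribute dialect used for serialization (gene_id "X"; style)
_GTF_DIALECT = {
    "field separator": "; ",
    "fmt": "gtf",
    "keyval separator": " ",
    "leading semicolon": False,
    "multival separator": ",",
    "quoted GFF2 values": True,
    "order": ["gene_id", "transcript_id", "gene_biotype"],
    "repeated keys": False,
    "trailing semicolon": True,
}


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
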