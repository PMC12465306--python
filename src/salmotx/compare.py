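"""gffcompare-style classification of assembled transcripts against a reference.

Each assembled transcript receives a single-character class code describing
its structural relation to the reference annotation, with precedence
``= > c > j > e > o > i > x > u``:

=  identical intron chain with some reference transcript (terminal exon
   boundaries free)
c  contained in a reference transcript with a compatible intron chain
j  multi-exon transcript sharing at least one splice junction, same strand
e  single-exon transcript lying within a reference exon (small flank allowed)
o  other same-strand exonic overlap
i  fully contained within a reference intron
x  exonic overlap on the opposite strand
u  no exonic overlap with the reference on either strand (intergenic)

The module also computes assembly-level sensitivity/precision, per-sample
support of intergenic transcripts, and the cross-dataset intergenic overlap
report used for benchmarking one assembly's intergenic set against another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from salmotx.annotation import GenomeAnnotation, SampleTable, Transcript

CLASS_CODES = ("=", "c", "j", "e", "o", "i", "x", "u", "other")

_E_FLANK = 10  # bp tolerance for single-exon containment within a reference exon


@dataclass
class TranscriptComparison:
    """Class code plus best reference match for one assembled transcript."""

    transcript_id: str
    class_code: str
    ref_match: str | None = None
    shared_junctions: int = 0


def _exonic_overlap(a: Transcript, b: Transcript) -> bool:
    for ea in a.exons:
        for eb in b.exons:
            if ea.start <= eb.end and eb.start <= ea.end:
                return True
    return False


def _contained_compatible(asm: Transcript, ref: Transcript) -> bool:
    """True when asm lies within ref's span and its introns are a contiguous
    sub-chain of ref's introns (single-exon asm: must not cross any ref intron)."""
    if asm.start < ref.start or asm.end > ref.end:
        return False
    aj = asm.junctions
    if not aj:
        # single exon: contained and not spanning any junction of ref
        return all(
            not (asm.start <= j0 and j1 <= asm.end) for j0, j1 in ref.junctions
        )
    rj_sorted = sorted(ref.junctions)
    aj_sorted = sorted(aj)
    if not aj <= ref.junctions:
        return False
    # sub-chain must be contiguous within ref's intron chain
    first = rj_sorted.index(aj_sorted[0])
    return rj_sorted[first : first + len(aj_sorted)] == aj_sorted


def classify(
    assembled: Transcript, reference: GenomeAnnotation
) -> TranscriptComparison:
    """Assign the class code of one assembled transcript.

    A transcript on a contig absent from the reference is classified "u"
    with a warning rather than an error.
    """
    contig = assembled.contig
    if contig not in reference._span_trees:
        warnings.warn(
            f"contig {contig!r} absent from reference; {assembled.id} -> 'u'"
        )
        return TranscriptComparison(assembled.id, "u")

    overlapping = reference.transcripts_overlapping(
        contig, assembled.start, assembled.end
    )
    same = [t for t in overlapping if t.strand == assembled.strand]
    anti = [t for t in overlapping if t.strand != assembled.strand]
    aj = assembled.junctions

    # "=": identical intron chain (multi-exon) or single-exon exonic overlap
    # with a single-exon reference transcript
    for ref in same:
        if aj and ref.junctions == aj:
            return TranscriptComparison(assembled.id, "=", ref.id, len(aj))
        if not aj and not ref.junctions and _exonic_overlap(assembled, ref):
            return TranscriptComparison(assembled.id, "=", ref.id, 0)

    # "c": contained with compatible intron chain
    for ref in sorted(same, key=lambda t: t.id):
        if _exonic_overlap(assembled, ref) and _contained_compatible(assembled, ref):
            return TranscriptComparison(
                assembled.id, "c", ref.id, len(aj & ref.junctions)
            )

    # "j": multi-exon sharing >= 1 junction
    if aj:
        best, shared = None, 0
        for ref in sorted(same, key=lambda t: t.id):
            s = len(aj & ref.junctions)
            if s > shared:
                best, shared = ref, s
        if best is not None:
            return TranscriptComparison(assembled.id, "j", best.id, shared)

    same_exonic = [
        t for t in same if _exonic_overlap(assembled, t)
    ]
    # "e": single-exon transcript within a reference exon (+/- flank)
    if not aj:
        for ref in sorted(same_exonic, key=lambda t: t.id):
            for e in ref.exons:
                if (
                    e.start - _E_FLANK <= assembled.start
                    and assembled.end <= e.end + _E_FLANK
                ):
                    return TranscriptComparison(assembled.id, "e", ref.id, 0)

    # "o": other same-strand exonic overlap
    if same_exonic:
        ref = sorted(same_exonic, key=lambda t: t.id)[0]
        return TranscriptComparison(assembled.id, "o", ref.id, 0)

    # "i": fully within an intron of a reference transcript (either strand)
    for ref in sorted(overlapping, key=lambda t: t.id):
        for i0, i1 in ref.introns:
            if i0 <= assembled.start and assembled.end <= i1:
                return TranscriptComparison(assembled.id, "i", ref.id, 0)

    # "x": exonic overlap on the opposite strand
    for ref in sorted(anti, key=lambda t: t.id):
        if _exonic_overlap(assembled, ref):
            return TranscriptComparison(assembled.id, "x", ref.id, 0)

    # span overlap without exon overlap on same strand and not intronic:
    # overlaps extended gene region; gffcompare has finer codes, collapse.
    if overlapping:
        return TranscriptComparison(assembled.id, "other", None, 0)

    return TranscriptComparison(assembled.id, "u")


def classify_all(
    assembled: GenomeAnnotation, reference: GenomeAnnotation
) -> dict[str, TranscriptComparison]:
    return {
        tid: classify(t, reference)
        for tid, t in sorted(assembled.transcripts.items())
    }


def summarize_codes(
    comparisons: dict[str, TranscriptComparison] | list[TranscriptComparison],
) -> dict[str, tuple[int, float]]:
    """Count and fraction per class code; fractions sum to 1."""
    if isinstance(comparisons, dict):
        comparisons = list(comparisons.values())
    if not comparisons:
        raise ValueError("no comparisons to summarize")
    counts: dict[str, int] = {}
    for c in comparisons:
        counts[c.class_code] = counts.get(c.class_code, 0) + 1
    n = len(comparisons)
    return {code: (k, k / n) for code, k in sorted(counts.items())}


def sensitivity_precision(
    comparisons: dict[str, TranscriptComparison] | list[TranscriptComparison],
    reference: GenomeAnnotation,
) -> tuple[float, float]:
    """Assembly-level (sensitivity %, precision %).

    Sensitivity: % of reference transcripts exactly matched ("=") by at
    least one assembled transcript.  Precision: % of assembled transcripts
    coded "=".
    """
    if isinstance(comparisons, dict):
        comparisons = list(comparisons.values())
    if reference.n_transcripts == 0:
        raise ValueError("empty reference annotation")
    if not comparisons:
        raise ValueError("no comparisons")
    matched_refs = {
        c.ref_match for c in comparisons if c.class_code == "=" and c.ref_match
    }
    n_eq = sum(1 for c in comparisons if c.class_code == "=")
    sens = 100.0 * len(matched_refs) / reference.n_transcripts
    prec = 100.0 * n_eq / len(comparisons)
    return sens, prec


@dataclass
class SupportTable:
    """Per-sample support counts for intergenic ("u") transcripts."""

    total_support: dict[str, int]
    per_tissue: dict[str, dict[str, int]]
    n_supported: int = 0
    n_more_than_five: int = 0
    n_tissue_exclusive: int = 0
    tissue_exclusive_ids: list[str] = field(default_factory=list)


def intergenic_support(
    presence: dict[str, set[str]],
    samples: SampleTable,
    comparisons: dict[str, TranscriptComparison],
) -> SupportTable:
    """Summarize assembly-based per-sample support for intergenic transcripts.

    ``presence`` maps sample id -> set of transcript ids present in that
    sample's assembly.  A transcript is tissue-exclusive when detected in
    exactly one tissue AND supported by every sample of that tissue.
    """
    for sid in presence:
        if sid not in samples.tissue_of:
            raise ValueError(f"unknown sample id {sid!r} in presence tables")
    intergenic = sorted(
        tid for tid, c in comparisons.items() if c.class_code == "u"
    )
    total: dict[str, int] = {}
    per_tissue: dict[str, dict[str, int]] = {}
    exclusive: list[str] = []
    tissue_sizes = {t: len(samples.samples_of(t)) for t in samples.tissues}
    for tid in intergenic:
        by_tissue = {t: 0 for t in samples.tissues}
        for sid, present in presence.items():
            if tid in present:
                by_tissue[samples.tissue_of[sid]] += 1
        total[tid] = sum(by_tissue.values())
        per_tissue[tid] = by_tissue
        seen = [t for t, k in by_tissue.items() if k > 0]
        if len(seen) == 1 and by_tissue[seen[0]] == tissue_sizes[seen[0]]:
            exclusive.append(tid)
    return SupportTable(
        total_support=total,
        per_tissue=per_tissue,
        n_supported=sum(1 for k in total.values() if k >= 1),
        n_more_than_five=sum(1 for k in total.values() if k > 5),
        n_tissue_exclusive=len(exclusive),
        tissue_exclusive_ids=exclusive,
    )


@dataclass
class OverlapReport:
    """Cross-dataset comparison of one intergenic set against another."""

    status: dict[str, str]  # transcript id -> complete / partial / unmatched
    shorter: dict[str, bool]  # among matched: query shorter than its match
    frac_matched: float = 0.0
    frac_shorter_of_matched: float = 0.0


def intergenic_overlap_report(
    query: GenomeAnnotation, subject: GenomeAnnotation
) -> OverlapReport:
    """Match each query transcript to the subject set by same-strand exonic
    overlap: complete when the intron chains agree (single-exon: mutual exon
    overlap with a single-exon subject), partial otherwise, unmatched when no
    same-strand exonic overlap exists."""
    status: dict[str, str] = {}
    shorter: dict[str, bool] = {}
    for tid, q in sorted(query.transcripts.items()):
        hits = [
            t
            for t in subject.transcripts_with_exon_overlap(q.contig, q.start, q.end)
            if t.strand == q.strand and _exonic_overlap(q, t)
        ]
        if not hits:
            status[tid] = "unmatched"
            continue
        complete = [t for t in hits if t.junctions == q.junctions]
        match = min(complete or hits, key=lambda t: t.id)
        status[tid] = "complete" if complete else "partial"
        shorter[tid] = q.length < match.length
    n = len(status)
    n_matched = sum(1 for s in status.values() if s != "unmatched")
    return OverlapReport(
        status=status,
        shorter=shorter,
        frac_matched=n_matched / n if n else 0.0,
        frac_shorter_of_matched=(
            sum(shorter.values()) / n_matched if n_matched else 0.0
        ),
    )
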