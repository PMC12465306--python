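"""Positional annotation of candidate lncRNAs relative to nearby genes.

Mirrors the sliding-window nearest-partner strategy used for lncRNA
classification: windows of 10-100 kb (step 10 kb) are grown around the
lncRNA until one contains an annotated transcript; the partner is the
candidate with the smallest boundary gap.  Direction (sense/antisense) and
location (upstream/downstream of the partner's TSS, in the partner's
orientation) define the positional subtype used to nominate divergent
(bi-directional promoter) arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass

from salmotx.annotation import GenomeAnnotation, Transcript, genomic_gap, tss

DEFAULT_WINDOWS = tuple(range(10_000, 100_001, 10_000))


@dataclass
class PositionAnnotation:
    lnc_id: str
    partner_id: str | None
    genic_context: str  # "genic" | "intergenic"
    direction: str | None  # "sense" | "antisense"
    location: str | None  # "upstream" | "downstream"
    subtype: str | None  # e.g. "intergenic antisense upstream"
    gap_bp: int | None
    tss_distance_bp: int | None
    window_used: int | None


def tss_distance(lnc: Transcript, partner: Transcript) -> int:
    """Absolute distance between the two transcription start sites."""
    if lnc.contig != partner.contig:
        raise ValueError("tss_distance requires transcripts on the same contig")
    return abs(tss(lnc) - tss(partner))


def _location(lnc: Transcript, partner: Transcript) -> str:
    """Upstream means the lncRNA lies on the partner's 5' side of its TSS.

    The lncRNA span midpoint is compared with the partner TSS so the call is
    well defined even when the spans overlap slightly (as divergent pairs
    often do).
    """
    mid = (lnc.start + lnc.end) / 2.0
    p_tss = tss(partner)
    if partner.strand == "+":
        return "upstream" if mid < p_tss else "downstream"
    return "upstream" if mid > p_tss else "downstream"


def find_partner(
    lnc: Transcript,
    annotation: GenomeAnnotation,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
) -> PositionAnnotation:
    """Annotate one lncRNA against its nearest annotated transcript.

    The smallest window containing at least one annotated transcript
    determines the candidate set; among candidates the partner minimizes the
    boundary gap (ties: smaller TSS distance, then lexicographic id).  A
    lncRNA overlapping an annotated transcript is genic (window 0).  With no
    candidate within the largest window the partner is None.
    """
    lnc_span = (lnc.start, lnc.end)

    overlapping = [
        t
        for t in annotation.transcripts_overlapping(lnc.contig, lnc.start, lnc.end)
        if t.id != lnc.id
    ]
    genic = bool(overlapping)

    chosen: Transcript | None = None
    window_used: int | None = None
    if genic:
        candidates = overlapping
        window_used = 0
    else:
        candidates = []
        for w in sorted(windows):
            hits = [
                t
                for t in annotation.transcripts_overlapping(
                    lnc.contig, max(1, lnc.start - w), lnc.end + w
                )
                if t.id != lnc.id
                and genomic_gap(lnc_span, (t.start, t.end)) <= w
            ]
            if hits:
                candidates = hits
                window_used = w
                break
    if candidates:
        chosen = min(
            candidates,
            key=lambda t: (
                genomic_gap(lnc_span, (t.start, t.end)),
                tss_distance(lnc, t),
                t.id,
            ),
        )
    if chosen is None:
        return PositionAnnotation(
            lnc.id, None, "intergenic", None, None, None, None, None, None
        )
    direction = "sense" if lnc.strand == chosen.strand else "antisense"
    location = _location(lnc, chosen)
    context = "genic" if genic else "intergenic"
    return PositionAnnotation(
        lnc_id=lnc.id,
        partner_id=chosen.id,
        genic_context=context,
        direction=direction,
        location=location,
        subtype=f"{context} {direction} {location}",
        gap_bp=genomic_gap(lnc_span, (chosen.start, chosen.end)),
        tss_distance_bp=tss_distance(lnc, chosen),
        window_used=window_used,
    )


def annotate_all(
    lncs: list[Transcript],
    annotation: GenomeAnnotation,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
) -> dict[str, PositionAnnotation]:
    return {t.id: find_partner(t, annotation, windows) for t in lncs}


def locus_rollup(
    positions: dict[str, PositionAnnotation],
    lnc_locus_of: dict[str, str],
) -> dict[str, PositionAnnotation]:
    """Locus-level partner: the member isoform annotation with the smallest
    boundary gap (partner search runs per isoform, reporting is per locus)."""
    best: dict[str, PositionAnnotation] = {}
    for tid, pos in positions.items():
        if pos.partner_id is None:
            continue
        lid = lnc_locus_of[tid]
        cur = best.get(lid)
        if (
            cur is None
            or (pos.gap_bp, pos.tss_distance_bp, tid)
            < (cur.gap_bp, cur.tss_distance_bp, cur.lnc_id)
        ):
            best[lid] = pos
    return best
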