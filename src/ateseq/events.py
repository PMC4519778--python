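"""Decompose a transcript pair into classified alternative transcription events.

Given two isoforms of a gene, the divergence between their exonic spaces is
anchored on shared *bases* (not shared whole exons): the first and last
genomic position present in both transcripts delimit the shared body.
Divergent exonic intervals strictly before the first shared base form one
upstream event, intervals strictly after the last shared base one downstream
event, and each maximal run of divergent intervals in between (runs are
broken only by shared exonic bases, not by bases intronic in both isoforms)
forms one contained event. Positional classes are expressed in 5'->3'
transcript orientation and map onto event types: upstream <-> alternative
promoter, contained <-> alternative splicing, downstream <-> alternative
3' end. Anchoring on bases rather than whole exons means partial terminal-exon
extensions - the dominant mode of 3' UTR shortening - are detected as
downstream events.

An event changes the coding sequence by the length of the CDS symmetric
difference restricted to its divergent intervals; events altering more than
100 bp of CDS are flagged ``coding``, the rest are UTR-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .annotation import (
    AnnotationError,
    Interval,
    TranscriptModel,
    interval_length,
    intersect_intervals,
    merge_intervals,
    subtract_intervals,
    symmetric_difference_intervals,
)

CDS_CODING_THRESHOLD_BP = 100  # CDS change above this marks an event as coding

_POSITIONAL_TO_TYPE = {
    "upstream": "alternative_promoter",
    "contained": "alternative_splicing",
    "downstream": "alternative_3prime",
}


@dataclass
class ATEvent:
    """One positional divergence between two isoforms of a gene."""

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    positional_class: str  # upstream / contained / downstream (5'->3')
    alt_ref: list[Interval]  # divergent intervals exonic in the reference only
    alt_alt: list[Interval]  # divergent intervals exonic in the other isoform only
    cds_change_bp: int = 0
    ref_id: str = ""
    alt_id: str = ""
    whole_transcript: bool = field(default=False)

    @property
    def event_type(self) -> str:
        return _POSITIONAL_TO_TYPE[self.positional_class]

    @property
    def coding(self) -> bool:
        return self.cds_change_bp > CDS_CODING_THRESHOLD_BP

    @property
    def divergent_intervals(self) -> list[Interval]:
        return merge_intervals(self.alt_ref + self.alt_alt)

    @property
    def divergent_bp(self) -> int:
        return interval_length(self.divergent_intervals)


@dataclass
class EventAnnotation:
    """An event expressed as two synthetic transcripts (ref/alt alternative)."""

    event: ATEvent
    ref_transcript: TranscriptModel  # id "<event_id>.ref"
    alt_transcript: TranscriptModel  # id "<event_id>.alt"

    @property
    def span(self) -> Interval:
        s = min(self.ref_transcript.start, self.alt_transcript.start)
        e = max(self.ref_transcript.end, self.alt_transcript.end)
        return (s, e)


def _check_pair(reference: TranscriptModel, changed: TranscriptModel) -> None:
    if reference.gene_id != changed.gene_id:
        raise AnnotationError(
            f"transcripts of different genes: {reference.gene_id} vs {changed.gene_id}"
        )
    if reference.strand != changed.strand or reference.chrom != changed.chrom:
        raise AnnotationError(
            f"{reference.transcript_id}/{changed.transcript_id}: "
            "strand or chromosome mismatch"
        )


def find_events(
    reference: TranscriptModel, changed: TranscriptModel
) -> list[ATEvent]:
    """Split the exonic divergence of a transcript pair into classified events.

    Returns one event per maximal divergent region; an empty list for
    structurally identical transcripts. If the pair shares no exonic base at
    all the whole divergence is reported as a single contained event with a
    warning.
    """
    _check_pair(reference, changed)
    shared = intersect_intervals(reference.exons, changed.exons)
    diff = symmetric_difference_intervals(reference.exons, changed.exons)
    if not diff:
        return []

    strand = reference.strand

    if not shared:
        warnings.warn(
            f"{reference.gene_id}: {reference.transcript_id} and "
            f"{changed.transcript_id} share no exonic base; reporting a single "
            "whole-transcript event",
            stacklevel=2,
        )
        groups = [("contained", diff)]
        return _build_events(reference, changed, groups, whole_transcript=True)

    first_shared = shared[0][0]
    last_shared = shared[-1][1]  # exclusive

    upstream_g: list[Interval] = []  # genomically left of first shared base
    downstream_g: list[Interval] = []
    internal: list[Interval] = []
    for s, e in diff:
        if e <= first_shared:
            upstream_g.append((s, e))
        elif s >= last_shared:
            downstream_g.append((s, e))
        else:
            # divergent intervals never straddle a shared base: shared and
            # divergent space are disjoint by construction, so an interval
            # overlapping (first_shared, last_shared) lies fully inside it
            internal.append((s, e))

    # maximal runs of internal divergence, split only by shared exonic bases
    runs: list[list[Interval]] = []
    for iv in internal:
        if runs and not intersect_intervals(shared, [(runs[-1][-1][1], iv[0])]):
            runs[-1].append(iv)
        else:
            runs.append([iv])

    groups: list[tuple[str, list[Interval]]] = []
    # positional class is in transcript 5'->3' orientation
    left_class = "upstream" if strand == "+" else "downstream"
    right_class = "downstream" if strand == "+" else "upstream"
    if upstream_g:
        groups.append((left_class, upstream_g))
    for run in runs:
        groups.append(("contained", run))
    if downstream_g:
        groups.append((right_class, downstream_g))
    return _build_events(reference, changed, groups, whole_transcript=False)


def _build_events(
    reference: TranscriptModel,
    changed: TranscriptModel,
    groups: list[tuple[str, list[Interval]]],
    whole_transcript: bool,
) -> list[ATEvent]:
    cds_r = reference.cds or []
    cds_a = changed.cds or []
    cds_diff = symmetric_difference_intervals(cds_r, cds_a)
    events = []
    for k, (pos_class, ivs) in enumerate(groups, start=1):
        alt_ref = intersect_intervals(ivs, reference.exons)
        alt_alt = intersect_intervals(ivs, changed.exons)
        cds_bp = interval_length(intersect_intervals(cds_diff, ivs))
        events.append(
            ATEvent(
                event_id=f"{reference.gene_id}.e{k}",
                gene_id=reference.gene_id,
                chrom=reference.chrom,
                strand=reference.strand,
                positional_class=pos_class,
                alt_ref=alt_ref,
                alt_alt=alt_alt,
                cds_change_bp=cds_bp,
                ref_id=reference.transcript_id,
                alt_id=changed.transcript_id,
                whole_transcript=whole_transcript,
            )
        )
    return events


def build_event_annotation(
    event: ATEvent,
    reference: TranscriptModel,
    changed: TranscriptModel,
    flank_exons: int = 1,
) -> EventAnnotation:
    """Turn an event into a pair of short synthetic transcripts.

    Each alternative consists of its divergent exons plus up to
    ``flank_exons`` shared exonic intervals on each side that abuts shared
    space (upstream events are flanked only downstream, downstream events
    only upstream). The flanks anchor junction-informative signal while
    keeping the event annotation short.
    """
    if flank_exons < 0:
        raise ValueError("flank_exons must be >= 0")
    _check_pair(reference, changed)
    shared = intersect_intervals(reference.exons, changed.exons)
    div = event.divergent_intervals
    if div:
        div_start, div_end = div[0][0], div[-1][1]
    else:
        raise ValueError(f"{event.event_id}: event has no divergent intervals")

    left = [iv for iv in shared if iv[1] <= div_start]
    right = [iv for iv in shared if iv[0] >= div_end]
    use_left = event.positional_class != (
        "upstream" if event.strand == "+" else "downstream"
    )
    use_right = event.positional_class != (
        "downstream" if event.strand == "+" else "upstream"
    )
    flanks: list[Interval] = []
    if use_left and flank_exons:
        flanks.extend(left[-flank_exons:])
    if use_right and flank_exons:
        flanks.extend(right[:flank_exons])

    ref_exons = merge_intervals(event.alt_ref + flanks)
    alt_exons = merge_intervals(event.alt_alt + flanks)
    if not ref_exons or not alt_exons:
        raise AnnotationError(
            f"{event.event_id}: an alternative has no exons "
            "(flank_exons=0 with an empty-side alternative)"
        )
    mk = lambda suffix, exons: TranscriptModel(  # noqa: E731
        transcript_id=f"{event.event_id}.{suffix}",
        gene_id=event.gene_id,
        chrom=event.chrom,
        strand=event.strand,
        exons=exons,
    )
    return EventAnnotation(
        event=event,
        ref_transcript=mk("ref", ref_exons),
        alt_transcript=mk("alt", alt_exons),
    )


def classify_utr_length(event: ATEvent) -> str:
    """Label which alternative of a UTR-only 3' event has the longer extent.

    Returns ``long_ref`` or ``long_alt`` for non-coding alternative-3'-end
    events, ``not_applicable`` otherwise. Ties break toward the reference.
    """
    if event.event_type != "alternative_3prime" or event.coding:
        return "not_applicable"
    len_ref = interval_length(event.alt_ref)
    len_alt = interval_length(event.alt_alt)
    if len_ref == len_alt:
        warnings.warn(
            f"{event.event_id}: equal alternative lengths, tie broken to long_ref",
            stacklevel=2,
        )
    return "long_ref" if len_ref >= len_alt else "long_alt"
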