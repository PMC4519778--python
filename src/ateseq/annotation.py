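"""Transcript and gene models, exonic interval algebra, and GTF I/O.

Coordinates are 0-based half-open internally; the GTF reader/writer converts
to and from the 1-based inclusive convention of Ensembl-style GTF. Interval
arithmetic on exon chains (union, intersection, symmetric difference,
restriction) underpins the alternative-transcription-event algebra, so it is
implemented here on plain sorted ``(start, end)`` tuples rather than through a
genome-arithmetic framework: the per-transcript interval lists are tiny and
the event definitions need exact per-base semantics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class GTFParseError(ValueError):
    """Raised when a GTF record cannot be interpreted."""


class AnnotationError(ValueError):
    """Raised when a transcript or gene violates a structural invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# interval-list algebra (lists of (start, end), sorted, disjoint)
# ---------------------------------------------------------------------------

def merge_intervals(ivs: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping or book-ended intervals."""
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def interval_length(ivs: list[Interval]) -> int:
    return sum(e - s for s, e in ivs)


def intersect_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Per-base intersection of two sorted disjoint interval lists."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Bases in ``a`` but not in ``b``."""
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def symmetric_difference_intervals(
    a: list[Interval], b: list[Interval]
) -> list[Interval]:
    """Maximal intervals covered by exactly one of the two sets."""
    return merge_intervals(subtract_intervals(a, b) + subtract_intervals(b, a))


def restrict_intervals(ivs: list[Interval], span: Interval) -> list[Interval]:
    """Clip an interval list to a single window."""
    return intersect_intervals(ivs, [span])


# ---------------------------------------------------------------------------
# transcript / gene models
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """One isoform: strand-aware ordered exons plus optional CDS intervals.

    Exons are kept in genomic order (sorted by start), pairwise disjoint and
    non-book-ended; CDS intervals must lie inside exonic space.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+'/'-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        merged = merge_intervals(exons)
        if len(merged) != len(exons):
            warnings.warn(
                f"{self.transcript_id}: merged book-ended exons", stacklevel=2
            )
        self.exons = merged
        for s, e in self.exons:
            if s >= e:
                raise AnnotationError(f"{self.transcript_id}: empty exon ({s},{e})")
        if self.cds is not None:
            cds = merge_intervals(self.cds)
            if subtract_intervals(cds, self.exons):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS extends outside exonic space"
                )
            self.cds = cds

    @property
    def length(self) -> int:
        return interval_length(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def transcript_coords(self) -> "TranscriptCoords":
        return TranscriptCoords(self)


class TranscriptCoords:
    """Bijection between exonic genomic positions and 5'->3' offsets.

    Offset 0 is the genomic start of the first exon on the + strand and the
    genomic end (last base) of the last exon on the - strand.
    """

    def __init__(self, t: TranscriptModel):
        self._t = t
        self._cum = []
        off = 0
        for s, e in t.exons:
            self._cum.append((s, e, off))
            off += e - s
        self._len = off

    @property
    def length(self) -> int:
        return self._len

    def to_offset(self, pos: int) -> int:
        for s, e, off in self._cum:
            if s <= pos < e:
                plus = off + (pos - s)
                return plus if self._t.strand == "+" else self._len - 1 - plus
        raise KeyError(f"position {pos} not in exonic space of {self._t.transcript_id}")

    def to_genomic(self, offset: int) -> int:
        if not 0 <= offset < self._len:
            raise KeyError(f"offset {offset} outside transcript of length {self._len}")
        plus = offset if self._t.strand == "+" else self._len - 1 - offset
        for s, e, off in self._cum:
            if off <= plus < off + (e - s):
                return s + (plus - off)
        raise AssertionError("unreachable")


@dataclass
class GeneModel:
    """A gene: >=1 transcripts sharing gene_id, chromosome and strand."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"{self.gene_id}: gene has no transcripts")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise AnnotationError(f"{self.gene_id}: duplicate transcript ids")
        strands = {t.strand for t in self.transcripts}
        if len(strands) > 1:
            raise AnnotationError(
                f"{self.gene_id}: transcripts on conflicting strands {strands}"
            )
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise AnnotationError(
                f"{self.gene_id}: transcripts on multiple chromosomes {chroms}"
            )
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise AnnotationError(
                    f"gene {self.gene_id} contains transcript of {t.gene_id}"
                )

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(f"{self.gene_id}: no transcript {transcript_id}")


def transcript_coords(t: TranscriptModel) -> TranscriptCoords:
    """Functional alias for :meth:`TranscriptModel.transcript_coords`."""
    return t.transcript_coords()


def exonic_symmetric_difference(
    a: TranscriptModel, b: TranscriptModel
) -> tuple[list[Interval], int]:
    """Intervals covered by exactly one transcript's exons, and their total bp."""
    if a.chrom != b.chrom:
        raise AnnotationError(
            f"{a.transcript_id} and {b.transcript_id} on different chromosomes"
        )
    if a.strand != b.strand:
        raise AnnotationError(
            f"{a.transcript_id} and {b.transcript_id} on different strands"
        )
    diff = symmetric_difference_intervals(a.exons, b.exons)
    return diff, interval_length(diff)


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect: exon + CDS rows, gene_id/transcript_id attributes)
# ---------------------------------------------------------------------------

def read_gtf(path) -> list[GeneModel]:
    """Read exon and CDS rows of an Ensembl-dialect GTF into gene models.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Genes are returned sorted by (chrom, gene start, gene_id).
    """
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # noqa: BLE001 - reported with line number
                raise GTFParseError(f"line {lineno}: cannot parse GTF record: {exc}")
            if feat.featuretype not in ("exon", "CDS"):
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs or not attrs["transcript_id"]:
                raise GTFParseError(
                    f"line {lineno}: {feat.featuretype} row lacks transcript_id"
                )
            if "gene_id" not in attrs or not attrs["gene_id"]:
                raise GTFParseError(
                    f"line {lineno}: {feat.featuretype} row lacks gene_id"
                )
            tid = attrs["transcript_id"][0]
            rec = exons.setdefault(
                tid,
                {
                    "gene_id": attrs["gene_id"][0],
                    "gene_name": attrs["gene_name"][0]
                    if "gene_name" in attrs
                    else None,
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "exons": [],
                    "cds": [],
                },
            )
            if feat.strand not in ("+", "-"):
                raise GTFParseError(f"line {lineno}: missing strand for {tid}")
            # GTF is 1-based inclusive -> 0-based half-open
            iv = (feat.start - 1, feat.end)
            rec[feat.featuretype.lower() + "s" if feat.featuretype == "exon" else "cds"].append(iv)

    genes: dict[str, list[TranscriptModel]] = {}
    names: dict[str, str | None] = {}
    for tid, rec in exons.items():
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
            cds=rec["cds"] or None,
        )
        genes.setdefault(rec["gene_id"], []).append(t)
        names.setdefault(rec["gene_id"], rec["gene_name"])

    out = [
        GeneModel(gene_id=gid, transcripts=sorted(ts, key=lambda t: t.transcript_id),
                  gene_name=names[gid])
        for gid, ts in genes.items()
    ]
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def _gtf_row(chrom, source, feature, start, end, strand, attrs: str) -> str:
    # internal 0-based half-open -> GTF 1-based inclusive
    return f"{chrom}\t{source}\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}"


def write_gtf(genes: list[GeneModel], path) -> None:
    """Write gene models as Ensembl-dialect GTF (exon + CDS rows).

    Output ordering is fully deterministic: genes by (chrom, start, gene_id),
    transcripts by id, intervals by genomic position. Two writes of the same
    input are byte-identical.
    """
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    lines = ["#!ateseq GTF export"]
    for g in genes:
        for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
            if g.gene_name:
                attrs += f' gene_name "{g.gene_name}";'
            for s, e in t.exons:
                lines.append(_gtf_row(t.chrom, "ateseq", "exon", s, e, t.strand, attrs))
            for s, e in t.cds or []:
                lines.append(_gtf_row(t.chrom, "ateseq", "CDS", s, e, t.strand, attrs))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
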