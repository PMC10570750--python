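"""Genomic interval algebra and annotation I/O.

Coordinates are stored 0-based half-open throughout the package; GTF input
and output is converted exactly from/to the format's native 1-based closed
convention.  Transcript models carry an ordered exon chain on one strand,
with the TSS defined strand-aware (start of the first exon on ``+``, end of
the last exon on ``-``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "Peak",
    "PeakSet",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_narrowpeak",
    "write_narrowpeak",
    "overlap_pairs",
    "compare_to_reference",
    "promoter_of",
    "gene_tss_map",
    "nearest_tss",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF lines; message carries the 1-based line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    """A transcript as an ordered chain of exons on one strand."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    source: str = "assembled"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: exons span chroms/strands")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first transcribed base)."""
        return self.start if self.strand != "-" else self.end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((a.end, b.start) for a, b in zip(self.exons, self.exons[1:]))


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    summit: int  # absolute genomic coordinate
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"[{self.interval.start}, {self.interval.end})"
            )


@dataclass
class PeakSet:
    """Peak calls for one mark, sorted by (chrom, start)."""

    mark: str
    records: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda p: (p.interval.chrom, p.interval.start)
        )

    def __len__(self) -> int:
        return len(self.records)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.records]

    def tree_by_chrom(self) -> dict[str, IntervalTree]:
        return _build_trees(self.intervals())

    def overlaps(self, query: GenomicInterval) -> bool:
        trees = getattr(self, "_trees", None)
        if trees is None:
            trees = self.tree_by_chrom()
            self._trees = trees
        t = trees.get(query.chrom)
        return bool(t is not None and t.overlap(query.start, query.end))


# ---------------------------------------------------------------------------
# GTF I/O (1-based closed on disk <-> 0-based half-open in memory)
# ---------------------------------------------------------------------------

def read_gtf(path) -> list[TranscriptModel]:
    """Read transcript models (exon features) from a GTF file.

    Raises :class:`GtfParseError` with the offending 1-based line number for
    malformed records.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # malformed column structure
                raise GtfParseError(f"line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            if feat.end < feat.start:
                raise GtfParseError(
                    f"line {lineno}: exon end {feat.end} < start {feat.start}"
                )
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise GtfParseError(f"line {lineno}: missing {exc} attribute") from exc
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            if tid not in exons:
                order.append(tid)
            exons.setdefault(tid, []).append(iv)
            genes[tid] = gid
    return [TranscriptModel(tid, genes[tid], exons[tid]) for tid in order]


def write_gtf(models: list[TranscriptModel], path, source: str = "isletomics") -> None:
    """Write transcript + exon records, sorted by (chrom, start, transcript_id)."""
    models = sorted(models, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with open(path, "w") as fh:
        for t in models:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Peak I/O
# ---------------------------------------------------------------------------

def read_narrowpeak(path, mark: str) -> PeakSet:
    """Read ENCODE narrowPeak (10 columns) or BED6 peak calls.

    The absolute summit is ``start + offset`` for a non-negative column-10
    offset; an offset of ``-1`` (the ENCODE "no summit" convention) and plain
    BED6 input both fall back to the interval midpoint.
    """
    records: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >=6 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            strand = cols[5] if cols[5] in ("+", "-") else "."
            score = float(cols[4]) if cols[4] != "." else 0.0
            iv = GenomicInterval(chrom, start, end, strand)
            offset = int(cols[9]) if len(cols) >= 10 else -1
            if offset >= end - start:
                raise ValueError(
                    f"{path}: line {lineno}: summit offset {offset} >= peak length"
                )
            summit = start + offset if offset >= 0 else start + (end - start) // 2
            records.append(Peak(iv, summit, score))
    return PeakSet(mark, records)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks.records):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.mark}_{i + 1}\t"
                f"{p.score:g}\t{iv.strand}\t0\t-1\t-1\t{p.summit - iv.start}\n"
            )


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def _build_trees(intervals: list[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees


def overlap_pairs(
    a: list[GenomicInterval],
    b: list[GenomicInterval],
    stranded: bool = False,
    min_bp: int = 1,
) -> list[tuple[int, int]]:
    """Index pairs (i, j) whose intervals share >= ``min_bp`` bases.

    Overlap is computed on half-open coordinates, on the same chromosome, and
    additionally on the same strand when ``stranded``.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = _build_trees(b)
    out: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            j = hit.data
            other = b[j]
            if stranded and iv.strand != other.strand:
                continue
            if iv.overlap_bp(other) >= min_bp:
                out.append((i, j))
    return sorted(out)


def compare_to_reference(
    assembled: list[TranscriptModel], reference: list[TranscriptModel]
) -> dict[str, str]:
    """Partition assembled transcripts into ``known`` vs ``unannotated``.

    A transcript is known iff it has any same-strand exonic overlap with a
    reference transcript, or shares an identical intron chain with one.
    Antisense-only overlap does not make a transcript known.
    """
    ref_exons: list[GenomicInterval] = []
    for t in reference:
        ref_exons.extend(t.exons)
    trees = _build_trees(ref_exons)
    chains = {(t.chrom, t.strand, t.intron_chain()) for t in reference if t.intron_chain()}

    result: dict[str, str] = {}
    for t in assembled:
        known = False
        tree = trees.get(t.chrom)
        if tree is not None:
            for e in t.exons:
                for hit in tree.overlap(e.start, e.end):
                    if ref_exons[hit.data].strand == t.strand:
                        known = True
                        break
                if known:
                    break
        if not known and t.intron_chain():
            known = (t.chrom, t.strand, t.intron_chain()) in chains
        result[t.transcript_id] = "known" if known else "unannotated"
    return result


def promoter_of(
    t: TranscriptModel,
    upstream: int = 2000,
    downstream: int = 500,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at chromosome bounds."""
    if upstream < 0 or downstream < 0:
        raise ValueError("promoter extents must be >= 0")
    if t.strand == "-":
        lo, hi = t.end - downstream, t.end + upstream
    else:
        lo, hi = t.start - upstream, t.start + downstream
    lo = max(0, lo)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return GenomicInterval(t.chrom, lo, hi, t.strand)


def gene_tss_map(transcripts: list[TranscriptModel]) -> dict[str, TranscriptModel]:
    """One representative transcript per gene: the longest (spliced), then
    lowest start coordinate, then lexicographic transcript id."""
    best: dict[str, TranscriptModel] = {}
    for t in transcripts:
        cur = best.get(t.gene_id)
        if cur is None:
            best[t.gene_id] = t
            continue
        key = (-t.spliced_length, t.start, t.transcript_id)
        cur_key = (-cur.spliced_length, cur.start, cur.transcript_id)
        if key < cur_key:
            best[t.gene_id] = t
    return best


def nearest_tss(
    position: int,
    chrom: str,
    transcripts: list[TranscriptModel],
) -> tuple[str, int] | None:
    """Gene with the TSS nearest to ``position`` on ``chrom``.

    Returns ``(gene_id, signed distance)`` with distance = position - TSS,
    or None when the chromosome carries no transcript.  Ties are broken by
    lower TSS coordinate, then lexicographic gene id.
    """
    per_gene = gene_tss_map([t for t in transcripts if t.chrom == chrom])
    if not per_gene:
        return None
    best: tuple[int, int, str] | None = None  # (|dist|, tss, gene)
    for t in per_gene.values():
        cand = (abs(position - t.tss), t.tss, t.gene_id)
        if best is None or cand < best:
            best = cand
    return best[2], position - best[1]
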