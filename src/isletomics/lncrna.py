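"""Triage of unannotated transcripts into lncRNAs and related categories.

The decision tree mirrors how novel transcripts from a de novo assembly are
sorted in islet transcriptomics:

1. transcripts with coding potential (longest sense-strand ORF at or above
   ``orf_min`` codons) are checked against the reference transcriptome for
   near-identical sequence: whole-length matches are pseudogene
   duplications, substantial partial matches are partial duplications, and
   the rest are novel coding transcripts;
2. non-coding transcripts longer than 200 nt with an active promoter
   (H3K4me3 + H3K27ac) and expression above the detection threshold are
   lncRNAs — antisense when their exons overlap a reference gene on the
   opposite strand, intergenic otherwise;
3. transcripts whose promoter lacks H3K4me3 but overlaps both H3K4me1 and
   H3K27ac are transcribed enhancer candidates;
4. anything else stays unresolved.

Naming: antisense lncRNAs become ``<PartnerGene>-as<k>`` (k by genomic
start within one partner), intergenic ones ``<prefix>-lnc<n>`` numbered by
descending mean expression so the most prominent transcript is lnc1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .annotation import GenomicInterval, PeakSet, TranscriptModel, overlap_pairs

__all__ = [
    "NoveltyCall",
    "TriageThresholds",
    "longest_orf",
    "coding_potential",
    "DuplicationMatch",
    "detect_duplication",
    "transcript_sequence",
    "classify_novel_transcript",
    "assign_names",
]

CATEGORIES = (
    "known",
    "coding_novel",
    "pseudogene_duplication",
    "partial_duplication",
    "lncRNA_antisense",
    "lncRNA_intergenic",
    "transcribed_enhancer",
    "unresolved",
)

STOPS = {"TAA", "TAG", "TGA"}

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class NoveltyCall:
    transcript_id: str
    category: str
    assigned_name: str | None = None
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class TriageThresholds:
    orf_min: int = 100          # codons; coding-potential proxy
    min_lnc_length: int = 200   # nt, spliced
    tpm_detect: float = 0.5     # detection threshold, mean TPM
    dup_min_identity: float = 0.9
    dup_min_cov: float = 0.5    # query coverage for a full duplication
    dup_partial_cov: float = 0.2


def longest_orf(seq: str) -> int:
    """Longest ATG->stop open reading frame, in codons, over the three
    forward frames of the given sense sequence.  The ATG codon counts; the
    stop does not.  N breaks an ORF (codons containing N neither start,
    extend, nor terminate one)."""
    seq = seq.upper()
    best = 0
    for frame in range(3):
        start = None
        n_codons = 0
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                start, n_codons = None, 0
                continue
            if start is None:
                if codon == "ATG":
                    start, n_codons = i, 1
            else:
                if codon in STOPS:
                    best = max(best, n_codons)
                    start, n_codons = None, 0
                else:
                    n_codons += 1
    return best


def coding_potential(seq: str, orf_min: int = 100) -> bool:
    return longest_orf(seq) >= orf_min


@dataclass
class DuplicationMatch:
    reference_id: str
    identity: float
    coverage: float  # fraction of the query involved in the match


def _kmers(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def detect_duplication(
    seq: str,
    reference_seqs: dict[str, str],
    min_identity: float = 0.9,
    min_cov: float = 0.5,
    partial_cov: float = 0.2,
    k: int = 15,
) -> DuplicationMatch | None:
    """K-mer-seeded sequence match of a query transcript against reference
    transcript sequences (sense strand only; the caller resolves strand from
    the exon model).

    The best candidate reference is the one sharing the most k-mers; the
    matched query span is the densest cluster of shared-k-mer positions
    (isolated stray hits are ignored), its identity is computed by infix
    alignment of that span against the reference, and coverage is the
    span's fraction of the query.  Returns None when nothing reaches
    ``min_identity`` with coverage >= ``partial_cov``.
    """
    seq = seq.upper()
    if len(seq) < k:
        return None
    best: tuple[int, str] | None = None
    hits_by_ref: dict[str, list[int]] = {}
    qmers = _kmers(seq, k)
    for rid, rseq in reference_seqs.items():
        rmers = set()
        rseq = rseq.upper()
        for i in range(len(rseq) - k + 1):
            rmers.add(rseq[i : i + k])
        qhits = sorted(
            pos for kmer, poss in qmers.items() if kmer in rmers for pos in poss
        )
        if qhits:
            hits_by_ref[rid] = qhits
            if best is None or len(qhits) > best[0]:
                best = (len(qhits), rid)
    if best is None:
        return None
    rid = best[1]
    qhits = hits_by_ref[rid]
    # split hit positions into clusters (gap > 100 nt) and keep the densest
    clusters: list[list[int]] = [[qhits[0]]]
    for pos in qhits[1:]:
        if pos - clusters[-1][-1] > 100:
            clusters.append([pos])
        else:
            clusters[-1].append(pos)
    dense = max(clusters, key=len)
    span_lo, span_hi = dense[0], dense[-1] + k
    segment = seq[span_lo:span_hi]
    aln = edlib.align(segment, reference_seqs[rid].upper(), mode="HW", task="distance")
    dist = aln["editDistance"]
    identity = 1.0 - dist / len(segment)
    coverage = len(segment) / len(seq)
    if identity >= min_identity and coverage >= partial_cov:
        return DuplicationMatch(rid, identity, coverage)
    return None


def transcript_sequence(t: TranscriptModel, genome: dict[str, str]) -> str:
    """Spliced sense-strand sequence of a transcript from genome sequence."""
    if t.chrom not in genome:
        raise KeyError(f"{t.transcript_id}: chromosome {t.chrom} absent from genome")
    chrom_seq = genome[t.chrom]
    if t.end > len(chrom_seq):
        raise ValueError(
            f"{t.transcript_id}: coordinates exceed {t.chrom} length {len(chrom_seq)}"
        )
    parts = [chrom_seq[e.start : e.end] for e in t.exons]
    seq = "".join(parts).upper()
    if t.strand == "-":
        seq = seq.translate(_COMP)[::-1]
    return seq


def classify_novel_transcript(
    t: TranscriptModel,
    promoter_state: str,
    promoter: GenomicInterval,
    k4me1: PeakSet,
    k27ac: PeakSet,
    mean_tpm: float,
    reference: list[TranscriptModel],
    reference_seqs: dict[str, str],
    genome: dict[str, str],
    thresholds: TriageThresholds = TriageThresholds(),
) -> NoveltyCall:
    """Run one unannotated transcript through the triage decision tree."""
    seq = transcript_sequence(t, genome)
    orf = longest_orf(seq)
    evidence: dict = {
        "orf_codons": orf,
        "spliced_length": t.spliced_length,
        "promoter_state": promoter_state,
        "mean_tpm": mean_tpm,
    }

    if orf >= thresholds.orf_min:
        match = detect_duplication(
            seq,
            reference_seqs,
            min_identity=thresholds.dup_min_identity,
            min_cov=thresholds.dup_min_cov,
            partial_cov=thresholds.dup_partial_cov,
        )
        if match is not None:
            evidence["duplication_of"] = match.reference_id
            evidence["duplication_identity"] = round(match.identity, 4)
            evidence["duplication_coverage"] = round(match.coverage, 4)
            category = (
                "pseudogene_duplication"
                if match.coverage >= thresholds.dup_min_cov
                else "partial_duplication"
            )
            return NoveltyCall(t.transcript_id, category, evidence=evidence)
        return NoveltyCall(t.transcript_id, "coding_novel", evidence=evidence)

    if (
        t.spliced_length > thresholds.min_lnc_length
        and promoter_state == "active"
        and mean_tpm > thresholds.tpm_detect
    ):
        partner = _antisense_partner(t, reference)
        if partner is not None:
            evidence["antisense_partner"] = partner
            return NoveltyCall(t.transcript_id, "lncRNA_antisense", evidence=evidence)
        return NoveltyCall(t.transcript_id, "lncRNA_intergenic", evidence=evidence)

    # "unmarked" here means the promoter lacks H3K4me3; enhancer chromatin
    # requires both H3K4me1 and H3K27ac over the window.
    if (
        promoter_state == "unmarked"
        and k4me1.overlaps(promoter)
        and k27ac.overlaps(promoter)
    ):
        return NoveltyCall(t.transcript_id, "transcribed_enhancer", evidence=evidence)

    return NoveltyCall(t.transcript_id, "unresolved", evidence=evidence)


def _antisense_partner(
    t: TranscriptModel, reference: list[TranscriptModel]
) -> str | None:
    """Gene id of a reference transcript with opposite-strand exonic overlap,
    preferring the largest overlap, then lowest coordinate."""
    ref_exons: list[GenomicInterval] = []
    owner: list[TranscriptModel] = []
    for r in reference:
        for e in r.exons:
            ref_exons.append(e)
            owner.append(r)
    pairs = overlap_pairs(t.exons, ref_exons, stranded=False)
    best: tuple[int, int, str] | None = None
    for i, j in pairs:
        r = owner[j]
        if r.strand == t.strand or t.strand == "." or r.strand == ".":
            continue
        bp = t.exons[i].overlap_bp(ref_exons[j])
        cand = (-bp, ref_exons[j].start, r.gene_id)
        if best is None or cand < best:
            best = cand
    return best[2] if best else None


def assign_names(
    calls: list[NoveltyCall],
    transcripts: dict[str, TranscriptModel],
    mean_tpm: dict[str, float],
    prefix: str = "Ri",
    intergenic_order: str = "expression",
) -> list[NoveltyCall]:
    """Assign publication-style names to lncRNA calls.

    Antisense: ``<PartnerGene>-as<k>`` with k ordering multiple antisense
    transcripts of one partner by genomic start.  Intergenic:
    ``<prefix>-lnc<n>`` by descending mean expression (``intergenic_order=
    "coordinate"`` switches to genomic order).  Names are unique per run;
    other categories keep their transcript id as the name.
    """
    by_partner: dict[str, list[NoveltyCall]] = {}
    for c in calls:
        if c.category == "lncRNA_antisense":
            partner = c.evidence.get("antisense_partner")
            if partner is None:
                raise ValueError(f"{c.transcript_id}: antisense call without partner")
            by_partner.setdefault(partner, []).append(c)
    for partner, group in sorted(by_partner.items()):
        group.sort(key=lambda c: (transcripts[c.transcript_id].start,
                                  c.transcript_id))
        for i, c in enumerate(group, start=1):
            c.assigned_name = f"{partner}-as{i}"

    intergenic = [c for c in calls if c.category == "lncRNA_intergenic"]
    if intergenic_order == "expression":
        intergenic.sort(
            key=lambda c: (-mean_tpm.get(c.transcript_id, 0.0), c.transcript_id)
        )
    else:
        intergenic.sort(
            key=lambda c: (
                transcripts[c.transcript_id].chrom,
                transcripts[c.transcript_id].start,
                c.transcript_id,
            )
        )
    for i, c in enumerate(intergenic, start=1):
        c.assigned_name = f"{prefix}-lnc{i}"

    seen: set[str] = set()
    for c in calls:
        if c.assigned_name is None:
            c.assigned_name = c.transcript_id
        if c.assigned_name in seen:
            raise ValueError(f"duplicate assigned name {c.assigned_name}")
        seen.add(c.assigned_name)
    return calls
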