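"""lncRNA candidate filter chain.

Candidate transcripts are positioned relative to protein-coding genes
(class codes ``u`` intergenic, ``x`` antisense, ``i`` intronic), then
filtered on spliced length (>= 200 nt), coding potential (score <= 0
kept) and protein-domain evidence, and finally collapsed to the single
longest isoform per locus.  Class codes map to biotypes: u -> lincRNA,
x -> NAT, i -> intronic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import GenomicInterval, PolylncError, TranscriptModel

logger = logging.getLogger(__name__)

CLASS_TO_BIOTYPE = {"u": "lincRNA", "x": "NAT", "i": "intronic"}

MIN_LENGTH_NT = 200          # transcripts shorter than this are discarded
CODING_SCORE_CUTOFF = 0.0    # score > 0 means protein-coding, discarded
ORF_CODON_THRESHOLD = 100    # built-in score: ORFs >= this many codons flag coding


@dataclass(frozen=True)
class CodingEvidence:
    """External coding-potential evidence for one transcript.

    ``coding_score`` follows the convention that positive means coding;
    ``has_domain_hit`` is True when a protein-domain search matched at
    E < 0.001.  A missing record means no evidence.
    """

    transcript_id: str
    coding_score: float
    has_domain_hit: bool = False


def assign_class_code(
    t: TranscriptModel, pcgs: Sequence[TranscriptModel]
) -> str:
    """Position a candidate transcript relative to coding annotation.

    Returns ``u`` (no exonic overlap with any PCG locus span), ``x``
    (exonic overlap with a PCG exon on the opposite strand), ``i``
    (entirely within a single intron of a same-strand PCG) or
    ``sense_overlap`` (anything else touching a PCG in sense; excluded
    downstream).

    Intergenic status is judged against locus spans while antisense
    requires exon-level overlap, mirroring assembler u/x semantics.
    An opposite-strand transcript contained in a single intron is also
    antisense (``x``), not intronic.
    """

    same_chrom = [p for p in pcgs if p.chrom == t.chrom]

    # group PCG transcripts into loci and take union spans
    by_locus: dict[str, list[TranscriptModel]] = {}
    for p in same_chrom:
        by_locus.setdefault(p.locus_id, []).append(p)

    span_overlaps = []
    for locus, txs in by_locus.items():
        span = GenomicInterval(
            t.chrom,
            min(x.interval.start for x in txs),
            max(x.interval.end for x in txs),
            txs[0].strand,
        )
        if any(e.overlaps(span) for e in t.exons):
            span_overlaps.append((locus, txs))
    if not span_overlaps:
        return "u"

    # antisense: candidate exon overlapping a PCG exon on the opposite strand
    for _locus, txs in span_overlaps:
        for p in txs:
            if p.strand != t.strand and any(
                te.overlaps(pe) for te in t.exons for pe in p.exons
            ):
                return "x"

    # intronic: whole candidate inside one intron of a same-strand PCG;
    # antisense-in-intron counts as x
    for _locus, txs in span_overlaps:
        for p in txs:
            for intron in p.introns:
                if intron.contains(t.interval):
                    return "i" if p.strand == t.strand else "x"

    return "sense_overlap"


def builtin_coding_score(sequence: str, orf_codons: int = ORF_CODON_THRESHOLD) -> float:
    """Longest-ORF coding-potential score.

    Positive iff the longest open reading frame across all six frames
    reaches ``orf_codons`` codons; magnitude is the relative excess or
    deficit ``(longest - threshold) / threshold``.  This is a documented
    built-in stand-in for an external coding-potential score.
    """

    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise PolylncError("sequence contains non-ACGTN symbols")
    longest = longest_orf_codons(seq)
    return (longest - orf_codons) / orf_codons


_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def longest_orf_codons(seq: str) -> int:
    """Longest ATG-initiated, stop-terminated ORF (codons incl. ATG,
    excl. stop) over all six reading frames."""

    best = 0
    for s in (seq, seq.translate(_COMP)[::-1]):
        for frame in range(3):
            best = max(best, _longest_in_frame(s, frame))
    return best


def _longest_in_frame(s: str, frame: int) -> int:
    # ORFs running off the sequence end (read-through) count too
    best = 0
    open_at = None
    last = frame
    for i in range(frame, len(s) - 2, 3):
        codon = s[i : i + 3]
        if open_at is None:
            if codon == "ATG":
                open_at = i
        elif codon in _STOPS:
            best = max(best, (i - open_at) // 3)
            open_at = None
        last = i + 3
    if open_at is not None:
        best = max(best, (last - open_at) // 3)
    return best


def filter_lncrna(
    candidates: Sequence[TranscriptModel],
    pcgs: Sequence[TranscriptModel],
    evidence: Mapping[str, CodingEvidence] | None = None,
    min_length: int = MIN_LENGTH_NT,
) -> list[TranscriptModel]:
    """Apply the full lncRNA filter chain and collapse to longest isoform.

    A transcript is kept iff spliced length >= ``min_length``, class code
    in {u, x, i}, coding score <= 0 and no domain hit; transcripts with
    no evidence record are treated as non-coding (logged).  Per locus
    only the longest (spliced length) survivor is retained; its biotype
    is set from the class code.
    """

    evidence = evidence or {}
    survivors: list[TranscriptModel] = []
    for t in candidates:
        if t.spliced_length < min_length:
            continue
        code = assign_class_code(t, pcgs)
        if code not in CLASS_TO_BIOTYPE:
            continue
        ev = evidence.get(t.transcript_id)
        if ev is None:
            logger.debug("no coding evidence for %s; kept as non-coding",
                         t.transcript_id)
        else:
            if ev.coding_score > CODING_SCORE_CUTOFF or ev.has_domain_hit:
                continue
        t.biotype = CLASS_TO_BIOTYPE[code]
        survivors.append(t)

    # longest isoform per locus; deterministic tie-break on transcript_id
    by_locus: dict[str, TranscriptModel] = {}
    for t in survivors:
        cur = by_locus.get(t.locus_id)
        if (
            cur is None
            or t.spliced_length > cur.spliced_length
            or (t.spliced_length == cur.spliced_length
                and t.transcript_id < cur.transcript_id)
        ):
            by_locus[t.locus_id] = t
    return sorted(by_locus.values(), key=lambda t: (t.chrom, t.interval.start))


def score_transcripts(
    transcripts: Iterable[TranscriptModel], genome: Mapping[str, str],
    orf_codons: int = ORF_CODON_THRESHOLD,
) -> dict[str, CodingEvidence]:
    """Score every transcript with the built-in ORF-based score."""

    out = {}
    for t in transcripts:
        seq = "".join(genome[t.chrom][e.start:e.end] for e in t.exons)
        if t.strand == "-":
            seq = seq.translate(_COMP)[::-1]
        out[t.transcript_id] = CodingEvidence(
            t.transcript_id, builtin_coding_score(seq, orf_codons)
        )
    return out
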