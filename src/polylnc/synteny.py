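"""Synteny-block chaining and allelic-expression classification of lncRNA.

Anchor pairs are reciprocal-best coding-gene hits between two (sub)genomes.
Collinear runs of anchors are chained by dynamic programming over gene-rank
space (MCScanX-style), and every lincRNA locus of genome A is then placed
against genome B and labelled:

``ST``
    syntenic and transcribed in both genomes (one-to-one lncRNA homology);
``SA``
    syntenic and allelic-transcribed: the homologous syntenic locus exists
    in B but only A transcribes a lncRNA from it;
``SYN_PCG``
    the syntenic homolog lies in a protein-coding exon of B;
``NON_SYN``
    outside any block, or no homology within the corresponding block span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import GenomicInterval, HomologyHit, TranscriptModel
from .io import best_hit_per_query

logger = logging.getLogger(__name__)

DEFAULT_MAX_EVALUE = 1e-10
DEFAULT_MIN_ANCHORS = 5
DEFAULT_MAX_GAP = 25
EXPRESSED_RPKM = 0.5

SYNTENY_LABELS = ("ST", "SA", "SYN_PCG", "NON_SYN")


@dataclass(frozen=True)
class GeneRank:
    """Rank index of a gene locus along its chromosome."""

    locus_id: str
    chrom: str
    rank: int
    span: GenomicInterval


@dataclass(frozen=True)
class AnchorPair:
    """A reciprocal-best gene pair, indexed by rank in both genomes."""

    gene_a: GeneRank
    gene_b: GeneRank
    score: float


@dataclass
class SyntenyBlock:
    """A chained run of collinear anchors between two chromosomes."""

    block_id: str
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str  # "same" | "inverted"

    @property
    def span_a(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom_a,
            min(a.gene_a.span.start for a in self.anchors),
            max(a.gene_a.span.end for a in self.anchors),
        )

    @property
    def span_b(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom_b,
            min(a.gene_b.span.start for a in self.anchors),
            max(a.gene_b.span.end for a in self.anchors),
        )


@dataclass(frozen=True)
class SyntenyCall:
    """The ST/SA/SYN_PCG/NON_SYN label for one lncRNA locus."""

    lnc_locus_id: str
    label: str
    partner_locus_id: str | None = None
    block_id: str | None = None


def gene_ranks(pcgs: Sequence[TranscriptModel]) -> dict[str, GeneRank]:
    """Rank PCG loci along each chromosome by locus-span start."""

    by_locus: dict[str, list[TranscriptModel]] = {}
    for t in pcgs:
        by_locus.setdefault(t.locus_id, []).append(t)
    spans = {
        locus: GenomicInterval(
            txs[0].chrom,
            min(t.interval.start for t in txs),
            max(t.interval.end for t in txs),
        )
        for locus, txs in by_locus.items()
    }
    out: dict[str, GeneRank] = {}
    by_chrom: dict[str, list[str]] = {}
    for locus, span in spans.items():
        by_chrom.setdefault(span.chrom, []).append(locus)
    for chrom, loci in by_chrom.items():
        loci.sort(key=lambda l: (spans[l].start, l))
        for rank, locus in enumerate(loci):
            out[locus] = GeneRank(locus, chrom, rank, spans[locus])
    return out


def reciprocal_best_pairs(
    hits_ab: Sequence[HomologyHit],
    hits_ba: Sequence[HomologyHit],
    ranks_a: Mapping[str, GeneRank],
    ranks_b: Mapping[str, GeneRank],
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[AnchorPair]:
    """Reciprocal-best anchor pairs at E below ``max_evalue`` both ways."""

    hits_ab = [h for h in hits_ab if h.evalue < max_evalue]
    hits_ba = [h for h in hits_ba if h.evalue < max_evalue]
    best_ab = best_hit_per_query(hits_ab)
    best_ba = best_hit_per_query(hits_ba)
    pairs = []
    for a_id, hab in sorted(best_ab.items()):
        b_id = hab.subject_id
        hba = best_ba.get(b_id)
        if hba is None or hba.subject_id != a_id:
            continue
        if a_id not in ranks_a or b_id not in ranks_b:
            continue
        pairs.append(
            AnchorPair(ranks_a[a_id], ranks_b[b_id],
                       score=min(hab.bitscore, hba.bitscore))
        )
    return pairs


def _best_chain(pairs: list[AnchorPair], max_gap: int, sign: int):
    """Max-weight monotone chain (weight = summed anchor scores) by DP.

    ``sign`` +1 requires rank_b increasing, -1 decreasing.  Ties resolve
    to the chain whose anchor index sequence is lexicographically
    smallest after sorting pairs by (rank_a, rank_b).
    """

    order = sorted(range(len(pairs)),
                   key=lambda i: (pairs[i].gene_a.rank, pairs[i].gene_b.rank))
    n = len(order)
    weight = [pairs[order[i]].score for i in range(n)]
    best_w = list(weight)
    prev = [-1] * n
    for i in range(n):
        pi = pairs[order[i]]
        for j in range(i):
            pj = pairs[order[j]]
            da = pi.gene_a.rank - pj.gene_a.rank
            db = (pi.gene_b.rank - pj.gene_b.rank) * sign
            if 0 < da <= max_gap and 0 < db <= max_gap:
                cand = best_w[j] + weight[i]
                if cand > best_w[i]:
                    best_w[i] = cand
                    prev[i] = j
    if not n:
        return 0.0, []
    end = max(range(n), key=lambda i: (best_w[i], -i))
    chain = []
    i = end
    while i != -1:
        chain.append(order[i])
        i = prev[i]
    chain.reverse()
    return best_w[end], [pairs[i] for i in chain]


def chain_collinear_blocks(
    pairs: Sequence[AnchorPair],
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[SyntenyBlock]:
    """Chain anchors into maximal-scoring collinear blocks.

    Chains extend i -> j iff 0 < delta rank_A <= max_gap and
    0 < |delta rank_B| <= max_gap with consistent sign.  Blocks are
    extracted best-chain-first; each anchor belongs to at most one
    block; chains shorter than ``min_anchors`` are dropped.  Duplicate
    (gene_a, gene_b) pairs are collapsed with a warning.
    """

    seen = set()
    uniq: list[AnchorPair] = []
    for p in pairs:
        key = (p.gene_a.locus_id, p.gene_b.locus_id)
        if key in seen:
            logger.warning("duplicate anchor pair %s collapsed", key)
            continue
        seen.add(key)
        uniq.append(p)

    by_chrom: dict[tuple[str, str], list[AnchorPair]] = {}
    for p in uniq:
        by_chrom.setdefault((p.gene_a.chrom, p.gene_b.chrom), []).append(p)

    blocks: list[SyntenyBlock] = []
    for (ca, cb) in sorted(by_chrom):
        pool = by_chrom[(ca, cb)]
        while True:
            w_fwd, c_fwd = _best_chain(pool, max_gap, +1)
            w_rev, c_rev = _best_chain(pool, max_gap, -1)
            if w_fwd >= w_rev:
                chain, orientation = c_fwd, "same"
            else:
                chain, orientation = c_rev, "inverted"
            if len(chain) < min_anchors:
                break
            bid = f"block{len(blocks) + 1}"
            blocks.append(SyntenyBlock(bid, ca, cb, chain, orientation))
            used = {(p.gene_a.locus_id, p.gene_b.locus_id) for p in chain}
            pool = [p for p in pool
                    if (p.gene_a.locus_id, p.gene_b.locus_id) not in used]
    return blocks


def corresponding_span(
    block: SyntenyBlock, pos_a: int, pad: int = 5000
) -> GenomicInterval:
    """Map a genome-A position inside a block to its expected B span.

    Linear interpolation between the midpoints of the flanking anchors,
    padded by ``pad`` bp on each side (coordinate transfer within a
    block is approximate by construction).
    """

    anchors = sorted(block.anchors, key=lambda p: p.gene_a.span.start)
    mids_a = [(p.gene_a.span.start + p.gene_a.span.end) // 2 for p in anchors]
    mids_b = [(p.gene_b.span.start + p.gene_b.span.end) // 2 for p in anchors]
    if pos_a <= mids_a[0]:
        lo, hi = 0, 1 if len(anchors) > 1 else 0
    elif pos_a >= mids_a[-1]:
        lo, hi = len(anchors) - 2 if len(anchors) > 1 else 0, len(anchors) - 1
    else:
        lo = max(i for i in range(len(anchors)) if mids_a[i] <= pos_a)
        hi = lo + 1
    if lo == hi:
        center = mids_b[lo]
    else:
        a0, a1 = mids_a[lo], mids_a[hi]
        b0, b1 = mids_b[lo], mids_b[hi]
        frac = 0.5 if a1 == a0 else (pos_a - a0) / (a1 - a0)
        center = b0 + frac * (b1 - b0)
    left = min(mids_b[lo], mids_b[hi], int(center)) - pad
    right = max(mids_b[lo], mids_b[hi], int(center)) + pad
    return GenomicInterval(block.chrom_b, max(0, left), right)


def _locus_spans(transcripts: Sequence[TranscriptModel]) -> dict[str, GenomicInterval]:
    by_locus: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_locus.setdefault(t.locus_id, []).append(t)
    return {
        locus: GenomicInterval(
            txs[0].chrom,
            min(t.interval.start for t in txs),
            max(t.interval.end for t in txs),
            txs[0].strand,
        )
        for locus, txs in by_locus.items()
    }


def place_lncrna(
    lnc_a: Sequence[TranscriptModel],
    blocks: Sequence[SyntenyBlock],
    lnc_hits_a_to_b: Sequence[HomologyHit],
    lnc_b: Sequence[TranscriptModel],
    pcg_b: Sequence[TranscriptModel],
    expressed_b: set[str],
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[SyntenyCall]:
    """Label every genome-A lincRNA locus as ST/SA/SYN_PCG/NON_SYN.

    ``lnc_hits_a_to_b`` are hits of A-lncRNA locus sequences (query id =
    locus id) against genome B.  ``expressed_b`` holds B lncRNA locus ids
    considered transcribed (RPKM > 0.5 in at least one sample).
    """

    spans_a = _locus_spans(lnc_a)
    spans_b = _locus_spans(lnc_b)
    hits_by_query: dict[str, list[HomologyHit]] = {}
    for h in lnc_hits_a_to_b:
        if h.evalue < max_evalue:
            hits_by_query.setdefault(h.query_id, []).append(h)

    calls = []
    for locus in sorted(spans_a):
        span = spans_a[locus]
        mid = (span.start + span.end) // 2
        block = next(
            (b for b in blocks
             if b.chrom_a == span.chrom
             and b.span_a.start <= mid < b.span_a.end),
            None,
        )
        if block is None:
            calls.append(SyntenyCall(locus, "NON_SYN"))
            continue
        target = corresponding_span(block, mid)
        in_span = [
            h for h in hits_by_query.get(locus, [])
            if h.subject_id == target.chrom
            and h.subject_interval.overlaps(target)
        ]
        if not in_span:
            calls.append(SyntenyCall(locus, "NON_SYN", block_id=block.block_id))
            continue
        best = max(in_span, key=lambda h: (h.bitscore, -h.evalue,
                                           -h.subject_interval.start))
        hit_iv = best.subject_interval

        partner = next(
            (lb for lb, sb in sorted(spans_b.items())
             if lb in expressed_b and hit_iv.overlaps(sb)),
            None,
        )
        if partner is not None:
            calls.append(
                SyntenyCall(locus, "ST", partner_locus_id=partner,
                            block_id=block.block_id)
            )
            continue
        pcg_hit = next(
            (p.locus_id for p in pcg_b
             if any(hit_iv.overlaps(e) for e in p.exons)),
            None,
        )
        if pcg_hit is not None:
            calls.append(
                SyntenyCall(locus, "SYN_PCG", partner_locus_id=pcg_hit,
                            block_id=block.block_id)
            )
            continue
        calls.append(SyntenyCall(locus, "SA", block_id=block.block_id))
    return calls


def homology_presence(
    locus_ids: Sequence[str],
    hit_tables: Mapping[str, Sequence[HomologyHit]],
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> dict[str, frozenset[str]]:
    """Per locus, the subset of target genomes with >= 1 qualifying hit.

    Every profile includes the locus' own genome under the name
    ``self``; a locus with no hits anywhere has the singleton profile.
    """

    profiles: dict[str, set[str]] = {l: {"self"} for l in locus_ids}
    for genome, hits in hit_tables.items():
        for h in hits:
            if h.evalue < max_evalue and h.query_id in profiles:
                profiles[h.query_id].add(genome)
    return {l: frozenset(s) for l, s in profiles.items()}


def presence_summary(profiles: Mapping[str, frozenset[str]]) -> dict[frozenset, int]:
    out: dict[frozenset, int] = {}
    for prof in profiles.values():
        out[prof] = out.get(prof, 0) + 1
    return out


def sa_fraction(calls: Sequence[SyntenyCall]) -> float | None:
    """Fraction of SA among syntenic homologous (ST + SA) lncRNA loci.

    Returns ``None`` when no locus is ST or SA (undefined).
    """

    n_sa = sum(1 for c in calls if c.label == "SA")
    n_st = sum(1 for c in calls if c.label == "ST")
    if n_sa + n_st == 0:
        return None
    return n_sa / (n_sa + n_st)
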