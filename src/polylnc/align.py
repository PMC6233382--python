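"""Naive exact-seed, ungapped homology search for synthetic sequences.

This is NOT a general aligner: it exists so that synteny and homology
stages can be exercised end-to-end on simulated genomes, where sequence
divergence is pure substitution (no indels) and every true homology
therefore lies on a single alignment diagonal.  Hits are reported in the
standard 12-column form (:class:`polylnc.core.HomologyHit`).
"""

from __future__ import annotations

import math
from collections import defaultdict

from .core import GenomicInterval, HomologyHit

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _index_kmers(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            idx[kmer].append(i)
    return idx


def _score(matches: int, mismatches: int) -> float:
    # blastn-like scoring: +2 match, -3 mismatch, in bits
    return max(0.0, 2.0 * matches - 3.0 * mismatches)


class SeedMatcher:
    """Exact k-mer seed matcher against a dict of subject sequences."""

    def __init__(self, subjects: dict[str, str], k: int = 13):
        self.k = k
        self.subjects = subjects
        self.index: dict[str, dict[str, list[int]]] = {
            name: _index_kmers(seq, k) for name, seq in subjects.items()
        }

    def search(self, query_id: str, query: str, min_bitscore: float = 50.0,
               max_evalue: float = 1e-10) -> list[HomologyHit]:
        """Search both strands of ``query``; report per-diagonal ungapped hits."""

        hits: list[HomologyHit] = []
        total_subject = sum(len(s) for s in self.subjects.values())
        for strand, qseq in (("+", query), ("-", revcomp(query))):
            for sname, sidx in self.index.items():
                sseq = self.subjects[sname]
                # collect seed matches keyed by diagonal (spos - qpos)
                diags: dict[int, list[int]] = defaultdict(list)
                for qpos in range(len(qseq) - self.k + 1):
                    kmer = qseq[qpos : qpos + self.k]
                    for spos in sidx.get(kmer, ()):
                        diags[spos - qpos].append(qpos)
                for diag, qposes in diags.items():
                    q0, q1 = min(qposes), max(qposes) + self.k
                    # extend outwards while identity stays high
                    q0, q1 = self._trim_extend(qseq, sseq, diag, q0, q1)
                    sub = sseq[q0 + diag : q1 + diag]
                    qsub = qseq[q0:q1]
                    matches = sum(a == b for a, b in zip(qsub, sub))
                    mismatches = len(qsub) - matches
                    bitscore = _score(matches, mismatches)
                    if bitscore < min_bitscore:
                        continue
                    evalue = len(query) * total_subject * math.pow(2.0, -bitscore)
                    if evalue > max_evalue:
                        continue
                    if strand == "+":
                        q_iv = GenomicInterval(query_id, q0, q1, "+")
                    else:
                        # map back to forward-strand query coordinates
                        q_iv = GenomicInterval(
                            query_id, len(query) - q1, len(query) - q0, "+"
                        )
                    s_iv = GenomicInterval(sname, q0 + diag, q1 + diag, strand)
                    hits.append(
                        HomologyHit(
                            query_id=query_id,
                            subject_id=sname,
                            query_interval=q_iv,
                            subject_interval=s_iv,
                            percent_identity=100.0 * matches / len(qsub),
                            evalue=evalue,
                            bitscore=bitscore,
                        )
                    )
        hits.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id,
                                 h.subject_interval.start))
        return self._dedupe(hits)

    def _trim_extend(self, qseq: str, sseq: str, diag: int, q0: int, q1: int,
                     x_drop: float = 18.0):
        """X-drop ungapped extension through isolated mismatches."""

        # leftwards
        score = best = 0.0
        best_q0 = q0
        i = q0 - 1
        while i >= 0 and i + diag >= 0:
            score += 2.0 if qseq[i] == sseq[i + diag] else -3.0
            if score > best:
                best, best_q0 = score, i
            if best - score > x_drop:
                break
            i -= 1
        # rightwards
        score = best = 0.0
        best_q1 = q1
        i = q1
        while i < len(qseq) and i + diag < len(sseq):
            score += 2.0 if qseq[i] == sseq[i + diag] else -3.0
            if score > best:
                best, best_q1 = score, i + 1
            if best - score > x_drop:
                break
            i += 1
        return best_q0, best_q1

    @staticmethod
    def _dedupe(hits: list[HomologyHit]) -> list[HomologyHit]:
        seen = set()
        out = []
        for h in hits:
            key = (h.subject_id, h.subject_interval.start, h.subject_interval.end,
                   h.subject_interval.strand)
            if key not in seen:
                seen.add(key)
                out.append(h)
        return out


def all_vs_genome(queries: dict[str, str], genome: dict[str, str],
                  k: int = 13, max_evalue: float = 1e-10) -> list[HomologyHit]:
    """Search every query against a genome; convenience wrapper."""

    matcher = SeedMatcher(genome, k=k)
    hits: list[HomologyHit] = []
    for qid, qseq in queries.items():
        hits.extend(matcher.search(qid, qseq, max_evalue=max_evalue))
    return hits
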