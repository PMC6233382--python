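"""Core genomic data model shared by every pipeline stage.

All coordinates are internally 0-based, half-open ``[start, end)``.
Conversion to/from the 1-based closed convention of GTF/GFF3 and the
0-based half-open convention of BED happens only at the I/O boundary
(:mod:`polylnc.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

#: Fixed vocabulary of transposable-element superfamilies.
TE_FAMILIES = ("Gypsy", "Copia", "LTR_other", "LINE", "SINE", "DNA", "unknown", "other")

#: Cytosine sequence contexts (H = A, C or T).
METH_CONTEXTS = ("CG", "CHG", "CHH")

#: Transcript biotypes after lncRNA classification.
BIOTYPES = ("PCG", "lncRNA_candidate", "lincRNA", "NAT", "intronic", "excluded")


class PolylncError(ValueError):
    """Base error for malformed inputs and contract violations."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome / scaffold name; must be non-empty.
    start, end : int
        0-based half-open bounds with ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise PolylncError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise PolylncError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise PolylncError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """An exon-structured transcript, the unit classified as lncRNA.

    ``exons`` are sorted, pairwise disjoint and contained in ``interval``;
    the spliced length is the sum of exon lengths.  ``locus_id`` groups
    isoforms of the same locus.
    """

    transcript_id: str
    locus_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "lncRNA_candidate"

    def __post_init__(self):
        if self.interval.strand == ".":
            raise PolylncError(
                f"transcript {self.transcript_id}: strand is required"
            )
        if not self.exons:
            self.exons = [self.interval]
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for e in self.exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise PolylncError(
                    f"transcript {self.transcript_id}: exon on wrong chrom/strand"
                )
            if not self.interval.contains(e):
                raise PolylncError(
                    f"transcript {self.transcript_id}: exon {e} outside span "
                    f"{self.interval}"
                )
            if prev_end is not None and e.start < prev_end:
                raise PolylncError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = e.end
        if self.biotype not in BIOTYPES:
            raise PolylncError(f"unknown biotype {self.biotype!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.chrom, a.end, b.start, self.strand)
                )
        return out


@dataclass(frozen=True)
class TEFeature:
    """An annotated transposable-element fragment with its superfamily."""

    interval: GenomicInterval
    family: str
    te_id: str

    def __post_init__(self):
        if self.family not in TE_FAMILIES:
            raise PolylncError(
                f"TE family {self.family!r} not in {TE_FAMILIES}"
            )

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class CytosineRecord:
    """Per-cytosine bisulfite counts (0-based position)."""

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_total: int

    def __post_init__(self):
        if self.context not in METH_CONTEXTS:
            raise PolylncError(f"unknown methylation context {self.context!r}")
        if not (0 <= self.n_meth <= self.n_total):
            raise PolylncError(
                f"invalid counts meth={self.n_meth} total={self.n_total}"
            )


@dataclass(frozen=True)
class HomologyHit:
    """One local-alignment hit between a query sequence and a subject genome."""

    query_id: str
    subject_id: str
    query_interval: GenomicInterval
    subject_interval: GenomicInterval
    percent_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not (0.0 <= self.percent_identity <= 100.0):
            raise PolylncError(
                f"percent identity {self.percent_identity} out of [0, 100]"
            )
        if self.evalue < 0:
            raise PolylncError("negative E-value")


class CountMatrix:
    """Locus x sample matrix of read counts with per-sample library sizes.

    Library sizes are total mapped reads per library and may exceed the
    column sums (reads assigned to no locus exist).
    """

    def __init__(self, counts: pd.DataFrame, library_sizes: pd.Series):
        counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise PolylncError("negative counts")
        library_sizes = library_sizes.astype(np.int64).reindex(counts.columns)
        if library_sizes.isna().any() or (library_sizes <= 0).any():
            raise PolylncError("library sizes must be positive for every sample")
        self.counts = counts
        self.library_sizes = library_sizes

    @property
    def locus_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.library_sizes[list(samples)])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.library_sizes.equals(other.library_sizes)
        )


def group_loci(transcripts: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Assign ``locus_id`` to transcripts lacking one.

    Transcripts that already carry a locus (gene) identifier keep it.
    Among the remainder, transcripts with same-strand exonic overlap are
    merged into one locus via union-find; singleton transcripts become
    their own locus.
    """

    transcripts = list(transcripts)
    anon = [t for t in transcripts if not t.locus_id]
    if not anon:
        return transcripts
    parent = list(range(len(anon)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    by_key: dict[tuple, list[int]] = {}
    for i, t in enumerate(anon):
        by_key.setdefault((t.chrom, t.strand), []).append(i)
    for idxs in by_key.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                ta, tb = anon[idxs[ai]], anon[idxs[bi]]
                if any(ea.overlaps(eb) for ea in ta.exons for eb in tb.exons):
                    union(idxs[ai], idxs[bi])
    roots: dict[int, str] = {}
    for i, t in enumerate(anon):
        r = find(i)
        if r not in roots:
            roots[r] = f"LOC_{anon[r].chrom}_{anon[r].interval.start}"
        t.locus_id = roots[r]
    return transcripts


def locus_span(transcripts: Sequence[TranscriptModel]) -> GenomicInterval:
    """Union span of a group of same-locus transcripts."""

    chrom = transcripts[0].chrom
    strand = transcripts[0].strand
    return GenomicInterval(
        chrom,
        min(t.interval.start for t in transcripts),
        max(t.interval.end for t in transcripts),
        strand,
    )
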