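"""Transposable-element overlap attribution and family enrichment.

Each lncRNA/PCG locus is decomposed into four feature regions (upstream
2 kb, exons, introns, downstream 2 kb).  TEs overlapping a region by at
least 1 bp compete for the assignment; the longest TE fragment wins
(ties: leftmost start, then te_id).  Family enrichment between ST and SA
lncRNA classes uses a two-sided Fisher exact test per family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, TEFeature, TranscriptModel

REGION_KINDS = ("upstream2k", "exon", "intron", "downstream2k")
DEFAULT_FLANK = 2000


@dataclass
class FeatureRegionSet:
    """The four per-locus regions TEs are attributed to."""

    locus_id: str
    chrom: str
    strand: str
    regions: dict[str, list[GenomicInterval]]


@dataclass(frozen=True)
class TEOverlapAssignment:
    """The single TE family attributed to one (locus, region kind)."""

    locus_id: str
    region_kind: str
    family: str
    te_id: str
    overlap_bp: int


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher-exact comparison of one TE family between ST and SA loci."""

    family: str
    n_st_with: int
    n_st_without: int
    n_sa_with: int
    n_sa_without: int
    log2_ratio: float
    fisher_p: float
    q_value: float = float("nan")


def decompose_regions(
    locus: TranscriptModel,
    flank: int = DEFAULT_FLANK,
    chrom_length: int | None = None,
) -> FeatureRegionSet:
    """Split a locus into upstream/exon/intron/downstream regions.

    Flanks are strand-aware (upstream is the 5' side) and clipped at
    chromosome ends; introns are the locus span minus the exons.
    """

    iv = locus.interval
    end_cap = chrom_length if chrom_length is not None else None

    def clipped(start: int, end: int) -> list[GenomicInterval]:
        start = max(0, start)
        if end_cap is not None:
            end = min(end, end_cap)
        if start >= end:
            return []
        return [GenomicInterval(iv.chrom, start, end, iv.strand)]

    left = clipped(iv.start - flank, iv.start)
    right = clipped(iv.end, iv.end + flank)
    if locus.strand == "+":
        upstream, downstream = left, right
    else:
        upstream, downstream = right, left
    return FeatureRegionSet(
        locus_id=locus.locus_id,
        chrom=iv.chrom,
        strand=iv.strand,
        regions={
            "upstream2k": upstream,
            "exon": list(locus.exons),
            "intron": locus.introns,
            "downstream2k": downstream,
        },
    )


def assign_te(
    regions: FeatureRegionSet, tes: Sequence[TEFeature]
) -> list[TEOverlapAssignment]:
    """Attribute at most one TE per region kind by the longest-TE rule.

    Among TEs overlapping the region by >= 1 bp the TE of greatest
    annotated fragment length is assigned; ties break by leftmost start,
    then lexicographic te_id.
    """

    out = []
    for kind in REGION_KINDS:
        ivs = regions.regions.get(kind, [])
        if not ivs:
            continue
        best = None
        best_overlap = 0
        for te in tes:
            if te.interval.chrom != regions.chrom:
                continue
            ov = sum(te.interval.overlap_bp(iv) for iv in ivs)
            if ov < 1:
                continue
            if best is None or _te_rank(te) < _te_rank(best):
                best, best_overlap = te, ov
        if best is not None:
            out.append(
                TEOverlapAssignment(
                    locus_id=regions.locus_id,
                    region_kind=kind,
                    family=best.family,
                    te_id=best.te_id,
                    overlap_bp=best_overlap,
                )
            )
    return out


def _te_rank(te: TEFeature):
    # sort key implementing: longest first, then leftmost, then te_id
    return (-len(te.interval), te.interval.start, te.te_id)


def assign_te_all(
    loci: Iterable[TranscriptModel],
    tes: Sequence[TEFeature],
    flank: int = DEFAULT_FLANK,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[TEOverlapAssignment]:
    """Decompose and assign for a set of loci (one isoform per locus)."""

    by_chrom: dict[str, list[TEFeature]] = {}
    for te in tes:
        by_chrom.setdefault(te.interval.chrom, []).append(te)
    out = []
    for locus in loci:
        cl = chrom_lengths.get(locus.chrom) if chrom_lengths else None
        regs = decompose_regions(locus, flank=flank, chrom_length=cl)
        out.extend(assign_te(regs, by_chrom.get(locus.chrom, [])))
    return out


def te_composition(
    assignments: Sequence[TEOverlapAssignment],
    by: str | None = None,
) -> pd.DataFrame:
    """Per region kind, the proportion of assigned loci per TE family.

    Proportions sum to 1 over the loci assigned in that region kind.
    Returns an empty frame for empty input.
    """

    if not assignments:
        return pd.DataFrame(columns=["region_kind", "family", "n", "proportion"])
    rows = pd.DataFrame(
        {
            "region_kind": [a.region_kind for a in assignments],
            "family": [a.family for a in assignments],
        }
    )
    if by is not None:
        rows = rows[rows["region_kind"] == by]
    counts = (
        rows.groupby(["region_kind", "family"]).size().rename("n").reset_index()
    )
    totals = counts.groupby("region_kind")["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals
    return counts


def family_enrichment(
    st_ids: set[str],
    sa_ids: set[str],
    assignments: Sequence[TEOverlapAssignment],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Per-family 2x2 Fisher exact comparison between ST and SA loci.

    A locus "has" a family when any of its region assignments carries
    that family.  The effect size is log2 of the ratio of within-class
    proportions with a pseudo-proportion guard eps = 0.5 / n_class.
    Families absent from both classes are skipped.  Benjamini-Hochberg
    q-values are reported alongside raw p.
    """

    if st_ids & sa_ids:
        raise ValueError("ST and SA id sets must be disjoint")
    fam_by_locus: dict[str, set[str]] = {}
    for a in assignments:
        fam_by_locus.setdefault(a.locus_id, set()).add(a.family)
    families = sorted({f for fams in fam_by_locus.values() for f in fams})

    results = []
    n_st, n_sa = len(st_ids), len(sa_ids)
    for fam in families:
        st_with = sum(1 for l in st_ids if fam in fam_by_locus.get(l, ()))
        sa_with = sum(1 for l in sa_ids if fam in fam_by_locus.get(l, ()))
        if st_with == 0 and sa_with == 0:
            continue
        table = [[st_with, n_st - st_with], [sa_with, n_sa - sa_with]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        eps_st = 0.5 / n_st if n_st else 0.5
        eps_sa = 0.5 / n_sa if n_sa else 0.5
        p_st = st_with / n_st if n_st else 0.0
        p_sa = sa_with / n_sa if n_sa else 0.0
        log2_ratio = math.log2((p_st + eps_st) / (p_sa + eps_sa))
        results.append(
            EnrichmentResult(fam, st_with, n_st - st_with, sa_with,
                             n_sa - sa_with, log2_ratio, float(p))
        )
    if results:
        qs = multipletests([r.fisher_p for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(r.family, r.n_st_with, r.n_st_without,
                             r.n_sa_with, r.n_sa_without, r.log2_ratio,
                             r.fisher_p, float(q))
            for r, q in zip(results, qs)
        ]
    return results
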