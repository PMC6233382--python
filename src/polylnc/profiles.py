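"""Methylation levels, coverage metaprofiles, DMR calling and association.

Weighted methylation of an interval is the coverage-weighted estimator
sum(meth) / sum(total) over cytosines of one context — not the mean of
per-cytosine ratios.  Metaprofiles scale feature bodies to a fixed
number of bins with fixed-width flank bins, strand-aware.  The DMR
caller is a sliding-window Fisher exact test; externally called DMRs can
be imported instead (TSV: chrom, start, end, context, direction, delta, p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CytosineRecord,
    GenomicInterval,
    METH_CONTEXTS,
    PolylncError,
)

SRNA_MIN_NT = 20
SRNA_MAX_NT = 25
SRNA_MAX_LOCI = 50

DMR_WINDOW = 100
DMR_STEP = 50
DMR_MIN_CYT = 4
DMR_ALPHA = 0.01
DMR_MIN_DELTA = 0.1

ASSOC_FLANK = 2000


@dataclass(frozen=True)
class SrnaRead:
    """A mapped small-RNA read with its multi-mapping multiplicity."""

    interval: GenomicInterval
    length: int
    n_mapped_loci: int = 1
    read_id: str = ""


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region, sample B relative to A."""

    interval: GenomicInterval
    context: str
    direction: str  # "hyper" | "hypo"
    delta: float    # level_B - level_A
    p_value: float

    def __post_init__(self):
        if self.context not in METH_CONTEXTS:
            raise PolylncError(f"unknown context {self.context!r}")
        if self.direction not in ("hyper", "hypo"):
            raise PolylncError(f"unknown direction {self.direction!r}")
        if self.delta != 0 and (self.delta > 0) != (self.direction == "hyper"):
            raise PolylncError("direction does not match delta sign")


@dataclass
class MetaProfile:
    """Mean signal across features over flank + scaled body + flank bins."""

    label: str
    track_label: str
    flank_bins: int
    body_bins: int
    values: np.ndarray  # masked bins are NaN
    n_features: int

    @property
    def body_values(self) -> np.ndarray:
        return self.values[self.flank_bins : self.flank_bins + self.body_bins]

    @property
    def upstream_values(self) -> np.ndarray:
        return self.values[: self.flank_bins]

    @property
    def downstream_values(self) -> np.ndarray:
        return self.values[self.flank_bins + self.body_bins :]


def filter_srna(
    reads: Iterable[SrnaRead],
    blacklist_ids: set[str] | None = None,
    min_nt: int = SRNA_MIN_NT,
    max_nt: int = SRNA_MAX_NT,
    max_loci: int = SRNA_MAX_LOCI,
) -> list[SrnaRead]:
    """siRNA selection: keep 20-25 nt reads mapping to <= 50 loci.

    ``blacklist_ids`` optionally removes reads annotated to structural
    RNA classes (miRNA/tRNA/rRNA/snoRNA) by read id.
    """

    blacklist_ids = blacklist_ids or set()
    return [
        r for r in reads
        if min_nt <= r.length <= max_nt
        and r.n_mapped_loci <= max_loci
        and r.read_id not in blacklist_ids
    ]


class MethylationTrack:
    """Indexed per-cytosine counts supporting fast interval aggregation."""

    def __init__(self, records: Sequence[CytosineRecord] = ()):
        data: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
        for r in records:
            data.setdefault((r.chrom, r.context), []).append(
                (r.pos, r.n_meth, r.n_total)
            )
        self._idx: dict[tuple[str, str], tuple[np.ndarray, ...]] = {}
        for key, rows in data.items():
            rows.sort()
            pos = np.array([p for p, _, _ in rows], dtype=np.int64)
            meth = np.array([m for _, m, _ in rows], dtype=np.int64)
            total = np.array([t for _, _, t in rows], dtype=np.int64)
            self._idx[key] = (pos, np.cumsum(meth), np.cumsum(total))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MethylationTrack":
        """Build from a columnar per-cytosine table (chrom, pos, context,
        n_meth, n_total), e.g. a simulated methylome."""

        track = cls()
        for (chrom, context), grp in frame.groupby(["chrom", "context"],
                                                   sort=True):
            grp = grp.sort_values("pos")
            pos = grp["pos"].to_numpy(np.int64)
            track._idx[(chrom, context)] = (
                pos,
                np.cumsum(grp["n_meth"].to_numpy(np.int64)),
                np.cumsum(grp["n_total"].to_numpy(np.int64)),
            )
        return track

    def counts(self, chrom: str, start: int, end: int, context: str):
        """(sum meth, sum total) over cytosines of ``context`` in [start, end)."""

        key = (chrom, context)
        if key not in self._idx:
            return 0, 0
        pos, cmeth, ctot = self._idx[key]
        lo = np.searchsorted(pos, start, "left")
        hi = np.searchsorted(pos, end, "left")
        if hi <= lo:
            return 0, 0
        m = cmeth[hi - 1] - (cmeth[lo - 1] if lo else 0)
        t = ctot[hi - 1] - (ctot[lo - 1] if lo else 0)
        return int(m), int(t)

    def level(self, chrom: str, start: int, end: int, context: str) -> float:
        """Weighted methylation level; NaN when no covered cytosine."""

        m, t = self.counts(chrom, start, end, context)
        return m / t if t > 0 else float("nan")

    def accessor(self, context: str) -> Callable[[str, int, int], float]:
        return lambda chrom, s, e: self.level(chrom, s, e, context)

    def positions(self, chrom: str, context: str) -> np.ndarray:
        key = (chrom, context)
        return self._idx[key][0] if key in self._idx else np.empty(0, np.int64)

    def chroms(self) -> set[str]:
        return {c for c, _ in self._idx}


def weighted_methylation(
    records_or_track, interval: GenomicInterval, context: str
) -> float:
    """Sum(meth)/sum(total) over one context within an interval (NaN if
    uncovered)."""

    track = (
        records_or_track
        if isinstance(records_or_track, MethylationTrack)
        else MethylationTrack(records_or_track)
    )
    return track.level(interval.chrom, interval.start, interval.end, context)


class CoverageTrack:
    """Per-bp read depth from intervals, optionally weighted.

    Multi-mapped sRNA reads should be weighted ``1 / n_mapped_loci``.
    """

    def __init__(
        self,
        intervals: Sequence[GenomicInterval],
        weights: Sequence[float] | None = None,
        chrom_lengths: Mapping[str, int] | None = None,
    ):
        if weights is None:
            weights = np.ones(len(intervals))
        lengths: dict[str, int] = dict(chrom_lengths or {})
        for iv in intervals:
            lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
        self._depth: dict[str, np.ndarray] = {
            c: np.zeros(l + 1) for c, l in lengths.items()
        }
        for iv, w in zip(intervals, weights):
            d = self._depth[iv.chrom]
            d[iv.start] += w
            d[iv.end] -= w
        self._depth = {c: np.cumsum(d)[:-1] for c, d in self._depth.items()}

    def value(self, chrom: str, start: int, end: int) -> float:
        if chrom not in self._depth or end <= start:
            return float("nan")
        d = self._depth[chrom]
        start = max(0, start)
        end = min(len(d), end)
        if end <= start:
            return 0.0
        return float(d[start:end].mean())

    def mean_depth(self, interval: GenomicInterval) -> float:
        return self.value(interval.chrom, interval.start, interval.end)


def coverage_from_srna(
    reads: Sequence[SrnaRead],
    chrom_lengths: Mapping[str, int] | None = None,
) -> CoverageTrack:
    """Depth track with 1/n_mapped_loci weighting of multi-mapped reads."""

    return CoverageTrack(
        [r.interval for r in reads],
        weights=[1.0 / r.n_mapped_loci for r in reads],
        chrom_lengths=chrom_lengths,
    )


def metaprofile(
    track_value: Callable[[str, int, int], float],
    features: Sequence[GenomicInterval],
    body_bins: int = 100,
    flank: int = 2000,
    flank_bin: int = 50,
    label: str = "",
    track_label: str = "",
) -> MetaProfile:
    """Strand-aware scaled-body metaprofile.

    The body of each feature is divided into ``body_bins`` equal
    fractions (fractional bp widths allowed for short features); flanks
    are covered by fixed ``flank_bin``-bp bins.  Per-bin value is the
    mean over features (NaN-aware), with minus-strand features reversed
    so that bin 0 is always the 5' end.
    """

    if not features:
        raise PolylncError("metaprofile needs at least one feature")
    if flank % flank_bin != 0:
        raise PolylncError("flank must be a multiple of flank_bin")
    n_flank = flank // flank_bin
    total_bins = 2 * n_flank + body_bins
    acc = np.zeros(total_bins)
    cnt = np.zeros(total_bins, dtype=np.int64)

    for feat in features:
        vals = np.full(total_bins, np.nan)
        # upstream flank (left in genome coords)
        for i in range(n_flank):
            s = feat.start - flank + i * flank_bin
            v = track_value(feat.chrom, s, s + flank_bin) if s + flank_bin > 0 else np.nan
            vals[i] = v
        # body: fractional equal bins
        L = len(feat)
        bounds = feat.start + np.arange(body_bins + 1) * (L / body_bins)
        for i in range(body_bins):
            s = int(np.floor(bounds[i]))
            e = int(np.ceil(bounds[i + 1]))
            e = max(e, s + 1)
            vals[n_flank + i] = track_value(feat.chrom, s, e)
        # downstream flank
        for i in range(n_flank):
            s = feat.end + i * flank_bin
            vals[n_flank + body_bins + i] = track_value(feat.chrom, s, s + flank_bin)
        if feat.strand == "-":
            vals = vals[::-1]
        ok = np.isfinite(vals)
        acc[ok] += vals[ok]
        cnt[ok] += 1

    with np.errstate(invalid="ignore"):
        values = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return MetaProfile(label, track_label, n_flank, body_bins, values,
                       len(features))


def call_dmrs(
    track_a: MethylationTrack,
    track_b: MethylationTrack,
    window: int = DMR_WINDOW,
    step: int = DMR_STEP,
    min_cyt: int = DMR_MIN_CYT,
    alpha: float = DMR_ALPHA,
    min_delta: float = DMR_MIN_DELTA,
) -> list[DMR]:
    """Sliding-window Fisher exact DMR caller (B relative to A).

    Per window and context with >= ``min_cyt`` covered cytosines in both
    samples, pooled (meth, unmeth) counts are compared with a two-sided
    Fisher exact test.  Windows with p < alpha and |delta| >= min_delta
    are merged with overlapping same-context, same-direction neighbours;
    the merged region's delta is recomputed and its p is the minimum
    window p.
    """

    candidates: dict[str, list[DMR]] = {c: [] for c in METH_CONTEXTS}
    for context in METH_CONTEXTS:
        chroms = {
            c for c in track_a.chroms() | track_b.chroms()
            if len(track_a.positions(c, context))
            and len(track_b.positions(c, context))
        }
        for chrom in sorted(chroms):
            pos_a = track_a.positions(chrom, context)
            pos_b = track_b.positions(chrom, context)
            last = int(max(pos_a[-1], pos_b[-1]))
            for start in range(0, last + 1, step):
                end = start + window
                na = np.searchsorted(pos_a, end) - np.searchsorted(pos_a, start)
                nb = np.searchsorted(pos_b, end) - np.searchsorted(pos_b, start)
                if na < min_cyt or nb < min_cyt:
                    continue
                ma, ta = track_a.counts(chrom, start, end, context)
                mb, tb = track_b.counts(chrom, start, end, context)
                if ta == 0 or tb == 0:
                    continue
                delta = mb / tb - ma / ta
                if abs(delta) < min_delta:
                    continue
                _, p = stats.fisher_exact(
                    [[ma, ta - ma], [mb, tb - mb]], alternative="two-sided"
                )
                if p >= alpha:
                    continue
                direction = "hyper" if delta > 0 else "hypo"
                candidates[context].append(
                    DMR(GenomicInterval(chrom, start, end), context,
                        direction, delta, float(p))
                )

    merged: list[DMR] = []
    for context, dmrs in candidates.items():
        dmrs.sort(key=lambda d: (d.interval.chrom, d.interval.start))
        i = 0
        while i < len(dmrs):
            j = i
            while (
                j + 1 < len(dmrs)
                and dmrs[j + 1].interval.chrom == dmrs[i].interval.chrom
                and dmrs[j + 1].direction == dmrs[i].direction
                and dmrs[j + 1].interval.start <= dmrs[j].interval.end
            ):
                j += 1
            chrom = dmrs[i].interval.chrom
            start = dmrs[i].interval.start
            end = max(d.interval.end for d in dmrs[i : j + 1])
            ma, ta = track_a.counts(chrom, start, end, context)
            mb, tb = track_b.counts(chrom, start, end, context)
            delta = (mb / tb - ma / ta) if ta and tb else dmrs[i].delta
            direction = dmrs[i].direction
            if delta != 0 and (delta > 0) != (direction == "hyper"):
                # merged-region recount disagrees with window direction;
                # keep the window-level direction and its sign
                delta = dmrs[i].delta
            merged.append(
                DMR(GenomicInterval(chrom, start, end), context, direction,
                    delta, min(d.p_value for d in dmrs[i : j + 1]))
            )
            i = j + 1
    merged.sort(key=lambda d: (d.interval.chrom, d.interval.start, d.context))
    return merged


def read_dmr_tsv(path) -> list[DMR]:
    """Import externally called DMRs (chrom, start, end, context,
    direction, delta, p)."""

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise PolylncError(f"{path}:{lineno}: expected 7 columns")
            out.append(
                DMR(GenomicInterval(f[0], int(f[1]), int(f[2])), f[3], f[4],
                    float(f[5]), float(f[6]))
            )
    return out


def write_dmr_tsv(dmrs: Sequence[DMR], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcontext\tdirection\tdelta\tp\n")
        for d in dmrs:
            fh.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}"
                f"\t{d.context}\t{d.direction}\t{d.delta:.4f}\t{d.p_value:.3g}\n"
            )


def dmr_context_composition(dmrs: Sequence[DMR]) -> dict[str, float]:
    """Proportion of DMRs per context (sums to 1; empty input -> zeros)."""

    n = len(dmrs)
    if n == 0:
        return {c: 0.0 for c in METH_CONTEXTS}
    return {
        c: sum(1 for d in dmrs if d.context == c) / n for c in METH_CONTEXTS
    }


def assign_dmrs_to_loci(
    dmrs: Sequence[DMR],
    locus_spans: Mapping[str, GenomicInterval],
    flank: int = ASSOC_FLANK,
) -> dict[int, list[str]]:
    """Greatest-overlap assignment of DMRs to lncRNA loci (span +/- flank).

    Returns a map from DMR index to assigned locus ids (singleton except
    exact overlap ties, which are flagged by assigning both).
    """

    out: dict[int, list[str]] = {}
    for i, d in enumerate(dmrs):
        best: list[str] = []
        best_ov = 0
        for locus, span in sorted(locus_spans.items()):
            ext = GenomicInterval(
                span.chrom, max(0, span.start - flank), span.end + flank
            )
            ov = d.interval.overlap_bp(ext)
            if ov > best_ov:
                best, best_ov = [locus], ov
            elif ov == best_ov and ov > 0:
                best.append(locus)
        if best:
            out[i] = best
    return out


def dmr_expression_association(
    dmrs: Sequence[DMR],
    locus_spans: Mapping[str, GenomicInterval],
    de_class: Mapping[str, str],
    flank: int = ASSOC_FLANK,
) -> pd.DataFrame:
    """Context composition and hyper/hypo split of DMRs per DE class.

    Returns a frame indexed by DE class with per-context proportions,
    hypo/hyper proportions and the number of associated DMRs.
    """

    assignment = assign_dmrs_to_loci(dmrs, locus_spans, flank)
    rows: dict[str, dict[str, float]] = {}
    counts: dict[str, list[DMR]] = {}
    for i, loci in assignment.items():
        for locus in loci:
            cls = de_class.get(locus)
            if cls is None:
                continue
            counts.setdefault(cls, []).append(dmrs[i])
    for cls, ds in sorted(counts.items()):
        n = len(ds)
        row = {f"prop_{c}": sum(1 for d in ds if d.context == c) / n
               for c in METH_CONTEXTS}
        row["prop_hypo"] = sum(1 for d in ds if d.direction == "hypo") / n
        row["prop_hyper"] = sum(1 for d in ds if d.direction == "hyper") / n
        row["n_dmrs"] = n
        rows[cls] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def methylation_expression_correlation(
    delta_meth: pd.DataFrame,
    log2fc: pd.Series,
    subset: Sequence[str] | None = None,
    method: str = "spearman",
) -> dict[str, float | None]:
    """Per-context correlation between methylation change and log2FC.

    ``delta_meth`` is a loci x contexts frame of methylation-level
    changes; ``subset`` restricts to differentially expressed loci.
    Contexts with fewer than 3 usable loci yield ``None``.
    """

    out: dict[str, float | None] = {}
    loci = list(subset) if subset is not None else list(delta_meth.index)
    for context in delta_meth.columns:
        pairs = [
            (delta_meth.at[l, context], log2fc[l])
            for l in loci
            if l in delta_meth.index and l in log2fc.index
            and np.isfinite(delta_meth.at[l, context])
            and np.isfinite(log2fc[l])
        ]
        if len(pairs) < 3:
            out[context] = None
            continue
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if np.all(x == x[0]) or np.all(y == y[0]):
            out[context] = None
            continue
        if method == "spearman":
            out[context] = float(stats.spearmanr(x, y).statistic)
        else:
            out[context] = float(stats.pearsonr(x, y).statistic)
    return out
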