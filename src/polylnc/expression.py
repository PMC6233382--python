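"""RPKM normalisation, in silico mid-parent mixing and differential calls.

The differential test is a pooled exact conditional binomial test after
median-of-ratios library normalisation: replicate counts are pooled per
side, and the pooled count of side A is tested against Binomial(total,
normalised depth share of A).  This is a fully specified, calibratable
substitute for replicate-aware negative-binomial machinery; dispersion
estimation is explicitly out of scope.

Expression classes follow the conventions used throughout the analysis:
expressed means RPKM > 0.5 in at least one member of the contrast; Up
means p < 0.01 and fold change > 2; Down means p < 0.01 and fold change
< 0.5; Equal is expressed but neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountMatrix, PolylncError

EXPRESSED_RPKM = 0.5
DEFAULT_ALPHA = 0.01
DEFAULT_FC = 2.0
PSEUDOCOUNT = 0.5

DE_CLASSES = ("Up", "Down", "Equal", "NotExpressed")


@dataclass(frozen=True)
class ExpressionRecord:
    locus_id: str
    contrast: str
    rpkm_a: float
    rpkm_b: float
    log2fc: float
    p_value: float
    de_class: str


def rpkm(counts: CountMatrix, lengths: Mapping[str, int]) -> pd.DataFrame:
    """Reads per kilobase per million: count * 1e9 / (length * library)."""

    lens = pd.Series({l: lengths[l] for l in counts.locus_ids}, dtype=float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0][0]
        raise PolylncError(f"zero or negative length for locus {bad}")
    mat = counts.counts.astype(float)
    return mat.mul(1e9).div(lens, axis=0).div(
        counts.library_sizes.astype(float), axis=1
    )


def in_silico_mix(parent_a: CountMatrix, parent_b: CountMatrix) -> CountMatrix:
    """Virtual mid-parent sample from two parental count matrices.

    Replicates are paired in sorted sample order (a warning is implied
    when replicate numbers differ; the surplus is dropped).  For each
    pair, counts are depth-normalised to the mean parental library size,
    then averaged: ``mix = round((normA + normB) / 2)``.  Loci absent
    from one parent contribute zero.
    """

    universe = sorted(set(parent_a.locus_ids) | set(parent_b.locus_ids))
    a = parent_a.counts.reindex(universe, fill_value=0)
    b = parent_b.counts.reindex(universe, fill_value=0)
    a_samples = sorted(parent_a.sample_ids)
    b_samples = sorted(parent_b.sample_ids)
    n_pairs = min(len(a_samples), len(b_samples))

    cols = {}
    sizes = {}
    for i in range(n_pairs):
        sa, sb = a_samples[i], b_samples[i]
        la = float(parent_a.library_sizes[sa])
        lb = float(parent_b.library_sizes[sb])
        mean_lib = (la + lb) / 2.0
        norm_a = a[sa].to_numpy(float) * (mean_lib / la)
        norm_b = b[sb].to_numpy(float) * (mean_lib / lb)
        name = f"mix_rep{i + 1}"
        cols[name] = np.round((norm_a + norm_b) / 2.0).astype(np.int64)
        sizes[name] = int(round(mean_lib))
    mix = pd.DataFrame(cols, index=universe)
    return CountMatrix(mix, pd.Series(sizes))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""

    import warnings

    mat = counts.to_numpy(float)
    with np.errstate(divide="ignore"):
        log = np.log(mat)
    log[~np.isfinite(log)] = np.nan
    with warnings.catch_warnings():
        # all-NaN rows (all-zero loci) are expected and handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        ref = np.nanmean(log, axis=1)
    usable = np.isfinite(ref)
    if not usable.any():
        return pd.Series(1.0, index=counts.columns)
    ratios = log[usable] - ref[usable, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sf = np.exp(np.nanmedian(ratios, axis=0))
    sf[~np.isfinite(sf) | (sf <= 0)] = 1.0
    return pd.Series(sf, index=counts.columns)


def de_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Pooled exact binomial differential test per locus.

    Returns a frame with columns ``p_value`` and ``log2fc`` indexed by
    locus.  Counts are normalised by median-of-ratios size factors
    computed over all replicates of both sides; pooled raw counts are
    compared with a two-sided exact binomial test whose success
    probability is the normalised depth share of side A.  Fold change
    uses normalised means with a 0.5 pseudo-count.  All-zero loci get
    p = 1, log2fc = 0.

    When ``library_sizes`` is given (indexed by sample), depths are
    taken from them directly instead of being estimated by the ratio
    median — use this when the locus set is too small or too skewed for
    median-of-ratios to be reliable.
    """

    if counts_a.shape[0] != counts_b.shape[0]:
        raise PolylncError("locus universes differ between sides")
    joint = pd.concat([counts_a, counts_b], axis=1)
    if library_sizes is not None:
        libs = library_sizes.reindex(joint.columns).astype(float)
        if libs.isna().any() or (libs <= 0).any():
            raise PolylncError("library sizes must cover every sample")
        sf = libs / np.exp(np.log(libs).mean())
    else:
        sf = size_factors(joint)
    sf_a = sf[counts_a.columns]
    sf_b = sf[counts_b.columns]
    share_a = float(sf_a.sum() / (sf_a.sum() + sf_b.sum()))

    pooled_a = counts_a.sum(axis=1).to_numpy(np.int64)
    pooled_b = counts_b.sum(axis=1).to_numpy(np.int64)
    total = pooled_a + pooled_b

    mean_a = counts_a.div(sf_a, axis=1).mean(axis=1).to_numpy(float)
    mean_b = counts_b.div(sf_b, axis=1).mean(axis=1).to_numpy(float)
    log2fc = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))

    p = np.ones(len(total))
    nz = total > 0
    idx = np.where(nz)[0]
    # binomtest is scalar; loop only over non-zero loci
    for i in idx:
        p[i] = stats.binomtest(
            int(pooled_a[i]), int(total[i]), share_a
        ).pvalue
    log2fc[~nz] = 0.0
    return pd.DataFrame(
        {"p_value": p, "log2fc": log2fc}, index=counts_a.index
    )


def classify_de(
    rpkm_a: pd.Series,
    rpkm_b: pd.Series,
    tests: pd.DataFrame,
    contrast: str = "A:B",
    alpha: float = DEFAULT_ALPHA,
    fc: float = DEFAULT_FC,
) -> list[ExpressionRecord]:
    """Assign Up/Down/Equal/NotExpressed per locus.

    ``rpkm_a``/``rpkm_b`` are representative (mean over replicates)
    RPKM values per side; ``tests`` comes from :func:`de_test`.
    """

    out = []
    for locus in tests.index:
        ra = float(rpkm_a.get(locus, 0.0))
        rb = float(rpkm_b.get(locus, 0.0))
        p = float(tests.at[locus, "p_value"])
        lfc = float(tests.at[locus, "log2fc"])
        expressed = ra > EXPRESSED_RPKM or rb > EXPRESSED_RPKM
        if not expressed:
            cls = "NotExpressed"
        elif p < alpha and lfc > np.log2(fc):
            cls = "Up"
        elif p < alpha and lfc < -np.log2(fc):
            cls = "Down"
        else:
            cls = "Equal"
        out.append(ExpressionRecord(locus, contrast, ra, rb, lfc, p, cls))
    return out


def de_summary(records: Sequence[ExpressionRecord]) -> dict:
    """Percentage of expressed loci that are differentially expressed."""

    n_expressed = sum(1 for r in records if r.de_class != "NotExpressed")
    n_de = sum(1 for r in records if r.de_class in ("Up", "Down"))
    return {
        "n_expressed": n_expressed,
        "n_de": n_de,
        "pct_de": de_percentage(n_de, n_expressed),
    }


def de_percentage(n_de: int, n_expressed: int) -> float | None:
    """100 * n_DE / n_expressed, rounded to two decimals; None if empty."""

    if n_expressed == 0:
        return None
    return round(100.0 * n_de / n_expressed, 2)


def expression_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> float | None:
    """Correlation between two expression vectors (undefined -> None)."""

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise PolylncError("correlation needs equal-length vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    if method == "spearman":
        r = stats.spearmanr(x, y).statistic
    elif method == "pearson":
        r = stats.pearsonr(x, y).statistic
    else:
        raise PolylncError(f"unknown correlation method {method!r}")
    return float(r)
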