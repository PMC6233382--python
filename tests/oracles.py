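"""Independent brute-force reference implementations used only in tests.

Each oracle is deliberately naive (quadratic loops, exhaustive
enumeration, per-bp averaging) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import math


def orf_scan_6frame(seq: str) -> int:
    """Longest ATG..stop ORF in codons over six frames, by regex-free
    character scanning (independent of the package scanner)."""

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(seq))
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for s in (seq, rc):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]
            i = 0
            while i < len(codons):
                if codons[i] == "ATG":
                    j = i
                    while j < len(codons) and codons[j] not in stops:
                        j += 1
                    best = max(best, j - i)
                    i += 1
                else:
                    i += 1
    return best


def overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def longest_te_assignment(regions, tes):
    """All-pairs intersection; pick longest TE, leftmost, then id.

    ``regions``: list of (start, end); ``tes``: list of
    (start, end, family, te_id).  Returns (family, te_id, overlap) or
    None.
    """

    candidates = []
    for (ts, te_, fam, tid) in tes:
        ov = sum(overlap_bp((ts, te_), r) for r in regions)
        if ov >= 1:
            candidates.append((-(te_ - ts), ts, tid, fam, ov))
    if not candidates:
        return None
    candidates.sort()
    neg_len, start, tid, fam, ov = candidates[0]
    return fam, tid, ov


def best_monotone_chain_weight(pairs, max_gap):
    """Exhaustive search over all monotone anchor chains.

    ``pairs``: list of (rank_a, rank_b, score).  Returns the maximal
    total score over chains whose consecutive steps satisfy
    0 < delta_a <= max_gap and 0 < |delta_b| <= max_gap with a
    consistent sign.
    """

    n = len(pairs)
    best = 0.0
    order = sorted(range(n), key=lambda i: (pairs[i][0], pairs[i][1]))

    def extend(chain_idx, sign, total):
        nonlocal best
        best = max(best, total)
        last = pairs[order[chain_idx[-1]]]
        for nxt in range(chain_idx[-1] + 1, n):
            p = pairs[order[nxt]]
            da = p[0] - last[0]
            db = p[1] - last[1]
            if not (0 < da <= max_gap):
                continue
            for s in ((sign,) if sign else (+1, -1)):
                if 0 < db * s <= max_gap:
                    extend(chain_idx + [nxt], s, total + p[2])

    for i in range(n):
        extend([i], 0, pairs[order[i]][2])
    return best


def fisher_two_sided(a, b, c, d) -> float:
    """Two-sided Fisher exact p by hypergeometric tail enumeration."""

    def log_comb(n, k):
        return (math.lgamma(n + 1) - math.lgamma(k + 1)
                - math.lgamma(n - k + 1))

    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = log_comb(n, col1)

    def prob(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > row2:
            return 0.0
        return math.exp(log_comb(row1, x) + log_comb(row2, col1 - x) - denom)

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def spearman_rank_pearson(x, y) -> float:
    """Average-rank Spearman computed as Pearson on manual ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def per_bp_profile(values_by_pos, start, end, strand, body_bins, flank,
                   flank_bin):
    """Per-bp averaging metaprofile oracle for one feature.

    ``values_by_pos``: callable pos -> value or None (missing).  The
    feature length must be a multiple of ``body_bins`` so that body bins
    are unambiguous.  Returns the ordered per-bin means with None for
    empty bins, 5'->3'.
    """

    assert (end - start) % body_bins == 0
    w = (end - start) // body_bins
    n_flank = flank // flank_bin
    bins = []
    for i in range(n_flank):
        s = start - flank + i * flank_bin
        bins.append((s, s + flank_bin))
    for i in range(body_bins):
        bins.append((start + i * w, start + (i + 1) * w))
    for i in range(n_flank):
        bins.append((end + i * flank_bin, end + (i + 1) * flank_bin))
    out = []
    for s, e in bins:
        vals = [values_by_pos(p) for p in range(s, e)]
        vals = [v for v in vals if v is not None]
        out.append(sum(vals) / len(vals) if vals else None)
    if strand == "-":
        out = out[::-1]
    return out
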