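"""Shared fixtures: one session-scoped synthetic dataset reused by the
classification, synteny, TE and profile suites."""

import pytest

from polylnc.align import all_vs_genome
from polylnc.classify import filter_lncrna, score_transcripts
from polylnc.expression import rpkm
from polylnc.simulate import (
    SimConfig,
    simulate_counts,
    simulate_genomes,
    simulate_methylome,
)
from polylnc.synteny import (
    chain_collinear_blocks,
    gene_ranks,
    place_lncrna,
    reciprocal_best_pairs,
)


@pytest.fixture(scope="session")
def dataset():
    return simulate_genomes(SimConfig(seed=11))


@pytest.fixture(scope="session")
def counts(dataset):
    return simulate_counts(dataset)


@pytest.fixture(scope="session")
def methylome(dataset):
    return simulate_methylome(dataset)


@pytest.fixture(scope="session")
def spliced_lengths(dataset):
    return {
        t.locus_id: t.spliced_length
        for g in "AD"
        for t in dataset.lnc[g] + dataset.pcg[g]
    }


@pytest.fixture(scope="session")
def classified(dataset):
    """Filtered lncRNA transcripts per genome."""

    out = {}
    for g in "AD":
        cands = dataset.lnc[g] + dataset.pcg[g]
        ev = score_transcripts(cands, dataset.genomes[g])
        out[g] = filter_lncrna(cands, dataset.pcg[g], ev)
    return out


@pytest.fixture(scope="session")
def synteny_calls(dataset, counts, classified, spliced_lengths):
    """ST/SA/SYN_PCG/NON_SYN calls for genome-A lincRNA loci."""

    ds = dataset
    tx = {
        g: {t.locus_id: "".join(ds.genomes[g][t.chrom][e.start:e.end]
                                for e in t.exons) for t in ds.pcg[g]}
        for g in "AD"
    }
    pairs = reciprocal_best_pairs(
        all_vs_genome(tx["A"], tx["D"]), all_vs_genome(tx["D"], tx["A"]),
        gene_ranks(ds.pcg["A"]), gene_ranks(ds.pcg["D"]),
    )
    blocks = chain_collinear_blocks(pairs)
    linc = [t for t in classified["A"] if t.biotype == "lincRNA"]
    lnc_seqs = {
        t.locus_id: ds.genomes["A"][t.chrom][t.interval.start:t.interval.end]
        for t in linc
    }
    hits = all_vs_genome(lnc_seqs, ds.genomes["D"])
    r = rpkm(counts, spliced_lengths)
    d_samples = [s for s in counts.sample_ids if s.startswith("Gr")]
    expressed_d = set(
        r.index[(r[d_samples] > 0.5).any(axis=1)]
    ) & {t.locus_id for t in ds.lnc["D"]}
    return place_lncrna(linc, blocks, hits, ds.lnc["D"], ds.pcg["D"],
                        expressed_d)
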