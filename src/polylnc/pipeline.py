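"""End-to-end orchestration: simulate -> classify -> synteny -> TE ->
expression -> methylation/sRNA profiles -> machine-readable report.

Every stage writes its intermediates under the output directory; the
summary report is recomputed from those intermediates (no in-memory-only
numbers) and serialised as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .align import all_vs_genome
from .classify import filter_lncrna, score_transcripts
from .core import GenomicInterval, PolylncError
from .expression import (
    classify_de,
    de_summary,
    de_test,
    expression_correlation,
    in_silico_mix,
    rpkm,
)
from .profiles import (
    MethylationTrack,
    coverage_from_srna,
    call_dmrs,
    dmr_context_composition,
    dmr_expression_association,
    filter_srna,
    metaprofile,
    methylation_expression_correlation,
    write_dmr_tsv,
)
from .simulate import (
    SimConfig,
    simulate_counts,
    simulate_genomes,
    simulate_methylome,
    simulate_srna,
)
from .synteny import (
    chain_collinear_blocks,
    gene_ranks,
    place_lncrna,
    reciprocal_best_pairs,
    sa_fraction,
)
from .te import assign_te_all, family_enrichment, te_composition

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All numeric thresholds the stages use (length 200 nt, coding
    score 0, domain E 0.001, hit E 1e-10, expressed RPKM 0.5, DE
    alpha/FC, 2 kb flanks), plus simulation settings and the output
    location."""

    seed: int = 0
    outdir: str = "polylnc_run"
    min_length_nt: int = 200
    coding_score_cutoff: float = 0.0
    domain_evalue: float = 0.001
    hit_evalue: float = 1e-10
    min_anchors: int = 5
    max_gap: int = 25
    expressed_rpkm: float = 0.5
    de_alpha: float = 0.01
    de_fc: float = 2.0
    flank: int = 2000
    dmr_window: int = 100
    dmr_step: int = 50
    dmr_min_cyt: int = 4
    dmr_alpha: float = 0.01
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PolylncError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.simulate)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations; empty means the run can start."""

    v = []
    if not (0.0 < config.de_alpha < 1.0):
        v.append(f"de_alpha={config.de_alpha} outside (0, 1)")
    if config.de_fc <= 1.0:
        v.append(f"de_fc={config.de_fc} must exceed 1")
    if config.min_length_nt < 1:
        v.append("min_length_nt must be positive")
    if config.hit_evalue <= 0:
        v.append("hit_evalue must be positive")
    if config.min_anchors < 2:
        v.append("min_anchors must be at least 2")
    if config.max_gap < 1:
        v.append("max_gap must be positive")
    if config.expressed_rpkm < 0:
        v.append("expressed_rpkm must be non-negative")
    if config.flank < 0:
        v.append("flank must be non-negative")
    if not (0.0 < config.dmr_alpha < 1.0):
        v.append(f"dmr_alpha={config.dmr_alpha} outside (0, 1)")
    if config.dmr_window < config.dmr_step:
        v.append("dmr_window must be >= dmr_step")
    try:
        config.sim_config().validate()
    except (PolylncError, TypeError) as exc:
        v.append(f"simulate: {exc}")
    return v


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-study pipeline and write the report.

    Returns the summary report (also serialised to ``report.json`` in
    the output directory).  Stage failures abort with the stage name;
    intermediates written so far are retained.
    """

    violations = validate_config(config)
    if violations:
        raise PolylncError("invalid config: " + "; ".join(violations))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {
        k: v for k, v in dataclasses.asdict(config).items() if k != "simulate"
    }}

    stage = "simulate"
    try:
        ds = simulate_genomes(config.sim_config())
        pio.write_fasta({c: s for g in "AD" for c, s in ds.genomes[g].items()},
                        out / "f1_genome.fasta")
        for g in "AD":
            pio.write_gtf(ds.pcg[g] + ds.lnc[g], out / f"annotation_{g}.gtf")
            pio.write_te_bed(ds.tes[g], out / f"te_{g}.bed")
        ds.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        counts = simulate_counts(ds)
        pio.write_count_matrix(counts, out / "counts.tsv")
        report[stage] = {
            "n_pcg": sum(len(v) for v in ds.pcg.values()),
            "n_lnc_planted": int(len(ds.truth)),
            "n_te": sum(len(v) for v in ds.tes.values()),
        }

        stage = "classify"
        lengths = {t.locus_id: t.spliced_length
                   for g in "AD" for t in ds.lnc[g] + ds.pcg[g]}
        kept = {}
        for g in "AD":
            cands = ds.lnc[g] + ds.pcg[g]
            ev = score_transcripts(cands, ds.genomes[g])
            kept[g] = filter_lncrna(cands, ds.pcg[g], ev,
                                    min_length=config.min_length_nt)
            pio.write_gtf(kept[g], out / f"lnc_{g}.gtf")
        report[stage] = {
            g: {"n_candidates": len(ds.lnc[g] + ds.pcg[g]),
                "n_kept": len(kept[g]),
                "biotypes": pd.Series(
                    [t.biotype for t in kept[g]]).value_counts().to_dict()}
            for g in "AD"
        }

        stage = "synteny"
        tx_seq = {
            g: {t.locus_id: "".join(ds.genomes[g][t.chrom][e.start:e.end]
                                    for e in t.exons) for t in ds.pcg[g]}
            for g in "AD"
        }
        hits_ad = all_vs_genome(tx_seq["A"], tx_seq["D"],
                                max_evalue=config.hit_evalue)
        hits_da = all_vs_genome(tx_seq["D"], tx_seq["A"],
                                max_evalue=config.hit_evalue)
        pio.write_hits_tabular(hits_ad, out / "hits_ad.tsv")
        pio.write_hits_tabular(hits_da, out / "hits_da.tsv")
        pairs = reciprocal_best_pairs(hits_ad, hits_da,
                                      gene_ranks(ds.pcg["A"]),
                                      gene_ranks(ds.pcg["D"]),
                                      max_evalue=config.hit_evalue)
        blocks = chain_collinear_blocks(pairs, min_anchors=config.min_anchors,
                                        max_gap=config.max_gap)
        with open(out / "blocks.tsv", "w") as fh:
            fh.write("block_id\tchrom_a\tstart_a\tend_a\tchrom_b\tstart_b"
                     "\tend_b\tn_anchors\torientation\n")
            for b in blocks:
                fh.write(f"{b.block_id}\t{b.chrom_a}\t{b.span_a.start}"
                         f"\t{b.span_a.end}\t{b.chrom_b}\t{b.span_b.start}"
                         f"\t{b.span_b.end}\t{len(b.anchors)}\t{b.orientation}\n")

        linc_a = [t for t in kept["A"] if t.biotype == "lincRNA"]
        lnc_seqs = {t.locus_id:
                    ds.genomes["A"][t.chrom][t.interval.start:t.interval.end]
                    for t in linc_a}
        lnc_hits = all_vs_genome(lnc_seqs, ds.genomes["D"],
                                 max_evalue=config.hit_evalue)
        pio.write_hits_tabular(lnc_hits, out / "lnc_hits_ad.tsv")
        rpkm_all = rpkm(counts, lengths)
        d_samples = [s for s in counts.sample_ids if s.startswith("Gr")]
        expressed_d = set(
            rpkm_all.index[(rpkm_all[d_samples] > config.expressed_rpkm)
                           .any(axis=1)]
        ) & {t.locus_id for t in ds.lnc["D"]}
        calls = place_lncrna(linc_a, blocks, lnc_hits, ds.lnc["D"],
                             ds.pcg["D"], expressed_d,
                             max_evalue=config.hit_evalue)
        calls_df = pd.DataFrame(
            [{"locus_id": c.lnc_locus_id, "label": c.label,
              "partner": c.partner_locus_id or "",
              "block_id": c.block_id or ""} for c in calls]
        )
        calls_df.to_csv(out / "synteny_calls.tsv", sep="\t", index=False)
        sa = sa_fraction(calls)
        report[stage] = {
            "n_anchor_pairs": len(pairs),
            "n_blocks": len(blocks),
            "labels": calls_df["label"].value_counts().to_dict(),
            "sa_fraction": None if sa is None else round(sa, 4),
            "sa_percent": None if sa is None else round(100 * sa, 2),
        }

        stage = "te_overlap"
        chrom_lengths = {c: len(s) for g in "AD"
                         for c, s in ds.genomes[g].items()}
        assignments = assign_te_all(linc_a, ds.tes["A"], flank=config.flank,
                                    chrom_lengths=chrom_lengths)
        comp = te_composition(assignments)
        comp.to_csv(out / "te_composition.tsv", sep="\t", index=False)
        st_ids = {c.lnc_locus_id for c in calls if c.label == "ST"}
        sa_ids = {c.lnc_locus_id for c in calls if c.label == "SA"}
        enrich = family_enrichment(st_ids, sa_ids, assignments)
        pd.DataFrame([dataclasses.asdict(e) for e in enrich]).to_csv(
            out / "te_enrichment.tsv", sep="\t", index=False
        )
        te_loci = {a.locus_id for a in assignments
                   if a.region_kind in ("exon", "intron")}
        report[stage] = {
            "n_assignments": len(assignments),
            "pct_lnc_te_overlapped": round(
                100 * len(te_loci) / max(1, len(linc_a)), 2),
            "n_enriched_families_p01": sum(1 for e in enrich
                                           if e.fisher_p < 0.01),
        }

        stage = "expression"
        ga = counts.subset_samples(
            [s for s in counts.sample_ids if s.startswith("Ga")])
        gr = counts.subset_samples(
            [s for s in counts.sample_ids if s.startswith("Gr")])
        f1 = counts.subset_samples(
            [s for s in counts.sample_ids if s.startswith("F1")])
        mix = in_silico_mix(ga, gr)
        pio.write_count_matrix(mix, out / "midparent_counts.tsv")
        tests = de_test(f1.counts, mix.counts.reindex(f1.counts.index))
        lnc_ids = [l for l in ds.truth.index]
        r_f1 = rpkm(f1, lengths).mean(axis=1)
        r_mix = rpkm(mix, lengths).mean(axis=1)
        records = classify_de(r_f1[lnc_ids], r_mix[lnc_ids],
                              tests.loc[lnc_ids], contrast="F1:midparent",
                              alpha=config.de_alpha, fc=config.de_fc)
        de_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        de_df.to_csv(out / "de_lnc.tsv", sep="\t", index=False)
        spearman = expression_correlation(
            np.log2(r_f1[lnc_ids] + 1), np.log2(r_mix[lnc_ids] + 1)
        )
        report[stage] = {
            **de_summary(records),
            "classes": de_df["de_class"].value_counts().to_dict(),
            "spearman_f1_vs_midparent": None if spearman is None
            else round(spearman, 3),
        }

        stage = "methylation"
        meth = simulate_methylome(ds)
        track_p = MethylationTrack.from_frame(meth["parent"])
        track_f = MethylationTrack.from_frame(meth["F1"])
        dmrs = call_dmrs(track_p, track_f, window=config.dmr_window,
                         step=config.dmr_step, min_cyt=config.dmr_min_cyt,
                         alpha=config.dmr_alpha)
        write_dmr_tsv(dmrs, out / "dmrs.tsv")
        locus_spans = {
            lid: GenomicInterval(row["chrom"], int(row["start"]),
                                 int(row["end"]), row["strand"])
            for lid, row in ds.truth.iterrows()
        }
        de_class = {r.locus_id: r.de_class for r in records}
        assoc = dmr_expression_association(dmrs, locus_spans, de_class,
                                           flank=config.flank)
        assoc.to_csv(out / "dmr_association.tsv", sep="\t")
        delta = pd.DataFrame({
            ctx: {lid: track_f.level(sp.chrom, sp.start, sp.end, ctx)
                  - track_p.level(sp.chrom, sp.start, sp.end, ctx)
                  for lid, sp in locus_spans.items()}
            for ctx in ("CG", "CHG", "CHH")
        })
        de_loci = [l for l, c in de_class.items() if c in ("Up", "Down")]
        corr = methylation_expression_correlation(
            delta, tests["log2fc"], subset=de_loci
        )
        report[stage] = {
            "n_dmrs": len(dmrs),
            "context_composition": {
                k: round(v, 4) for k, v in
                dmr_context_composition(dmrs).items()},
            "meth_expr_correlation": {
                k: None if v is None else round(v, 3)
                for k, v in corr.items()},
            "association": assoc.round(4).to_dict(orient="index"),
        }

        stage = "srna"
        reads = filter_srna(simulate_srna(ds))
        pio.write_bed_intervals([r.interval for r in reads],
                                out / "srna_reads.bed")
        cov = coverage_from_srna(reads, chrom_lengths=chrom_lengths)
        lnc_span_list = {
            g: [(t.interval.start, t.interval.end, t.chrom)
                for t in ds.lnc[g]] for g in "AD"
        }

        def te_features(inside_lnc: bool):
            out_ivs = []
            for g in "AD":
                for te in ds.tes[g]:
                    ins = any(te.interval.start < e and s < te.interval.end
                              and te.interval.chrom == c
                              for s, e, c in lnc_span_list[g])
                    if ins == inside_lnc:
                        out_ivs.append(te.interval)
            return out_ivs

        prof_gw = metaprofile(cov.value, te_features(False), body_bins=40,
                              flank=1000, flank_bin=50, label="TE_genomewide",
                              track_label="siRNA")
        prof_lnc = metaprofile(cov.value, te_features(True), body_bins=40,
                               flank=1000, flank_bin=50, label="TE_lnc",
                               track_label="siRNA")
        pd.DataFrame({
            "bin": range(len(prof_gw.values)),
            "te_genomewide": prof_gw.values,
            "te_lnc_overlapped": prof_lnc.values,
        }).to_csv(out / "srna_profiles.tsv", sep="\t", index=False)
        report[stage] = {
            "n_reads_kept": len(reads),
            "te_body_mean": round(float(np.nanmean(prof_gw.body_values)), 4),
            "te_flank_mean": round(float(
                (np.nanmean(prof_gw.upstream_values)
                 + np.nanmean(prof_gw.downstream_values)) / 2), 4),
            "lnc_te_body_mean": round(float(
                np.nanmean(prof_lnc.body_values)), 4),
        }
    except Exception as exc:
        raise PolylncError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
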