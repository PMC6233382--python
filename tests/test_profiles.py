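"""Methylation levels, metaprofiles, sRNA filter, DMR caller, association."""

import numpy as np
import pandas as pd
import pytest

from polylnc.core import CytosineRecord, GenomicInterval
from polylnc.profiles import (  # noqa
    CoverageTrack,
    DMR,
    MethylationTrack,
    SrnaRead,
    assign_dmrs_to_loci,
    call_dmrs,
    coverage_from_srna,
    dmr_context_composition,
    dmr_expression_association,
    filter_srna,
    metaprofile,
    methylation_expression_correlation,
    read_dmr_tsv,
    weighted_methylation,
    write_dmr_tsv,
)

from oracles import per_bp_profile


def cyt(pos, meth, total, context="CG", chrom="c"):
    return CytosineRecord(chrom, pos, "+", context, meth, total)


def srna(start, length, n_loci=1, chrom="c"):
    return SrnaRead(GenomicInterval(chrom, start, start + length), length,
                    n_loci)


class TestSrnaFilter:
    def test_length_boundaries(self):
        reads = [srna(0, 19), srna(100, 20), srna(200, 25), srna(300, 26)]
        kept = filter_srna(reads)
        assert [r.length for r in kept] == [20, 25]

    def test_multimapping_boundary(self):
        reads = [srna(0, 24, 50), srna(100, 24, 51)]
        kept = filter_srna(reads)
        assert len(kept) == 1 and kept[0].n_mapped_loci == 50

    def test_hundred_read_fixture_matches_manual_filter(self):
        rng = np.random.default_rng(0)
        reads = [srna(int(100 * i), int(l), int(m)) for i, (l, m) in
                 enumerate(zip(rng.integers(15, 35, 100),
                               rng.integers(1, 80, 100)))]
        kept = filter_srna(reads)
        manual = [r for r in reads
                  if 20 <= r.length <= 25 and r.n_mapped_loci <= 50]
        assert kept == manual

    def test_blacklist_removal(self):
        reads = [SrnaRead(GenomicInterval("c", 0, 24), 24, 1, "mir1"),
                 SrnaRead(GenomicInterval("c", 50, 74), 24, 1, "ok")]
        kept = filter_srna(reads, blacklist_ids={"mir1"})
        assert [r.read_id for r in kept] == ["ok"]


class TestWeightedMethylation:
    def test_single_cytosine(self):
        level = weighted_methylation([cyt(10, 3, 4)],
                                     GenomicInterval("c", 0, 100), "CG")
        assert level == pytest.approx(0.75)

    def test_fully_unmethylated(self):
        recs = [cyt(i, 0, 5) for i in range(10)]
        assert weighted_methylation(recs, GenomicInterval("c", 0, 50),
                                    "CG") == 0.0

    def test_no_coverage_masked(self):
        assert np.isnan(weighted_methylation([cyt(10, 1, 2)],
                                             GenomicInterval("c", 50, 90),
                                             "CG"))

    def test_weighted_not_mean_of_ratios(self):
        """30-cytosine fixture: the coverage-weighted estimator differs
        from the mean of per-site ratios and matches the hand sum."""

        rng = np.random.default_rng(1)
        totals = rng.integers(1, 40, 30)
        meths = [int(rng.integers(0, t + 1)) for t in totals]
        recs = [cyt(i * 3, m, int(t)) for i, (m, t) in
                enumerate(zip(meths, totals))]
        iv = GenomicInterval("c", 0, 100)
        got = weighted_methylation(recs, iv, "CG")
        hand_weighted = sum(meths) / sum(totals)
        mean_of_ratios = np.mean([m / t for m, t in zip(meths, totals)])
        assert got == pytest.approx(hand_weighted)
        assert abs(got - mean_of_ratios) > 1e-3   # estimators do differ here

    def test_union_property(self):
        """Level over a union of disjoint intervals equals the
        count-weighted combination of the parts."""

        rng = np.random.default_rng(2)
        recs = [cyt(int(p), int(m), int(m) + int(u))
                for p, m, u in zip(rng.choice(500, 60, replace=False),
                                   rng.integers(0, 10, 60),
                                   rng.integers(1, 10, 60))]
        track = MethylationTrack(recs)
        a = GenomicInterval("c", 0, 200)
        b = GenomicInterval("c", 200, 500)
        whole = GenomicInterval("c", 0, 500)
        ma, ta = track.counts("c", a.start, a.end, "CG")
        mb, tb = track.counts("c", b.start, b.end, "CG")
        assert track.level("c", 0, 500, "CG") == pytest.approx(
            (ma + mb) / (ta + tb))


class TestMetaprofile:
    def test_uniform_track_flat_profile(self):
        track = CoverageTrack([GenomicInterval("c", 0, 50_000)])
        prof = metaprofile(track.value,
                           [GenomicInterval("c", 10_000, 12_000, "+")],
                           body_bins=20, flank=2000, flank_bin=100)
        assert np.allclose(prof.values, 1.0)

    def test_step_track_steps_at_body_midpoint(self):
        # depth 1 only over the second half of the body
        feat = GenomicInterval("c", 10_000, 12_000, "+")
        track = CoverageTrack([GenomicInterval("c", 11_000, 12_000)],
                              chrom_lengths={"c": 50_000})
        prof = metaprofile(track.value, [feat], body_bins=100,
                           flank=2000, flank_bin=100)
        body = prof.body_values
        assert np.allclose(body[:50], 0.0)
        assert np.allclose(body[50:], 1.0)

    def test_minus_strand_reversed(self):
        feat = GenomicInterval("c", 10_000, 12_000, "-")
        track = CoverageTrack([GenomicInterval("c", 11_000, 12_000)],
                              chrom_lengths={"c": 50_000})
        prof = metaprofile(track.value, [feat], body_bins=100,
                           flank=2000, flank_bin=100)
        body = prof.body_values
        assert np.allclose(body[:50], 1.0)    # 5' half on minus strand
        assert np.allclose(body[50:], 0.0)

    def test_random_fixtures_match_per_bp_oracle(self):
        """<= 10 features per fixture, 100 fixtures, coverage binning
        equals naive per-bp averaging."""

        rng = np.random.default_rng(3)
        for trial in range(100):
            n_feat = int(rng.integers(1, 11))
            body_bins = int(rng.choice([4, 10, 20]))
            feats = []
            for _ in range(n_feat):
                start = int(rng.integers(3000, 30_000))
                length = body_bins * int(rng.integers(5, 60))
                strand = "+" if rng.random() < 0.5 else "-"
                feats.append(GenomicInterval("c", start, start + length,
                                             strand))
            reads = [GenomicInterval("c", int(s), int(s) + int(l))
                     for s, l in zip(rng.integers(0, 40_000, 80),
                                     rng.integers(20, 2000, 80))]
            track = CoverageTrack(reads, chrom_lengths={"c": 60_000})
            prof = metaprofile(track.value, feats, body_bins=body_bins,
                               flank=1000, flank_bin=100)

            depth = np.zeros(60_000)
            for r in reads:
                depth[r.start:r.end] += 1
            per_feat = [per_bp_profile(lambda p: depth[p], f.start, f.end,
                                       f.strand, body_bins, 1000, 100)
                        for f in feats]
            expected = np.nanmean(
                np.array([[np.nan if v is None else v for v in row]
                          for row in per_feat]), axis=0)
            assert np.allclose(prof.values, expected, rtol=1e-9,
                               atol=1e-12), f"trial {trial}"

    def test_short_feature_fractional_bins(self):
        # 10 bp body into 20 bins: every bin still gets a finite value
        feat = GenomicInterval("c", 5000, 5010, "+")
        track = CoverageTrack([GenomicInterval("c", 0, 20_000)])
        prof = metaprofile(track.value, [feat], body_bins=20, flank=1000,
                           flank_bin=100)
        assert np.all(np.isfinite(prof.body_values))


class TestDmrCaller:
    def _tracks(self, pi_a, pi_b, n=600, depth=20, seed=0, context="CG"):
        rng = np.random.default_rng(seed)
        pos = np.arange(0, n * 10, 10)
        recs_a, recs_b = [], []
        for p in pos:
            ta, tb = rng.poisson(depth) + 1, rng.poisson(depth) + 1
            recs_a.append(CytosineRecord("c", int(p), "+", context,
                                         int(rng.binomial(ta, pi_a(p))), ta))
            recs_b.append(CytosineRecord("c", int(p), "+", context,
                                         int(rng.binomial(tb, pi_b(p))), tb))
        return MethylationTrack(recs_a), MethylationTrack(recs_b)

    def test_identical_samples_no_dmrs(self):
        ta, tb = self._tracks(lambda p: 0.5, lambda p: 0.5, seed=1)
        # identical generating process; any calls are false positives at
        # alpha with the delta filter, expect none at these settings
        dmrs = call_dmrs(ta, ta)
        assert dmrs == []

    def test_planted_hypo_drop_detected(self):
        """0.8 -> 0.2 CG drop over a 500 bp window at ~20x depth is found
        as a hypo DMR in >= 95% of 50 seeded replicates."""

        found = 0
        for seed in range(50):
            ta, tb = self._tracks(
                lambda p: 0.8,
                lambda p: 0.2 if 2000 <= p < 2500 else 0.8,
                n=500, seed=seed,
            )
            dmrs = call_dmrs(ta, tb)
            hit = any(d.direction == "hypo" and d.context == "CG"
                      and d.interval.start < 2500 and d.interval.end > 2000
                      for d in dmrs)
            found += hit
        assert found >= 48  # 96%

    def test_window_below_min_cyt_skipped(self):
        recs = [cyt(p, 0, 10) for p in (0, 30, 60)]       # 3 cytosines
        alt = [cyt(p, 10, 10) for p in (0, 30, 60)]
        dmrs = call_dmrs(MethylationTrack(recs), MethylationTrack(alt),
                         window=100, step=100, min_cyt=4)
        assert dmrs == []

    def test_direction_matches_delta_sign(self):
        ta, tb = self._tracks(lambda p: 0.2, lambda p: 0.8, n=100, seed=3)
        dmrs = call_dmrs(ta, tb)
        assert dmrs and all(d.direction == "hyper" and d.delta > 0
                            for d in dmrs)

    def test_null_type_one_rate_bounded(self):
        """Null methylome: fraction of windows called stays below twice
        the window-level alpha."""

        n_called = 0
        n_windows = 0
        for seed in range(5):
            ta, tb = self._tracks(lambda p: 0.5, lambda p: 0.5,
                                  n=2000, seed=50 + seed)
            dmrs = call_dmrs(ta, tb, window=100, step=100)
            n_called += len(dmrs)
            n_windows += 2000 * 10 // 100
        assert n_called / n_windows < 2 * 0.01


class TestDmrImportAndComposition:
    def test_round_trip(self, tmp_path):
        dmrs = [DMR(GenomicInterval("c", 0, 100), "CG", "hypo", -0.4, 1e-5),
                DMR(GenomicInterval("c", 500, 650), "CHH", "hyper", 0.2,
                    1e-3)]
        p = tmp_path / "d.tsv"
        write_dmr_tsv(dmrs, p)
        back = read_dmr_tsv(p)
        assert len(back) == 2
        assert back[0].context == "CG" and back[0].direction == "hypo"

    def test_composition_all_cg(self):
        dmrs = [DMR(GenomicInterval("c", i, i + 50), "CG", "hypo", -0.2, 0.001)
                for i in range(0, 300, 100)]
        assert dmr_context_composition(dmrs) == {"CG": 1.0, "CHG": 0.0,
                                                 "CHH": 0.0}

    def test_planted_mix_passthrough(self):
        rng = np.random.default_rng(4)
        mix = ["CG"] * 191 + ["CHG"] * 76 + ["CHH"] * 33   # 300 planted
        rng.shuffle(mix)
        dmrs = [DMR(GenomicInterval("c", 100 * i, 100 * i + 50), ctx,
                    "hypo", -0.2, 1e-4) for i, ctx in enumerate(mix)]
        comp = dmr_context_composition(dmrs)
        assert comp["CG"] == pytest.approx(191 / 300)
        assert comp["CHG"] == pytest.approx(76 / 300)
        assert comp["CHH"] == pytest.approx(33 / 300)

    def test_direction_delta_mismatch_rejected(self):
        with pytest.raises(Exception):
            DMR(GenomicInterval("c", 0, 10), "CG", "hyper", -0.5, 0.01)


class TestAssociation:
    def test_no_dmrs_empty(self):
        spans = {"L1": GenomicInterval("c", 1000, 2000)}
        out = dmr_expression_association([], spans, {"L1": "Up"})
        assert out.empty

    def test_planted_hypo_chh_at_up_loci(self):
        spans = {"up1": GenomicInterval("c", 10_000, 12_000),
                 "down1": GenomicInterval("c", 50_000, 52_000)}
        dmrs = [DMR(GenomicInterval("c", 10_500, 10_700), "CHH", "hypo",
                    -0.3, 1e-4),
                DMR(GenomicInterval("c", 11_000, 11_300), "CHH", "hypo",
                    -0.2, 1e-4),
                DMR(GenomicInterval("c", 50_500, 50_900), "CG", "hyper",
                    0.3, 1e-4)]
        out = dmr_expression_association(dmrs, spans,
                                         {"up1": "Up", "down1": "Down"})
        assert out.at["Up", "prop_hypo"] == 1.0
        assert out.at["Up", "prop_CHH"] == 1.0
        assert out.at["Down", "prop_hyper"] == 1.0

    def test_greatest_overlap_assignment_and_tie(self):
        spans = {"L1": GenomicInterval("c", 1000, 2000),
                 "L2": GenomicInterval("c", 2000, 3000)}
        # overlaps L1's flank-extended span by more than L2's
        d1 = DMR(GenomicInterval("c", 900, 1500), "CG", "hypo", -0.2, 1e-3)
        got = assign_dmrs_to_loci([d1], spans, flank=0)
        assert got == {0: ["L1"]}
        # symmetric tie across the shared boundary: both flagged
        d2 = DMR(GenomicInterval("c", 1900, 2100), "CG", "hypo", -0.2, 1e-3)
        got = assign_dmrs_to_loci([d2], spans, flank=0)
        assert got == {0: ["L1", "L2"]}


class TestMethExprCorrelation:
    def test_exact_linear_anticorrelation(self):
        lfc = pd.Series({f"L{i}": v for i, v in enumerate(
            [-2.0, -1.0, 0.5, 1.5, 3.0])})
        delta = pd.DataFrame({"CG": -0.1 * lfc})
        out = methylation_expression_correlation(delta, lfc)
        assert out["CG"] == pytest.approx(-1.0)

    def test_too_few_loci_flagged(self):
        lfc = pd.Series({"a": 1.0, "b": 2.0})
        delta = pd.DataFrame({"CG": {"a": 0.1, "b": 0.2}})
        assert methylation_expression_correlation(delta, lfc)["CG"] is None

    def test_independent_pairs_near_zero(self):
        """Null: |r| < 0.15 in at least 95% of seeded replicates."""

        ok = 0
        for seed in range(40):
            rng = np.random.default_rng(200 + seed)
            loci = [f"L{i}" for i in range(500)]
            lfc = pd.Series(rng.normal(size=500), index=loci)
            delta = pd.DataFrame({"CG": rng.normal(size=500)}, index=loci)
            r = methylation_expression_correlation(delta, lfc)["CG"]
            ok += abs(r) < 0.15
        assert ok >= 38


class TestSimulatedMethylome:
    def test_boundary_pi_one(self, dataset):
        """Forcing methylation probability to ~1 makes every covered
        cytosine fully methylated (binomial boundary)."""

        from polylnc.simulate import SimConfig, simulate_methylome

        cfg = dataset.config
        sat = {k: {c: 1.0 for c in v} for k, v in cfg.meth_baseline.items()}
        import dataclasses as dc

        ds2_cfg = dc.replace(cfg, meth_baseline=sat, demeth_effect=0.0)
        # reuse the already built genome; only the baseline table differs
        old = dataset.config
        dataset.config = ds2_cfg
        try:
            frames = simulate_methylome(dataset,
                                        np.random.default_rng(0))
        finally:
            dataset.config = old
        f = frames["parent"]
        covered = f[f["n_total"] > 0]
        # pi clipped at 0.995: allow a tiny shortfall
        assert (covered["n_meth"] / covered["n_total"]).mean() > 0.99

    def test_planted_delta_recovered_at_reprogrammed_loci(self, dataset,
                                                          methylome):
        track_p = MethylationTrack.from_frame(methylome["parent"])
        track_f = MethylationTrack.from_frame(methylome["F1"])
        truth = dataset.truth
        rep = truth[truth["f1_class_truth"] != "Equal"]
        errs = []
        for lid, row in rep.iterrows():
            measured = (track_f.level(row["chrom"], row["start"], row["end"],
                                      "CG")
                        - track_p.level(row["chrom"], row["start"],
                                        row["end"], "CG"))
            if np.isfinite(measured):
                errs.append(measured - row["delta_meth_CG"])
        assert len(errs) > 10
        assert abs(float(np.mean(errs))) < 0.05
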