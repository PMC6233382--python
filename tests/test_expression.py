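"""RPKM, mid-parent mixing, the pooled exact DE test and its calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polylnc.core import CountMatrix, PolylncError
from polylnc.expression import (
    classify_de,
    de_percentage,
    de_summary,
    de_test,
    expression_correlation,
    in_silico_mix,
    rpkm,
)

from oracles import spearman_rank_pearson


def cm(data: dict, sizes: dict) -> CountMatrix:
    return CountMatrix(pd.DataFrame(data), pd.Series(sizes))


class TestRpkm:
    def test_closed_form(self):
        m = cm({"s": {"L1": 100}}, {"s": 10**6})
        out = rpkm(m, {"L1": 1000})
        assert out.at["L1", "s"] == pytest.approx(100.0)

    def test_zero_count_zero_rpkm(self):
        m = cm({"s": {"L1": 0}}, {"s": 10**6})
        assert rpkm(m, {"L1": 500}).at["L1", "s"] == 0.0

    def test_zero_length_errors(self):
        m = cm({"s": {"L1": 5}}, {"s": 100})
        with pytest.raises(PolylncError):
            rpkm(m, {"L1": 0})

    def test_random_matrix_matches_formula_recomputation(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, (20, 4)),
                              index=[f"L{i}" for i in range(20)],
                              columns=list("abcd"))
        sizes = pd.Series(rng.integers(10**5, 10**6, 4), index=list("abcd"))
        lengths = {f"L{i}": int(l) for i, l in
                   enumerate(rng.integers(200, 5000, 20))}
        out = rpkm(CountMatrix(counts, sizes), lengths)
        for locus in counts.index:      # independent cell-by-cell recompute
            for s in counts.columns:
                expected = (counts.at[locus, s] * 1e9
                            / (lengths[locus] * sizes[s]))
                assert out.at[locus, s] == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 7))
    def test_scaling_invariance(self, c):
        counts = pd.DataFrame({"s": {"L1": 40, "L2": 7}})
        base = rpkm(CountMatrix(counts, pd.Series({"s": 1000})),
                    {"L1": 300, "L2": 700})
        scaled = rpkm(CountMatrix(counts * c, pd.Series({"s": 1000 * c})),
                      {"L1": 300, "L2": 700})
        assert np.allclose(base, scaled)


class TestMix:
    def test_identical_parents_idempotent(self):
        a = cm({"a1": {"L1": 10, "L2": 40}}, {"a1": 1000})
        b = cm({"b1": {"L1": 10, "L2": 40}}, {"b1": 1000})
        mix = in_silico_mix(a, b)
        assert list(mix.counts["mix_rep1"]) == [10, 40]
        assert mix.library_sizes["mix_rep1"] == 1000

    def test_parent_specific_locus_halved(self):
        a = cm({"a1": {"L1": 40}}, {"a1": 1000})
        b = cm({"b1": {"L2": 8}}, {"b1": 1000})
        mix = in_silico_mix(a, b)
        assert mix.counts.at["L1", "mix_rep1"] == 20
        assert mix.counts.at["L2", "mix_rep1"] == 4

    def test_replicate_mismatch_pairs_by_sorted_order(self):
        a = cm({"a2": {"L1": 10}, "a1": {"L1": 30}}, {"a2": 1000, "a1": 1000})
        b = cm({"b1": {"L1": 50}}, {"b1": 1000})
        mix = in_silico_mix(a, b)
        # one pair only: sorted-first parent replicate a1 with b1
        assert mix.sample_ids == ["mix_rep1"]
        assert mix.counts.at["L1", "mix_rep1"] == 40

    def test_mix_rpkm_is_mean_of_parent_rpkms(self):
        """Algebraic identity of count-level 1:1 mixing, within rounding."""

        rng = np.random.default_rng(1)
        loci = [f"L{i}" for i in range(30)]
        a = cm({"a1": dict(zip(loci, rng.integers(100, 3000, 30)))},
               {"a1": 200_000})
        b = cm({"b1": dict(zip(loci, rng.integers(100, 3000, 30)))},
               {"b1": 300_000})
        lengths = {l: 1000 for l in loci}
        mix = in_silico_mix(a, b)
        r_mix = rpkm(mix, lengths)["mix_rep1"]
        r_mean = ((rpkm(a, lengths)["a1"] + rpkm(b, lengths)["b1"]) / 2
                  ).reindex(r_mix.index)
        assert np.allclose(r_mix, r_mean, rtol=0.02, atol=0.05)


class TestDeTest:
    def test_equal_counts_p_one(self):
        a = pd.DataFrame({"a1": {"L": 50}, "a2": {"L": 50}})
        b = pd.DataFrame({"b1": {"L": 50}, "b2": {"L": 50}})
        out = de_test(a, b)
        assert out.at["L", "p_value"] == pytest.approx(1.0)
        assert out.at["L", "log2fc"] == pytest.approx(0.0)

    def test_all_zero_locus_degenerate(self):
        a = pd.DataFrame({"a1": {"L": 0}, "a2": {"L": 0}})
        b = pd.DataFrame({"b1": {"L": 0}, "b2": {"L": 0}})
        out = de_test(a, b)
        assert out.at["L", "p_value"] == 1.0
        assert out.at["L", "log2fc"] == 0.0

    def test_strong_difference_significant_among_null_loci(self):
        rng = np.random.default_rng(9)
        null = rng.poisson(100, size=(100, 4))
        loci = [f"N{i}" for i in range(100)] + ["DE"]
        mat = np.vstack([null, [400, 380, 50, 60]])
        a = pd.DataFrame(mat[:, :2], index=loci, columns=["a1", "a2"])
        b = pd.DataFrame(mat[:, 2:], index=loci, columns=["b1", "b2"])
        out = de_test(a, b)
        assert out.at["DE", "p_value"] < 1e-6
        assert out.at["DE", "log2fc"] > 2

    def test_library_sizes_rescue_degenerate_locus_set(self):
        # single-locus frame: the ratio median alone would absorb the
        # signal; explicit library sizes keep the depths honest
        a = pd.DataFrame({"a1": {"L": 400}, "a2": {"L": 380}})
        b = pd.DataFrame({"b1": {"L": 50}, "b2": {"L": 60}})
        libs = pd.Series({"a1": 10**5, "a2": 10**5, "b1": 10**5, "b2": 10**5})
        out = de_test(a, b, library_sizes=libs)
        assert out.at["L", "p_value"] < 1e-6

    def test_null_type_one_error_within_documented_bounds(self):
        """Negative-binomial null (dispersion 0.1, low-expression regime,
        2000 loci x 20 seeds): rejection rate at alpha = 0.01 stays within
        the documented [0.002, 0.05] band."""

        rates = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            mean, disp, n = 5.0, 0.1, 2000
            r = 1.0 / disp
            p = r / (r + mean)
            a = pd.DataFrame({
                "a1": rng.negative_binomial(r, p, n),
                "a2": rng.negative_binomial(r, p, n),
            })
            b = pd.DataFrame({
                "b1": rng.negative_binomial(r, p, n),
                "b2": rng.negative_binomial(r, p, n),
            })
            out = de_test(a, b)
            rates.append((out["p_value"] < 0.01).mean())
        overall = float(np.mean(rates))
        assert 0.002 <= overall <= 0.05


class TestClassify:
    def test_paper_printed_percentages(self):
        # printed numerator/denominator pairs reproduce to two decimals;
        # the ovule pair arithmetically gives 50.04, not a round 50
        assert de_percentage(73, 4281) == 1.71
        assert de_percentage(1999, 5752) == 34.75
        assert de_percentage(2594, 5184) == 50.04

    def test_no_expressed_loci_flagged(self):
        assert de_percentage(0, 0) is None

    def test_class_thresholds(self):
        tests = pd.DataFrame({
            "p_value": {"up": 1e-5, "down": 1e-5, "eq_p": 0.5,
                        "eq_fc": 1e-5, "off": 1e-9},
            "log2fc": {"up": 2.0, "down": -2.0, "eq_p": 3.0,
                       "eq_fc": 0.5, "off": 5.0},
        })
        ra = pd.Series({"up": 10, "down": 1, "eq_p": 10, "eq_fc": 5,
                        "off": 0.2})
        rb = pd.Series({"up": 1, "down": 10, "eq_p": 1, "eq_fc": 4,
                        "off": 0.1})
        cls = {r.locus_id: r.de_class
               for r in classify_de(ra, rb, tests)}
        assert cls == {"up": "Up", "down": "Down", "eq_p": "Equal",
                       "eq_fc": "Equal", "off": "NotExpressed"}

    def test_summary_counts_consistent(self):
        tests = pd.DataFrame({"p_value": {"a": 1e-9, "b": 0.9},
                              "log2fc": {"a": 3.0, "b": 0.0}})
        recs = classify_de(pd.Series({"a": 50, "b": 3}),
                           pd.Series({"a": 2, "b": 3}), tests)
        s = de_summary(recs)
        assert s["n_expressed"] == 2 and s["n_de"] == 1
        assert s["pct_de"] == 50.0


class TestCorrelation:
    def test_identity_and_reversal(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert expression_correlation(x, x) == pytest.approx(1.0)
        assert expression_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        assert expression_correlation([1, 1, 1], [1, 2, 3]) is None

    def test_short_vector_rejected(self):
        with pytest.raises(PolylncError):
            expression_correlation([1, 2], [3, 4])

    def test_ties_match_manual_rank_then_pearson(self):
        rng = np.random.default_rng(5)
        x = list(rng.integers(0, 6, 20).astype(float))   # heavy ties
        y = list(rng.integers(0, 6, 20).astype(float))
        got = expression_correlation(x, y)
        assert got == pytest.approx(spearman_rank_pearson(x, y), rel=1e-9)


class TestPlantedRecovery:
    def test_midparent_additivity_without_reprogramming(self):
        """frac_f1_reprogrammed = 0: no systematic deviation from the
        mid-parent (the signed median log-ratio is near zero; per-locus
        spread reflects biological dispersion, not bias)."""

        from polylnc.simulate import (SimConfig, simulate_counts,
                                      simulate_genomes)

        ds = simulate_genomes(SimConfig(seed=21, frac_f1_reprogrammed=0.0))
        counts = simulate_counts(ds)
        ga = counts.subset_samples([s for s in counts.sample_ids
                                    if s.startswith("Ga")])
        gr = counts.subset_samples([s for s in counts.sample_ids
                                    if s.startswith("Gr")])
        f1 = counts.subset_samples([s for s in counts.sample_ids
                                    if s.startswith("F1")])
        mix = in_silico_mix(ga, gr)
        f1m = f1.counts.mean(axis=1)
        mm = mix.counts.reindex(f1m.index).mean(axis=1)
        ok = (f1m > 0) & (mm > 0)
        med = np.median(np.log2(f1m[ok] / mm[ok]))
        assert abs(med) < 0.1

    def test_planted_up_down_recovery(self):
        """Four-fold planted effects recovered with sensitivity >= 0.9 and
        FDR <= 0.1 at p < 0.01, fold change > 2 / < 0.5."""

        from polylnc.simulate import (SimConfig, simulate_counts,
                                      simulate_genomes)

        sens_all, fdr_all = [], []
        for seed in (31, 32):
            cfg = SimConfig(seed=seed, reprogram_log2fc_lo=2.0,
                            reprogram_log2fc_hi=2.0)
            ds = simulate_genomes(cfg)
            counts = simulate_counts(ds)
            parts = {p: counts.subset_samples(
                [s for s in counts.sample_ids if s.startswith(p)])
                for p in ("Ga", "Gr", "F1")}
            mix = in_silico_mix(parts["Ga"], parts["Gr"])
            tests = de_test(parts["F1"].counts,
                            mix.counts.reindex(parts["F1"].counts.index))
            lengths = {t.locus_id: t.spliced_length
                       for g in "AD" for t in ds.lnc[g] + ds.pcg[g]}
            lnc_ids = list(ds.truth.index)
            ra = rpkm(parts["F1"], lengths).mean(axis=1)[lnc_ids]
            rb = rpkm(mix, lengths).mean(axis=1).reindex(lnc_ids)
            cls = {r.locus_id: r.de_class for r in
                   classify_de(ra, rb, tests.loc[lnc_ids])}
            truth = ds.truth["f1_class_truth"]
            tp = sum(1 for l in lnc_ids
                     if truth[l] in ("Up", "Down") and cls[l] == truth[l])
            called = sum(1 for l in lnc_ids if cls[l] in ("Up", "Down"))
            fp = sum(1 for l in lnc_ids
                     if cls[l] in ("Up", "Down") and truth[l] == "Equal")
            n_true = (truth != "Equal").sum()
            sens_all.append(tp / n_true)
            fdr_all.append(fp / max(1, called))
        assert np.mean(sens_all) >= 0.9
        assert np.mean(fdr_all) <= 0.1
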