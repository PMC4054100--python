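"""Expression counting, exact binomial differentials, densities and the
shifted-window read-through control."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, kstest

from retrocount.annotation import TagSet
from retrocount.expression import (activation_fraction, binom_two_sided,
                                   count_expression, differential_expression,
                                   fold_change_density, readthrough_control,
                                   strand_bias_test)
from conftest import brute_force_assign, make_repeats, random_scene


def reads_from(rows):
    return TagSet("rna", pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand"]))


class TestCounting:
    ann = make_repeats([
        ("chr1", 100, 200, "+", "IAPEz-int", "ERVK", "LTR"),
        ("chr1", 300, 400, "-", "L1Md_A", "L1", "LINE"),
    ])

    def test_no_reads_all_zero(self):
        counts = count_expression(
            {"control": reads_from([]), "mutant": reads_from([])}, self.ann)
        assert (counts[["count_control", "count_mutant"]] == 0).all().all()

    def test_strand_modes_and_split_conservation(self):
        rows = [("chr1", 150, 160, "+"), ("chr1", 150, 160, "-"),
                ("chr1", 350, 360, "-"), ("chr1", 350, 360, "-")]
        counts = count_expression(
            {"mutant": reads_from(rows)}, self.ann,
            strand_mode="split").set_index("locus_id")
        lo, li = self.ann["locus_id"]
        assert counts.loc[lo, "count_mutant"] == 2
        assert counts.loc[lo, "sense_mutant"] == 1
        assert counts.loc[li, "sense_mutant"] == 2  # minus-strand locus
        total = counts[["sense_mutant", "antisense_mutant"]].sum(axis=1)
        assert (total == counts["count_mutant"]).all()
        sense_only = count_expression({"mutant": reads_from(rows)}, self.ann,
                                      strand_mode="sense").set_index("locus_id")
        assert sense_only.loc[lo, "count_mutant"] == 1

    def test_unknown_strand_mode_rejected(self):
        with pytest.raises(ValueError):
            count_expression({"m": reads_from([])}, self.ann, strand_mode="both")

    def test_matches_brute_force_oracle(self):
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            ann, tags = random_scene(rng, n_loci=25, n_tags=300)
            counts = count_expression(
                {"x": TagSet("x", tags)}, ann).set_index("locus_id")
            expected = pd.Series(brute_force_assign(tags, ann)).value_counts()
            for locus in ann["locus_id"]:
                assert counts.loc[locus, "count_x"] == expected.get(locus, 0)


class TestDifferential:
    def make_counts(self, pairs):
        return pd.DataFrame({
            "locus_id": [f"l{i}" for i in range(len(pairs))],
            "count_control": [c for c, _ in pairs],
            "count_mutant": [m for _, m in pairs],
        })

    def test_equal_counts_equal_depth(self):
        out = differential_expression(
            self.make_counts([(10, 10)]), {"control": 1000, "mutant": 1000})
        assert out.loc[0, "norm_log2fc"] == 0.0
        assert out.loc[0, "p_value"] == 1.0

    def test_one_sided_extreme_doubles_tail(self):
        out = differential_expression(
            self.make_counts([(0, 12)]), {"control": 1000, "mutant": 1000})
        assert out.loc[0, "p_value"] == pytest.approx(2 * 0.5 ** 12)

    def test_swap_negates_fold_change_exactly(self):
        rng = np.random.default_rng(2)
        pairs = [(int(a), int(b)) for a, b in rng.integers(0, 50, size=(40, 2))]
        sizes = {"control": 5_000, "mutant": 8_000}
        fwd = differential_expression(self.make_counts(pairs), sizes)
        swapped = self.make_counts([(m, c) for c, m in pairs])
        rev = differential_expression(
            swapped, {"control": 8_000, "mutant": 5_000})
        assert np.allclose(fwd["norm_log2fc"], -rev["norm_log2fc"])

    def test_min_total_gates_bh_family(self):
        out = differential_expression(
            self.make_counts([(1, 2), (30, 3)]),
            {"control": 1000, "mutant": 1000}, min_total=5)
        assert not out.loc[0, "informative"] and np.isnan(out.loc[0, "p_bh"])
        assert out.loc[1, "informative"] and np.isfinite(out.loc[1, "p_bh"])

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            differential_expression(self.make_counts([(1, 1)]),
                                    {"control": 0, "mutant": 10})

    def test_binomial_two_sided_matches_tail_sums(self):
        for k, n, p in [(3, 10, 0.5), (9, 10, 0.3), (0, 6, 0.8), (5, 5, 0.5)]:
            lower = binom.cdf(k, n, p)
            upper = binom.sf(k - 1, n, p)
            assert binom_two_sided(k, n, p) == pytest.approx(
                min(1.0, 2 * min(lower, upper)))


class TestDensity:
    def test_single_value_peak_height(self):
        d = fold_change_density(np.array([2.0]), bandwidth=0.5)
        # the analytic kernel peak, up to the finite evaluation grid
        assert d.density.max() == pytest.approx(
            1 / (0.5 * np.sqrt(2 * np.pi)), rel=1e-3)
        assert abs(d.grid[np.argmax(d.density)] - 2.0) < 0.05

    def test_symmetric_values_symmetric_tails(self):
        vals = np.array([-6.0, 6.0, -6.0, 6.0, 0.0])
        d = fold_change_density(vals)
        assert d.frac_above == d.frac_below == pytest.approx(0.4)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(3)
        d = fold_change_density(rng.normal(size=400))
        assert np.trapezoid(d.density, d.grid) == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_values_histogram_fallback(self):
        d = fold_change_density(np.zeros(10))
        assert d.histogram_fallback
        assert d.frac_above == d.frac_below == 0.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            fold_change_density(np.array([1.0]), subset=np.array([False]))


class TestActivationFraction:
    def test_all_positive_is_one(self):
        rec = pd.DataFrame({"norm_log2fc": [0.2, 3.0, 5.0],
                            "informative": [True, True, True]})
        assert activation_fraction(rec) == 1.0

    def test_empty_informative_set_is_missing(self):
        rec = pd.DataFrame({"norm_log2fc": [1.0], "informative": [False]})
        assert np.isnan(activation_fraction(rec))


class TestStrandBias:
    def test_worked_examples(self):
        assert strand_bias_test(10, 10) == 1.0
        assert strand_bias_test(12, 0) == pytest.approx(2 * 0.5 ** 12)

    def test_null_p_values_uniform(self):
        """Under symmetric strand sampling at satellite-aggregate depth the
        exact test's p-values are uniform (KS at alpha=0.01)."""
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            total = rng.poisson(2_000)
            sense = rng.binomial(total, 0.5)
            ps.append(strand_bias_test(sense, total - sense))
        assert kstest(ps, "uniform").pvalue > 0.01


class TestReadthroughControl:
    def test_constructed_autonomous_and_readthrough(self):
        ann = make_repeats([
            ("chr1", 50_000, 52_000, "+", "IAPEz-int", "ERVK", "LTR"),
            ("chr1", 90_000, 92_000, "+", "IAPLTR1", "ERVK", "LTR"),
        ])
        auto_id, rt_id = ann["locus_id"]
        rng = np.random.default_rng(5)

        def uniform_reads(lo, hi, n):
            starts = rng.integers(lo, hi - 50, size=n)
            return [("chr1", int(s), int(s) + 50, "+") for s in starts]

        # autonomous locus: body-only activation; read-through locus:
        # transcript tiling from 12 kb upstream through the locus
        control = uniform_reads(50_000, 52_000, 10) + \
            uniform_reads(78_000, 92_000, 10) + \
            uniform_reads(10_000, 40_000, 400)
        mutant = uniform_reads(50_000, 52_000, 300) + \
            uniform_reads(78_000, 92_000, 300) + \
            uniform_reads(10_000, 40_000, 400)
        out = readthrough_control(
            {"control": reads_from(control), "mutant": reads_from(mutant)},
            ann).set_index("locus_id")
        assert out.loc[auto_id, "classification"] == "autonomous"
        assert out.loc[auto_id, "up_p_bh"] >= 0.05 or np.isnan(
            out.loc[auto_id, "up_p_bh"])
        assert out.loc[rt_id, "classification"] == "read_through"

    def test_flagged_window_not_called_readthrough(self):
        # upstream window of the second locus lands on the first repeat
        ann = make_repeats([
            ("chr1", 39_500, 42_500, "+", "IAPEz-int", "ERVK", "LTR"),
            ("chr1", 50_000, 52_000, "+", "IAPLTR1", "ERVK", "LTR"),
        ])
        rng = np.random.default_rng(6)

        def uniform_reads(lo, hi, n):
            starts = rng.integers(lo, hi - 50, size=n)
            return [("chr1", int(s), int(s) + 50, "+") for s in starts]

        control = uniform_reads(39_500, 42_500, 10) + \
            uniform_reads(50_000, 52_000, 10) + uniform_reads(0, 30_000, 200)
        mutant = uniform_reads(39_500, 42_500, 400) + \
            uniform_reads(50_000, 52_000, 400) + uniform_reads(0, 30_000, 200)
        out = readthrough_control(
            {"control": reads_from(control), "mutant": reads_from(mutant)},
            ann).set_index("locus_id")
        second = ann.loc[1, "locus_id"]
        assert bool(out.loc[second, "up_flagged"])
        assert out.loc[second, "classification"] == "autonomous"


class TestPlantedExpressionRecovery:
    def test_activated_loci_recovered(self, coupled_scenes):
        """Planted +5 log2FC loci are called at BH<0.05 with sensitivity
        >=90% at the default per-locus depth."""
        tp = n_planted = 0
        for bundle in coupled_scenes:
            scene, expr = bundle["scene"], bundle["expr"]
            planted = set(scene.truth.locus_expr_log2fc)
            called = set(expr.loc[
                (expr["p_bh"] < 0.05) & (expr["norm_log2fc"] > 0), "locus_id"])
            tp += len(called & planted)
            n_planted += len(planted)
        assert tp / n_planted >= 0.90
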