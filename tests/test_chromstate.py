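import math

import numpy as np
import pandas as pd
import pytest

from bivalint import chromstate as cs
from bivalint import synthetic_data as sd
from bivalint.io_formats import GeneAnnotation, make_peakset


def brute_overlap(a_intervals, b_intervals):
    """O(n*m) interval overlap: does each a-interval touch any b-interval?"""
    out = []
    for ca, sa, ea in a_intervals:
        hit = any(cb == ca and sb < ea and eb > sa for cb, sb, eb in b_intervals)
        out.append(hit)
    return out


class TestPromoters:
    def test_symmetric_window_and_strand_invariance(self, small_annotation):
        prom = cs.make_promoters(small_annotation, 3000)
        assert tuple(prom.table.loc["PGR", ["start", "end"]]) == (8500, 11500)
        # minus-strand gene: same symmetric window
        assert tuple(prom.table.loc["ESR1", ["start", "end"]]) == (48500, 51500)

    def test_clipping_at_chromosome_start(self):
        ann = GeneAnnotation(
            pd.DataFrame(
                {"chrom": ["chr1"], "strand": ["+"], "tss": [1000]},
                index=pd.Index(["A"], name="gene"),
            )
        )
        prom = cs.make_promoters(ann, 3000)
        assert tuple(prom.table.loc["A", ["start", "end"]]) == (0, 2500)

    def test_odd_width_rejected(self, small_annotation):
        with pytest.raises(ValueError, match="even"):
            cs.make_promoters(small_annotation, 3001)


class TestConsensusPeaks:
    def test_identical_replicates_identity(self):
        ps = make_peakset("m", 1, ["chr1", "chr1"], [100, 500], [200, 600], [3, 4])
        out = cs.consensus_peaks(ps, make_peakset("m", 2, ["chr1", "chr1"], [100, 500], [200, 600], [3, 4]))
        assert list(out.intervals["start"]) == [100, 500]
        assert list(out.intervals["end"]) == [200, 600]

    def test_rep1_only_peak_dropped(self):
        r1 = make_peakset("m", 1, ["chr1", "chr1"], [100, 900], [200, 950])
        r2 = make_peakset("m", 2, ["chr1"], [150], [250])
        out = cs.consensus_peaks(r1, r2)
        assert len(out) == 1

    def test_union_rule_hand_oracle(self):
        r1 = make_peakset("m", 1, ["chr1"], [100], [300])
        r2 = make_peakset("m", 2, ["chr1"], [250], [400])
        out = cs.consensus_peaks(r1, r2)
        assert tuple(out.intervals.iloc[0][["start", "end"]]) == (100, 400)

    def test_mark_mismatch_rejected(self):
        a = make_peakset("H3K4me3", 1, ["chr1"], [0], [10])
        b = make_peakset("H3K27me3", 2, ["chr1"], [0], [10])
        with pytest.raises(ValueError, match="mark"):
            cs.consensus_peaks(a, b)


class TestFlagPromoterOverlap:
    def test_half_open_boundary(self, small_annotation):
        prom = cs.make_promoters(small_annotation, 3000)
        # PGR promoter is [8500, 11500): abutting peak at 11500 must not hit
        abutting = make_peakset("m", 0, ["chr1"], [11500], [12000])
        assert not cs.flag_promoter_overlap(prom, abutting)["PGR"]
        one_bp = make_peakset("m", 0, ["chr1"], [11499], [12000])
        assert cs.flag_promoter_overlap(prom, one_bp)["PGR"]

    def test_matches_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(17)
        n = 100
        ann = GeneAnnotation(
            pd.DataFrame(
                {
                    "chrom": rng.choice(["c1", "c2"], n),
                    "strand": rng.choice(["+", "-"], n),
                    "tss": rng.integers(2000, 100_000, n),
                },
                index=pd.Index([f"G{i}" for i in range(n)], name="gene"),
            )
        )
        prom = cs.make_promoters(ann, 2000)
        starts = np.sort(rng.integers(0, 100_000, n))
        peaks = make_peakset(
            "m", 0, rng.choice(["c1", "c2"], n), starts, starts + rng.integers(1, 5000, n)
        )
        got = cs.flag_promoter_overlap(prom, peaks)
        want = brute_overlap(
            list(prom.table[["chrom", "start", "end"]].itertuples(index=False)),
            list(peaks.intervals[["chrom", "start", "end"]].itertuples(index=False)),
        )
        assert list(got.values) == want


class TestClassifyStates:
    def test_partition_and_bivalent_rule(self):
        genes = pd.Index(["A", "B", "C", "D"], name="gene")
        k4 = pd.Series([True, True, False, False], index=genes)
        k27 = pd.Series([True, False, True, False], index=genes)
        table, summary = cs.classify_states(k4, k27)
        assert table.table.loc["A", "state"] == "bivalent"
        assert table.table.loc["B", "state"] == "K4-only"
        assert table.table.loc["C", "state"] == "K27-only"
        assert table.table.loc["D", "state"] == "neither"
        assert sum(summary[s] for s in cs.STATES) == summary["universe"] == 4

    def test_planted_states_recovered_exactly_without_decoys(self):
        truth, ann = sd.generate_truth(400, seed=31)
        peaks = sd.generate_peaks(truth, ann, seed=32, decoy_fraction=0.0)
        prom = cs.make_promoters(ann, 3000)
        k4 = cs.flag_promoter_overlap(prom, cs.consensus_peaks(*peaks["H3K4me3"]))
        k27 = cs.flag_promoter_overlap(prom, cs.consensus_peaks(*peaks["H3K27me3"]))
        table, summary = cs.classify_states(k4, k27)
        assert (table.table["state"] == truth.table["chromatin_state"]).all()
        assert sum(summary[s] for s in cs.STATES) == len(truth)

    def test_single_replicate_decoys_removed_by_consensus(self):
        truth, ann = sd.generate_truth(400, seed=31)
        peaks = sd.generate_peaks(truth, ann, seed=32, decoy_fraction=0.3)
        prom = cs.make_promoters(ann, 3000)
        k4 = cs.flag_promoter_overlap(prom, cs.consensus_peaks(*peaks["H3K4me3"]))
        k27 = cs.flag_promoter_overlap(prom, cs.consensus_peaks(*peaks["H3K27me3"]))
        table, _ = cs.classify_states(k4, k27)
        assert (table.table["state"] == truth.table["chromatin_state"]).all()


def hypergeom_tail_enumeration(M, nA, nB, k):
    """P(overlap >= k) by direct enumeration of the hypergeometric pmf."""
    total = math.comb(M, nB)
    acc = 0
    for j in range(k, min(nA, nB) + 1):
        if nA >= j and M - nA >= nB - j:
            acc += math.comb(nA, j) * math.comb(M - nA, nB - j)
    return acc / total


class TestHypergeometric:
    def test_worked_example(self):
        U = set(range(10))
        A = set(range(5))
        B = {0, 1, 2, 3}
        st = cs.hypergeometric_enrichment(A, B, U)
        assert st.overlap == 4
        assert st.p_hyper == pytest.approx(
            (math.comb(5, 4) * math.comb(5, 0)) / math.comb(10, 4), rel=1e-12
        )
        assert st.expected == pytest.approx(2.0)

    def test_degenerate_cases(self):
        U = set(range(6))
        st = cs.hypergeometric_enrichment({0, 1}, {2, 3}, U)
        assert st.overlap == 0 and st.p_hyper == pytest.approx(1.0)
        st2 = cs.hypergeometric_enrichment(U, {1, 2}, U)
        assert st2.overlap == 2 and st2.p_hyper == pytest.approx(1.0)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            cs.hypergeometric_enrichment({"x"}, {"a"}, {"a", "b"})

    def test_matches_enumeration_for_all_small_universes(self):
        for M in range(1, 13):
            for nA in range(M + 1):
                for nB in range(M + 1):
                    for k in range(max(0, nA + nB - M), min(nA, nB) + 1):
                        A = set(range(nA))
                        B = set(range(k)) | set(range(nA, nA + nB - k))
                        st = cs.hypergeometric_enrichment(A, B, set(range(M)))
                        assert st.overlap == k
                        assert st.p_hyper == pytest.approx(
                            hypergeom_tail_enumeration(M, nA, nB, k), rel=1e-9, abs=1e-12
                        )


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities <= observed."""
    r1, n1 = a + b, a + c
    N = a + b + c + d
    def pmf(x):
        return (
            math.comb(n1, x) * math.comb(N - n1, r1 - x) / math.comb(N, r1)
            if 0 <= x <= n1 and 0 <= r1 - x <= N - n1
            else 0.0
        )
    p_obs = pmf(a)
    return sum(p for x in range(min(r1, n1) + 1) if (p := pmf(x)) <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_worked_example(self):
        # table [[2,0],[0,2]]: both extremes have probability 1/6 -> p = 1/3
        x = pd.Series([True, True, False, False])
        y = pd.Series([True, True, False, False])
        st = cs.fisher_association(x, y)
        assert st.p_fisher == pytest.approx(1 / 3, rel=1e-12)
        assert st.degenerate  # identical flags: zero off-diagonal cells
        assert np.isfinite(st.odds_ratio)

    def test_matches_enumeration_for_all_small_tables(self):
        for N in range(2, 13):
            for a in range(N + 1):
                for b in range(N + 1 - a):
                    for c in range(N + 1 - a - b):
                        d = N - a - b - c
                        x = np.array([True] * (a + b) + [False] * (c + d))
                        y = np.array([True] * a + [False] * b + [True] * c + [False] * d)
                        st = cs.fisher_association(x, y)
                        assert st.p_fisher == pytest.approx(
                            fisher_two_sided_enumeration(a, b, c, d), rel=1e-7, abs=1e-12
                        )

    def test_null_calibration(self):
        rng = np.random.default_rng(23)
        ps = []
        for _ in range(300):
            x = rng.random(60) < 0.5
            y = rng.random(60) < 0.5
            ps.append(cs.fisher_association(x, y).p_fisher)
        # exact test is conservative; check it is not anti-conservative
        assert np.mean(np.asarray(ps) < 0.05) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 300)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cs.fisher_association(np.array([], dtype=bool), np.array([], dtype=bool))


class TestExpressionByState:
    @staticmethod
    def make_states(n_per_state, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for state, n in n_per_state.items():
            rows += [state] * n
        genes = pd.Index([f"g{i}" for i in range(len(rows))], name="gene")
        k4 = pd.Series([s in ("bivalent", "K4-only") for s in rows], index=genes)
        k27 = pd.Series([s in ("bivalent", "K27-only") for s in rows], index=genes)
        table, _ = cs.classify_states(k4, k27)
        return table

    def test_planted_difference_detected(self):
        states = self.make_states({"K4-only": 60, "K27-only": 60})
        rng = np.random.default_rng(3)
        expr = pd.Series(0.0, index=states.genes)
        is_k4 = states.table["state"] == "K4-only"
        expr[is_k4] = rng.lognormal(4, 0.5, int(is_k4.sum()))
        expr[~is_k4] = rng.lognormal(1, 0.5, int((~is_k4).sum()))
        out = cs.expression_by_state(expr, states, groups=[("K4-only", "K27-only")])
        row = out.iloc[0]
        assert row["median1"] > row["median2"]
        assert row["pvalue"] < 0.01

    def test_null_pvalue_not_anticonservative(self):
        states = self.make_states({"K4-only": 50, "K27-only": 50})
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(200):
            expr = pd.Series(rng.normal(size=100), index=states.genes)
            p = cs.expression_by_state(expr, states, groups=[("K4-only", "K27-only")])["pvalue"][0]
            hits += p < 0.05
        assert hits / 200 <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_small_group_warns_and_nan(self):
        states = self.make_states({"K4-only": 2, "K27-only": 10})
        expr = pd.Series(1.0, index=states.genes)
        with pytest.warns(UserWarning, match="< 3"):
            out = cs.expression_by_state(expr, states, groups=[("K4-only", "K27-only")])
        assert np.isnan(out["pvalue"][0])


class TestPromoterMarkVsExpression:
    def test_window_rule(self):
        tss = 100_000
        near = make_peakset("H3K27me3", 1, ["c"], [tss + 2000 - 250], [tss + 2000 + 250])
        far = make_peakset("H3K27me3", 2, ["c"], [tss + 3500 - 100], [tss + 3500 + 400])
        expr = np.array([1.0, 2.0, 3.0, 4.0])
        panels = [near, far, far, near]
        res = cs.promoter_mark_vs_expression(expr, panels, tss, "c", window=6000)
        assert list(res.marked) == [True, False, False, True]

    def test_empty_group_rejected(self):
        tss = 100_000
        near = make_peakset("m", 1, ["c"], [tss], [tss + 100])
        with pytest.raises(ValueError, match="unmarked"):
            cs.promoter_mark_vs_expression(
                np.array([1.0, 2.0, 3.0]), [near, near, near], tss, "c"
            )

    def test_power_on_simulated_panels(self):
        wins = 0
        for seed in range(100):
            expr, panel = sd.generate_crosssample_panel(56, 20, 0.2, seed=seed)
            res = cs.promoter_mark_vs_expression(expr, panel, 500_000, "chrP", 6000)
            wins += (res.mean_marked < res.mean_unmarked) and (res.pvalue < 0.05)
        assert wins >= 95
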