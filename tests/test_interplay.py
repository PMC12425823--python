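import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methevolve.diffmeth import compute_ubiquity
from methevolve.interplay import (
    allchat_test_pair,
    classify_gene_events,
    classify_interplay,
    detect_allchat,
    dosage_compensation_scan,
    filter_cnas_for_allchat,
    fisher_enrichment,
    make_allchat_pairs,
    timing_contingency,
    timing_patterns,
    timing_table_test,
)
from methevolve.io import build_promoters
from methevolve.simulate import simulate_allchat_candidates


def event_grid(rows):
    """rows: (gene, patient, region, hyper, hypo, loss, gain, amp)"""
    recs = [(g, f"{p}_{r}", p, r, h, hp, l, gn, a, False, False, 2)
            for g, p, r, h, hp, l, gn, a in rows]
    return pd.DataFrame(recs, columns=["gene_id", "sample_id", "patient_id",
                                       "region_id", "hyper", "hypo", "loss", "gain",
                                       "amplification", "mutation",
                                       "boundary_flagged", "n_t"])


class TestClassifyGeneEvents:
    def setup_inputs(self, n_t, ploidy=2.0):
        prom = build_promoters(pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "tss": [100_000], "strand": ["+"]}))
        seg = pd.DataFrame({"sample_id": ["s1"], "chrom": ["chr1"], "start": [1],
                            "end": [10**6], "n_t": [n_t], "n_n": [2]})
        ctx = pd.DataFrame([("s1", "p1", "R1", "tumor", 0.7, "x", ploidy)],
                           columns=["sample_id", "patient_id", "region_id",
                                    "tissue", "purity", "histology", "ploidy"])
        status = pd.DataFrame({"s1": ["none"]}, index=pd.Index(["g"], name="gene_id"))
        return status, seg, ctx, prom

    def test_diploid_single_copy_is_loss(self):
        ev = classify_gene_events(*self.setup_inputs(n_t=1))
        assert ev["loss"].iloc[0] and not ev["gain"].iloc[0]

    def test_high_copy_on_triploid_is_amplification(self):
        ev = classify_gene_events(*self.setup_inputs(n_t=6, ploidy=3.1))
        assert ev["amplification"].iloc[0] and not ev["loss"].iloc[0]

    def test_no_events_anywhere(self):
        ev = classify_gene_events(*self.setup_inputs(n_t=2))
        assert not ev[["hyper", "hypo", "loss", "gain", "amplification"]].to_numpy().any()

    def test_boundary_spanning_gene_flagged(self):
        status, _, ctx, prom = self.setup_inputs(n_t=2)
        seg = pd.DataFrame({"sample_id": ["s1", "s1"], "chrom": ["chr1", "chr1"],
                            "start": [1, 99_000], "end": [98_999, 10**6],
                            "n_t": [2, 3], "n_n": [2, 2]})
        ev = classify_gene_events(status, seg, ctx, prom)
        assert ev["boundary_flagged"].iloc[0]


class TestInterplay:
    def test_double_hit(self):
        ev = event_grid([("g", "p", "R1", True, False, False, False, False),
                         ("g", "p", "R2", True, False, True, False, False)])
        out = classify_interplay(ev)
        assert out["category"].iloc[0] == "double_hit"

    def test_parallel(self):
        ev = event_grid([("g", "p", "R1", True, False, False, False, False),
                         ("g", "p", "R2", False, False, True, False, False)])
        assert classify_interplay(ev)["category"].iloc[0] == "parallel"

    def test_hypo_with_gain_is_concordant(self):
        ev = event_grid([("g", "p", "R1", False, True, False, True, False)])
        out = classify_interplay(ev)
        assert out["concordant_fraction"].iloc[0] == 1.0
        assert out["category"].iloc[0] == "other"

    def test_categories_partition(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in range(20):
            for p in range(3):
                for r in range(3):
                    rows.append((f"g{g}", f"p{p}", f"R{r}",
                                 *(rng.random(5) < 0.2)))
        out = classify_interplay(event_grid(rows))
        assert len(out) == 60
        assert out["category"].isin(["double_hit", "parallel", "single_mechanism",
                                     "other", "none"]).all()


class TestTiming:
    def ub(self, feature, patient, present_regions, total=3):
        return pd.DataFrame({
            "feature_id": feature, "patient_id": patient,
            "region_id": [f"R{i}" for i in range(total)],
            "present": [i in present_regions for i in range(total)],
        })

    def test_pattern_labels(self):
        hyper = compute_ubiquity(self.ub("g", "p", {0, 1, 2}))
        loss = compute_ubiquity(self.ub("g", "p", {0}))
        pat = timing_patterns(hyper, loss)
        assert pat["pattern"].iloc[0] == "clonal_hyper_subclonal_loss"

    def test_chi_squared_matches_hand_oracle(self):
        table = np.array([[84, 27], [28, 38]])
        res = timing_table_test(table)
        # hand chi-squared without continuity correction
        exp = stats.contingency.expected_freq(table)
        chi2 = ((table - exp) ** 2 / exp).sum()
        assert res["test"] == "chi2"
        assert res["statistic"] == pytest.approx(chi2)
        assert res["p_value"] == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_identical_distributions_p_near_one(self):
        res = timing_table_test(np.array([[50, 50], [50, 50]]))
        assert res["p_value"] == pytest.approx(1.0)

    def test_small_expected_switches_to_exact(self):
        res = timing_table_test(np.array([[2, 1], [1, 3]]))
        assert res["test"] == "fisher_exact" and "notice" in res

    def test_planted_ordering_recovered_from_calls(self):
        # methylation-early set: mostly clonal hyper + subclonal loss
        rows_a, rows_b = [], []
        for i in range(30):
            rows_a.append((f"a{i}", "p", "clonal_hyper_subclonal_loss"))
            rows_b.append((f"b{i}", "p", "clonal_loss_subclonal_hyper"))
        for i in range(5):
            rows_a.append((f"a{30+i}", "p", "clonal_loss_subclonal_hyper"))
            rows_b.append((f"b{30+i}", "p", "clonal_hyper_subclonal_loss"))
        calls_a = pd.DataFrame(rows_a, columns=["gene_id", "patient_id", "pattern"])
        calls_b = pd.DataFrame(rows_b, columns=["gene_id", "patient_id", "pattern"])
        res = timing_contingency(calls_a, calls_b)
        assert np.array_equal(res["table"], [[30, 5], [5, 30]])
        assert res["p_value"] < 0.01


class TestDosageCompensation:
    def build(self, meth_amp, meth_not, expr_amp, expr_not, n=6):
        samples = [f"s{i}" for i in range(2 * n)]
        amp = pd.DataFrame([[True] * n + [False] * n], index=["g"], columns=samples)
        meth = pd.DataFrame([[meth_amp] * n + [meth_not] * n], index=["g"], columns=samples)
        rng = np.random.default_rng(0)
        expr = pd.DataFrame([np.concatenate([
            expr_amp * rng.lognormal(0, 0.05, n), expr_not * rng.lognormal(0, 0.05, n)])],
            index=["g"], columns=samples)
        return meth, expr, amp

    def test_compensated_passenger_flagged_buffered(self):
        out = dosage_compensation_scan(*self.build(0.5, 0.2, 100, 100))
        rec = out.iloc[0]
        assert rec["flagged"] and rec["expression_class"] == "buffered"

    def test_scaling_oncogene_not_flagged(self):
        out = dosage_compensation_scan(*self.build(0.1, 0.3, 250, 100))
        rec = out.iloc[0]
        assert not rec["flagged"] and rec["expression_class"] == "scaling"

    def test_identical_strata_buffered_delta_zero(self):
        out = dosage_compensation_scan(*self.build(0.3, 0.3, 100, 100))
        rec = out.iloc[0]
        assert rec["delta_median_meth"] == 0.0 and rec["expression_class"] == "buffered"

    def test_too_few_regions_is_missing(self):
        out = dosage_compensation_scan(*self.build(0.5, 0.2, 100, 100, n=2))
        assert out.empty


class TestAllChAT:
    def test_planted_pair_detected_identical_pair_rejected(self):
        pairs, data = simulate_allchat_candidates(n_pairs=4, n_planted=2, seed=1)
        det = detect_allchat(pairs, data).set_index("pair_id")
        assert det.loc["pair000", "verdict"] and det.loc["pair001", "verdict"]
        assert not det.loc["pair002", "verdict"]

    def test_distance_rule_excludes_far_genes(self):
        prom = build_promoters(pd.DataFrame(
            {"gene_id": ["onc", "near", "far"], "chrom": ["chr1"] * 3,
             "tss": [10**6, 15 * 10**6, 26 * 10**6], "strand": ["+"] * 3}))
        pairs = make_allchat_pairs(["onc"], prom)
        assert set(pairs["passenger_id"]) == {"near"}

    def test_missing_histone_gives_partial_verdict(self):
        pairs, data = simulate_allchat_candidates(n_pairs=1, n_planted=1, seed=2)
        d = {k: v for k, v in data["pair000"].items() if k[1] == "meth"}
        ok, partial, _ = allchat_test_pair(d)
        assert partial and ok

    def test_monotone_in_effect_size(self):
        prev_verdicts = None
        for eff in (0.22, 0.3, 0.4, 0.6):
            pairs, data = simulate_allchat_candidates(
                n_pairs=10, n_planted=10, meth_effect=eff, seed=3)
            det = detect_allchat(pairs, data)
            v = det["verdict"].sum()
            if prev_verdicts is not None:
                assert v >= prev_verdicts  # strengthening never flips true->false
            prev_verdicts = v

    def test_nongained_require_mode_demands_reverse_margin(self):
        pairs, data = simulate_allchat_candidates(n_pairs=2, n_planted=2,
                                                  nongained_margin=0.0, seed=4)
        det = detect_allchat(pairs, data, nongained_mode="require")
        assert not det["verdict"].any()


class TestCNAFilter:
    def seg(self, span, n_t):
        return pd.DataFrame({"sample_id": ["s"], "chrom": ["chr1"], "start": [1],
                             "end": [span], "n_t": [n_t], "n_n": [2]})

    def test_small_gain_removed(self):
        out = filter_cnas_for_allchat(self.seg(49_900_000, 3), ploidy=2.0)
        assert out.empty

    def test_large_gain_retained(self):
        out = filter_cnas_for_allchat(self.seg(60_000_000, 3), ploidy=2.0)
        assert len(out) == 1 and out["direction"].iloc[0] == "gain"

    def test_empty_input_empty_output(self):
        empty = self.seg(1, 2).iloc[:0]
        assert filter_cnas_for_allchat(empty, ploidy=2.0).empty


def test_fisher_enrichment_matches_scipy():
    hits = {"a", "b", "c"}
    universe = {chr(ord("a") + i) for i in range(10)}
    annotation = {"a", "b", "z"}
    res = fisher_enrichment(hits, universe, annotation)
    ref = stats.fisher_exact(res["table"])
    assert res["p_value"] == pytest.approx(ref[1])
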