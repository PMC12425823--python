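import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methevolve.diffmeth import (
    call_dmps,
    call_dmps_cohort,
    call_dmrs,
    compute_dhcr,
    compute_ubiquity,
    dmp_pvalue,
    methsig_dmp_calls,
    promoter_methylation_status,
)
from methevolve.io import build_promoters, map_cpgs_to_promoters


class TestCallDMPs:
    def test_large_effect_insignificant_is_ns(self):
        # delta passes, p fails (tiny counts)
        res = call_dmps(np.array([0.9]), np.array([0.5]),
                        kb=np.array([3]), nb=np.array([4]),
                        kn=np.array([2]), nn=np.array([4]))
        assert res.status[0] == 0

    def test_small_effect_significant_is_ns(self):
        res = call_dmps(np.array([0.65]), np.array([0.50]),
                        kb=np.array([650]), nb=np.array([1000]),
                        kn=np.array([500]), nn=np.array([1000]))
        assert res.p_value[0] < 0.01 and res.status[0] == 0  # delta 0.15 < 0.2

    def test_hyper_call_and_exact_oracle_agreement(self):
        res = call_dmps(np.array([0.9]), np.array([0.2]),
                        kb=np.array([45]), nb=np.array([50]),
                        kn=np.array([10]), nn=np.array([50]))
        assert res.status[0] == 1
        oracle = stats.fisher_exact([[45, 5], [10, 40]])[1]
        assert (res.p_value[0] < 0.01) == (oracle < 0.01)

    def test_missing_normal_excluded_and_counted(self):
        res = call_dmps(np.array([0.9, 0.9]), np.array([0.2, np.nan]),
                        kb=np.array([45, 45]), nb=np.array([50, 50]),
                        kn=np.array([10, 0]), nn=np.array([50, 0]))
        assert res.status[1] == 0 and res.excluded[1] and res.n_skipped == 1

    def test_exact_fallback_matches_scipy_on_sparse_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            kb, nb = rng.integers(0, 4), 10
            kn, nn = rng.integers(0, 4), 12
            ours = dmp_pvalue(np.array([kb]), np.array([nb]),
                              np.array([kn]), np.array([nn]))[0]
            ref = stats.fisher_exact([[kb, nb - kb], [kn, nn - kn]])[1]
            # tail-doubling is never anti-conservative vs the two-sided exact p
            assert ours >= ref - 1e-12


def oracle_dmrs(is_dmp, chrom, pos, gap=100, min_run=4, min_total=5):
    """Literal re-implementation: chain CpGs within gap bp, scan runs."""
    order = np.lexsort((pos, chrom))
    bins = []
    cur = []
    for idx in order:
        if cur and chrom[idx] == chrom[cur[-1]] and pos[idx] - pos[cur[-1]] <= gap:
            cur.append(idx)
        else:
            if cur:
                bins.append(cur)
            cur = [idx]
    if cur:
        bins.append(cur)
    out = []
    for b in bins:
        flags = [bool(is_dmp[i]) for i in b]
        best = run = 0
        for f in flags:
            run = run + 1 if f else 0
            best = max(best, run)
        out.append((chrom[b[0]], pos[b[0]], pos[b[-1]],
                    best >= min_run and sum(flags) >= min_total))
    return out


class TestCallDMRs:
    def bins_for(self, pattern, spacing=50):
        is_dmp = np.array([c == "D" for c in pattern])
        pos = np.arange(len(pattern)) * spacing + 100
        chrom = np.array(["chr1"] * len(pattern))
        bins, _ = call_dmrs(is_dmp, chrom, pos)
        return bins

    def test_four_consecutive_five_total_is_dmr(self):
        bins = self.bins_for("DDDDND")
        assert bool(bins["is_dmr"].iloc[0])

    def test_max_run_three_is_not_dmr(self):
        bins = self.bins_for("DDDNDD")
        assert not bool(bins["is_dmr"].iloc[0])

    def test_gap_chaining_single_bin(self):
        pos = np.array([100, 150, 200, 260, 320])
        bins, bin_id = call_dmrs(np.ones(5, bool), ["chr1"] * 5, pos)
        assert len(bins) == 1 and len(set(bin_id)) == 1

    def test_gap_over_100_splits_bins(self):
        pos = np.array([100, 201])
        bins, _ = call_dmrs(np.ones(2, bool), ["chr1"] * 2, pos)
        assert len(bins) == 2

    def test_matches_bruteforce_oracle_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(1, 60)
            pos = np.sort(rng.choice(np.arange(1, 4000), n, replace=False))
            chrom = np.array([f"chr{c}" for c in rng.integers(1, 3, n)])
            is_dmp = rng.random(n) < 0.5
            bins, _ = call_dmrs(is_dmp, chrom, pos)
            ref = oracle_dmrs(is_dmp, chrom, pos)
            got = [(r.chrom, r.start, r.end, bool(r.is_dmr))
                   for r in bins.itertuples(index=False)]
            assert sorted(got) == sorted(ref)


class TestPromoterStatus:
    @pytest.fixture()
    def prom(self):
        return build_promoters(pd.DataFrame(
            {"gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"],
             "tss": [10_000, 200_000], "strand": ["+", "+"]}))

    def test_hyper_dmr_overlap_gives_hyper(self, prom):
        hyper = pd.DataFrame({"chrom": ["chr1"], "start": [9_000], "end": [9_500],
                              "is_dmr": [True]})
        st = promoter_methylation_status(hyper, None, prom, covered_genes={"g1", "g2"})
        assert st["g1"] == "hyper" and st["g2"] == "none"

    def test_dmps_without_qualifying_dmr_is_none(self, prom):
        bins = pd.DataFrame({"chrom": ["chr1"], "start": [9_000], "end": [9_500],
                             "is_dmr": [False]})
        st = promoter_methylation_status(bins, None, prom, covered_genes={"g1", "g2"})
        assert st["g1"] == "none"

    def test_uncovered_gene_is_missing_not_none(self, prom):
        st = promoter_methylation_status(None, None, prom, covered_genes={"g1"})
        assert st["g1"] == "none" and pd.isna(st["g2"])

    def test_conflicting_directions_flagged_as_both(self, prom):
        hyper = pd.DataFrame({"chrom": ["chr1"], "start": [9_000], "end": [9_100],
                              "is_dmr": [True]})
        hypo = pd.DataFrame({"chrom": ["chr1"], "start": [10_100], "end": [10_200],
                             "is_dmr": [True]})
        st = promoter_methylation_status(hyper, hypo, prom, covered_genes={"g1"})
        assert st["g1"] == "both"


class TestUbiquity:
    def events(self, present_by_region):
        return pd.DataFrame({
            "feature_id": "f", "patient_id": "p",
            "region_id": [f"R{i}" for i in range(len(present_by_region))],
            "present": present_by_region,
        })

    def test_all_regions_is_ubiquitous(self):
        out = compute_ubiquity(self.events([True, True, True]))
        assert out["clonality"].iloc[0] == "ubiquitous"

    def test_one_of_three_is_subclonal_third(self):
        out = compute_ubiquity(self.events([True, False, False]))
        assert out["fraction"].iloc[0] == pytest.approx(1 / 3)
        assert out["clonality"].iloc[0] == "subclonal"

    def test_two_of_two_ubiquitous(self):
        out = compute_ubiquity(self.events([True, True]))
        assert out["clonality"].iloc[0] == "ubiquitous"

    def test_single_region_clonality_missing(self):
        out = compute_ubiquity(self.events([True]))
        assert out["fraction"].iloc[0] == 1.0 and pd.isna(out["clonality"].iloc[0])


class TestDHcR:
    def make_map(self, n_sites):
        prom = build_promoters(pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "tss": [5_000], "strand": ["+"]}))
        sites = pd.DataFrame({"chrom": "chr1", "pos": 2_600 + 100 * np.arange(n_sites)})
        return map_cpgs_to_promoters(sites, prom)

    @pytest.mark.parametrize("n_hyper,expected", [(5, 0.25), (0, 0.0), (20, 1.0)])
    def test_ratio_arithmetic(self, n_hyper, expected):
        pmap = self.make_map(20)
        hyper = np.zeros((20, 1), bool)
        hyper[:n_hyper, 0] = True
        covered = np.ones((20, 1), bool)
        d = compute_dhcr(hyper, covered, pmap, ["s"])
        assert d.at["g", "s"] == pytest.approx(expected)

    def test_invariant_to_cpg_order(self):
        pmap = self.make_map(10)
        rng = np.random.default_rng(0)
        hyper = rng.random((10, 1)) < 0.4
        covered = np.ones((10, 1), bool)
        a = compute_dhcr(hyper, covered, pmap, ["s"]).at["g", "s"]
        perm = rng.permutation(10)
        pmap2 = pmap.copy()
        pmap2["site_index"] = pmap["site_index"].to_numpy()[perm]
        b = compute_dhcr(hyper, covered, pmap2, ["s"]).at["g", "s"]
        assert a == pytest.approx(b)

    def test_zero_profiled_gene_excluded(self):
        pmap = self.make_map(5)
        d = compute_dhcr(np.zeros((5, 1), bool), np.zeros((5, 1), bool), pmap, ["s"])
        assert np.isnan(d.at["g", "s"])

    def test_methsig_calls_control_fdr_direction(self):
        rng = np.random.default_rng(1)
        n = 2000
        kn = rng.binomial(40, 0.3, (n, 1))
        kb = rng.binomial(40, 0.3, (n, 1))
        nb = np.full((n, 1), 40)
        calls = methsig_dmp_calls(kb, nb, kn, nb, fdr=0.15)
        assert calls.mean() < 0.02  # null: BH keeps discoveries near zero


class TestCohortCaller:
    def test_type_one_error_controlled_on_null(self, toy_contexts):
        from methevolve.containers import CohortMethylation
        rng = np.random.default_rng(3)
        n = 4000
        m = np.where(rng.random(n) < 0.5, rng.beta(1.5, 20, n), rng.beta(20, 1.5, n))
        sites = pd.DataFrame({"chrom": "chr1", "pos": 1000 + 10 * np.arange(n)})
        samples = list(toy_contexts["sample_id"])
        total = rng.poisson(30, (n, len(samples)))
        meth = rng.binomial(total, m[:, None])
        cohort = CohortMethylation(sites, samples, meth, total)
        seg = pd.DataFrame([(s, "chr1", 1, 10**6, 2, 2) for s in samples
                            if "N" not in s],
                           columns=["sample_id", "chrom", "start", "end", "n_t", "n_n"])
        res = call_dmps_cohort(cohort, toy_contexts, seg)
        rate = (res["status"] != 0).mean()
        assert rate <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / n)
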