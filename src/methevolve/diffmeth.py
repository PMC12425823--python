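"""Tumor-normal differential methylation: DMPs, DMRs, promoter status,
ubiquity and the differentially hypermethylated cytosine ratio (DHcR).

Two DMP callers coexist and are named for their consumers:

* :func:`call_dmps` — per-sample calls at the 0.2 effect / 0.01 significance
  thresholds on deconvolved rates.  The significance test exploits the
  identity m_t − m_n = w/(n_t·rho) · (m_b − m_n) (w = n_t·rho + n_n·(1−rho)):
  the deconvolved difference is zero exactly when the bulk and normal
  proportions agree, so the p-value is computed on the observed read counts
  (two-proportion z-test, exact conditional fallback for sparse cells) and is
  exactly calibrated, while the effect threshold stays on the deconvolved
  scale.
* :func:`methsig_dmp_calls` — chi-squared test with per-sample 15% FDR, the
  variant feeding DHcR/driver ranking.

:func:`call_dmps_cohort` aggregates the per-sample evidence across a
multi-region cohort (patient-pooled counts, mid-p signed z, Stouffer across
patients) to recover cohort-level DMP status at the same 0.2/0.01 thresholds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import (
    bh_fdr,
    fisher_exact_doubled,
    midp_signed_z,
    stouffer,
    two_proportion_pvalue,
)

HYPER, NS, HYPO = 1, 0, -1


# ---------------------------------------------------------------------------
# per-sample DMP calling
# ---------------------------------------------------------------------------

@dataclass
class DMPResult:
    """Aligned per-site arrays for one tumor sample (or site x sample 2-D)."""

    delta: np.ndarray
    p_value: np.ndarray
    status: np.ndarray      # +1 hyper, -1 hypo, 0 ns; status is 0 where excluded
    excluded: np.ndarray    # sites skipped (missing coverage either side)

    @property
    def n_skipped(self) -> int:
        return int(self.excluded.sum())


def dmp_pvalue(kb, nb, kn, nn, exact_cell_min: int = 5):
    """Two-sided p for bulk vs normal methylated proportions.

    Pooled two-proportion z-test; whenever any cell of the 2x2 count table is
    below ``exact_cell_min``, the conditional exact (tail-doubled) p replaces
    the normal approximation.
    """
    kb = np.asarray(kb)
    nb = np.asarray(nb)
    kn = np.asarray(kn)
    nn = np.asarray(nn)
    p = two_proportion_pvalue(kb, nb, kn, nn)
    cells = np.minimum.reduce([kb, nb - kb, kn, nn - kn])
    small = cells < exact_cell_min
    if np.any(small):
        p = np.where(small, fisher_exact_doubled(kb, nb, kn, nn), p)
    return p


def call_dmps(m_t_hat, m_n_hat, kb, nb, kn, nn,
              delta: float = 0.2, alpha: float = 0.01) -> DMPResult:
    """Per-sample DMP calls on deconvolved tumor rates vs matched normal.

    hyper iff m_t_hat − m_n > ``delta`` and p < ``alpha``; hypo mirrored.
    Sites with missing coverage on either side (or undeconvolvable, NaN
    m_t_hat) are excluded and counted, never silently dropped.
    """
    m_t_hat = np.asarray(m_t_hat, float)
    m_n_hat = np.asarray(m_n_hat, float)
    nb = np.asarray(nb)
    nn = np.asarray(nn)
    excluded = (nb <= 0) | (nn <= 0) | ~np.isfinite(m_t_hat) | ~np.isfinite(m_n_hat)
    d = m_t_hat - m_n_hat
    p = np.ones(d.shape)
    ok = ~excluded
    if np.any(ok):
        p_ok = dmp_pvalue(np.asarray(kb)[ok], nb[ok], np.asarray(kn)[ok], nn[ok])
        p[ok] = p_ok
    status = np.zeros(d.shape, dtype=np.int8)
    sig = ok & (p < alpha)
    status[sig & (d > delta)] = HYPER
    status[sig & (d < -delta)] = HYPO
    return DMPResult(delta=np.where(excluded, np.nan, d), p_value=np.where(excluded, np.nan, p),
                     status=status, excluded=excluded)


def call_dmps_cohort(cohort, contexts: pd.DataFrame, segments: pd.DataFrame,
                     delta: float = 0.2, alpha: float = 0.01,
                     min_patients: int = 2, n_n: int = 2) -> pd.DataFrame:
    """Cohort-level DMP status from multi-region evidence.

    Per patient, region read counts are pooled per CpG and compared with the
    matched normal through the signed mid-p conditional z; patient scores are
    Stouffer-combined (patients are independent; regions of one patient share
    a normal and are pooled, not double-counted).  A CpG is called hyper when
    the combined two-sided p is below ``alpha`` and at least ``min_patients``
    patients show a sign-consistent patient-level deconvolved difference
    above ``delta`` (hypo mirrored).  Effect sizes are read-weighted means of
    per-region deconvolved deltas.
    """
    from .deconvolution import deconvolve_cohort

    dec = deconvolve_cohort(cohort, contexts, segments, n_n=n_n, min_total=1)
    ctx = contexts.set_index("sample_id")
    tumor_ids = dec.samples
    patients = sorted({ctx.loc[s, "patient_id"] for s in tumor_ids})
    pat_cols = {p: [j for j, s in enumerate(tumor_ids) if ctx.loc[s, "patient_id"] == p]
                for p in patients}
    normal_col = {}
    for p in patients:
        nid = contexts[(contexts["patient_id"] == p) & (contexts["tissue"] == "normal")]["sample_id"].iloc[0]
        normal_col[p] = cohort.column(nid)

    n = cohort.n_sites
    z_pat = np.zeros((n, len(patients)))
    d_pat = np.full((n, len(patients)), np.nan)
    tumor_cols = {s: cohort.column(s) for s in tumor_ids}
    for i, p in enumerate(patients):
        cols = pat_cols[p]
        jt = [tumor_cols[tumor_ids[j]] for j in cols]
        kb = cohort.meth[:, jt].sum(axis=1)
        nb = cohort.total[:, jt].sum(axis=1)
        kn = cohort.meth[:, normal_col[p]]
        nn = cohort.total[:, normal_col[p]]
        ok = (nb > 0) & (nn > 0)
        z = np.zeros(n)
        z[ok] = midp_signed_z(kb[ok], nb[ok], kn[ok], nn[ok])
        z_pat[:, i] = z
        # read-weighted mean of per-region deconvolved deltas
        deltas = dec.m_t_hat[:, cols] - dec.m_n_hat[:, cols]
        w = np.where(np.isfinite(deltas), cohort.total[:, jt], 0.0)
        num = np.nansum(np.where(np.isfinite(deltas), deltas, 0.0) * w, axis=1)
        den = w.sum(axis=1)
        d_pat[:, i] = np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)

    z_comb, p_comb = stouffer(z_pat, axis=1)
    with np.errstate(invalid="ignore"):
        n_hyper = np.nansum(d_pat > delta, axis=1)
        n_hypo = np.nansum(d_pat < -delta, axis=1)
    status = np.zeros(n, dtype=np.int8)
    sig = p_comb < alpha
    status[sig & (z_comb > 0) & (n_hyper >= min_patients)] = HYPER
    status[sig & (z_comb < 0) & (n_hypo >= min_patients)] = HYPO
    out = cohort.sites[["chrom", "pos"]].copy()
    out["z"] = z_comb
    out["p_value"] = p_comb
    out["n_patients_hyper"] = n_hyper.astype(int)
    out["n_patients_hypo"] = n_hypo.astype(int)
    out["status"] = status
    return out


# ---------------------------------------------------------------------------
# DMRs
# ---------------------------------------------------------------------------

def call_dmrs(is_dmp, chrom, pos, gap: int = 100,
              min_run: int = 4, min_total: int = 5):
    """Bin CpGs into neighborhoods and flag DMP hotspots as DMRs.

    CpGs within ``gap`` bp of one another (same chromosome) chain into one
    bin.  A bin is a DMR when it contains a run of at least ``min_run``
    consecutive DMPs (consecutive = adjacent covered CpGs in the series) and
    at least ``min_total`` DMPs overall.

    Returns ``(bins, bin_id)``: a per-bin frame and the per-site bin index.
    """
    is_dmp = np.asarray(is_dmp, dtype=bool)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    order = np.lexsort((pos, chrom))
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    c, p, d = chrom[order], pos[order], is_dmp[order]
    if len(p) == 0:
        return (pd.DataFrame(columns=["bin_id", "chrom", "start", "end", "n_cpgs",
                                      "n_dmps", "max_run", "is_dmr"]),
                np.array([], dtype=np.int64))
    new_bin = np.ones(len(p), dtype=bool)
    same = (c[1:] == c[:-1]) & (p[1:] - p[:-1] <= gap)
    new_bin[1:] = ~same
    bin_sorted = np.cumsum(new_bin) - 1
    rows = []
    for b in range(bin_sorted[-1] + 1):
        sel = bin_sorted == b
        flags = d[sel]
        run = best = 0
        for f in flags:
            run = run + 1 if f else 0
            best = max(best, run)
        n_dmps = int(flags.sum())
        rows.append((b, c[sel][0], int(p[sel][0]), int(p[sel][-1]), int(sel.sum()),
                     n_dmps, best, best >= min_run and n_dmps >= min_total))
    bins = pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end", "n_cpgs",
                                       "n_dmps", "max_run", "is_dmr"])
    return bins, bin_sorted[inv]


def promoter_methylation_status(hyper_bins: pd.DataFrame, hypo_bins: pd.DataFrame,
                                promoters: pd.DataFrame,
                                covered_genes: set | None = None) -> pd.Series:
    """Per-gene methylation status from qualifying DMRs for one sample.

    A gene is ``hyper`` when >=1 hyper DMR overlaps its promoter window
    (hypo analogously); both directions give ``both``; a covered gene with
    DMPs but no qualifying DMR is ``none``; genes without covered promoter
    CpGs are missing (NaN), not ``none``.
    """
    def overlapping(bins):
        hit = set()
        if bins is None or bins.empty:
            return hit
        dmrs = bins[bins["is_dmr"]]
        for g in promoters.itertuples(index=False):
            sel = dmrs[(dmrs["chrom"] == g.chrom)
                       & (dmrs["end"] >= g.window_start)
                       & (dmrs["start"] <= g.window_end)]
            if len(sel):
                hit.add(g.gene_id)
        return hit

    hyper = overlapping(hyper_bins)
    hypo = overlapping(hypo_bins)
    out = {}
    for g in promoters["gene_id"]:
        if covered_genes is not None and g not in covered_genes:
            out[g] = np.nan
            continue
        if g in hyper and g in hypo:
            out[g] = "both"
        elif g in hyper:
            out[g] = "hyper"
        elif g in hypo:
            out[g] = "hypo"
        else:
            out[g] = "none"
    return pd.Series(out, name="status")


# ---------------------------------------------------------------------------
# ubiquity
# ---------------------------------------------------------------------------

def compute_ubiquity(events: pd.DataFrame) -> pd.DataFrame:
    """Fraction of assessable regions carrying an event, per feature/patient.

    ``events`` is long: feature_id, patient_id, region_id, present (bool);
    one row per assessable (feature, region).  ``ubiquitous`` requires the
    fraction to equal 1 with at least two assessable regions; clonality is
    missing (NaN) for single-region patients.
    """
    g = events.groupby(["feature_id", "patient_id"], sort=True)["present"].agg(["sum", "count"])
    out = g.reset_index().rename(columns={"sum": "n_regions_with_event",
                                          "count": "n_regions_assessable"})
    out["fraction"] = out["n_regions_with_event"] / out["n_regions_assessable"]
    clon = np.where(out["fraction"] == 1.0, "ubiquitous", "subclonal").astype(object)
    out["clonality"] = np.where(out["n_regions_assessable"] >= 2, clon, np.nan)
    return out


# ---------------------------------------------------------------------------
# DHcR (MethSig-style hypermethylated cytosine ratio)
# ---------------------------------------------------------------------------

def methsig_dmp_calls(kb, nb, kn, nn, fdr: float = 0.15) -> np.ndarray:
    """Hypermethylation calls for DHcR: chi-squared test on methylated /
    unmethylated counts, BH-adjusted per sample at ``fdr``; a site must also
    be more methylated in the tumor than the normal.

    Arrays are site x sample; uncovered sites are never called.
    """
    kb = np.atleast_2d(np.asarray(kb))
    nb = np.atleast_2d(np.asarray(nb))
    kn = np.atleast_2d(np.asarray(kn))
    nn = np.atleast_2d(np.asarray(nn))
    calls = np.zeros(kb.shape, dtype=bool)
    for j in range(kb.shape[1]):
        ok = (nb[:, j] > 0) & (nn[:, j] > 0)
        p = np.full(kb.shape[0], np.nan)
        p[ok] = two_proportion_pvalue(kb[ok, j], nb[ok, j], kn[ok, j], nn[ok, j])
        q = bh_fdr(p)
        with np.errstate(invalid="ignore", divide="ignore"):
            higher = (kb[:, j] / nb[:, j]) > (kn[:, j] / nn[:, j])
        calls[:, j] = ok & (q < fdr) & higher
    return calls


def compute_dhcr(hyper: np.ndarray, covered: np.ndarray,
                 promoter_map: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Ratio of hypermethylated cytosines to profiled promoter CpGs per gene.

    ``hyper`` and ``covered`` are site x sample boolean arrays;
    ``promoter_map`` is the long gene-to-site map from
    :func:`methevolve.io.map_cpgs_to_promoters`.  Genes with zero profiled
    CpGs in a sample are excluded (NaN), with the reason countable from the
    returned ``n_profiled`` frame.
    """
    hyper = np.atleast_2d(hyper)
    covered = np.atleast_2d(covered)
    genes = promoter_map["gene_id"].unique()
    dhcr = pd.DataFrame(index=pd.Index(genes, name="gene_id"), columns=samples, dtype=float)
    nprof = pd.DataFrame(0, index=dhcr.index, columns=samples, dtype=int)
    for g, grp in promoter_map.groupby("gene_id", sort=False):
        idx = grp["site_index"].to_numpy()
        cov = covered[idx, :]
        hyp = hyper[idx, :] & cov
        n_cov = cov.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = hyp.sum(axis=0) / n_cov
        dhcr.loc[g] = np.where(n_cov > 0, ratio, np.nan)
        nprof.loc[g] = n_cov
    dhcr.attrs["n_profiled"] = nprof
    return dhcr


def normal_reference_hyper(kn_rates: np.ndarray, delta: float = 0.2) -> np.ndarray:
    """Hypermethylation of each normal sample with respect to the median
    normal (used for normal-sample DHcR baselines)."""
    med = np.nanmedian(kn_rates, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        return (kn_rates - med) > delta
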