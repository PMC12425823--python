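"""The M_R/M_N regulatory-selection ratio.

Promoter CpGs that are recurrently hypermethylated in tumors are split into
*regulatory* (their hypermethylation coincides with significantly reduced
cognate-gene expression) and *nonregulatory* classes.  Per gene,

    M_R = (sum_i H_i R_i + 1) / (sum_i R_i + 1)
    M_N = (sum_i H_i (1 - R_i) + 1) / (n - sum_i R_i + 1)

with H_i the binary hypermethylation status and R_i the binary regulatory
status of event opportunity i, and a pseudocount of 1 on every component.
By analogy with dN/dS, a ratio M_R/M_N above 1 indicates preferential
hypermethylation of expression-regulatory CpGs (candidate functional
silencing under positive selection); below 1, enrichment of inert events.

Event opportunities are indexed by covered (CpG, sample) pairs by default
(matching event counts across the cohort); a per-CpG mode collapses each CpG
to "hypermethylated in >= 1 sample".
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr


# ---------------------------------------------------------------------------
# regulatory / nonregulatory assignment
# ---------------------------------------------------------------------------

def assign_cpg_regulatory_status(hyper: np.ndarray, covered: np.ndarray,
                                 expression: pd.DataFrame,
                                 promoter_map: pd.DataFrame,
                                 samples: list[str],
                                 alpha: float = 0.05,
                                 min_group: int = 2) -> pd.DataFrame:
    """Classify hypermethylated promoter CpGs as regulatory or not.

    For each promoter CpG hypermethylated in >= 1 tumor sample, cognate-gene
    expression in hypermethylated vs non-hypermethylated samples is compared
    with a two-sample t-test; regulatory (R=1) requires p < ``alpha`` with the
    hypermethylated group expressing less.  CpGs whose groups are smaller
    than ``min_group`` get no assignment (excluded from M_R/M_N denominators).
    """
    hyper = np.atleast_2d(hyper)
    covered = np.atleast_2d(covered)
    expr = expression[samples].to_numpy(dtype=float)
    gene_row = {g: i for i, g in enumerate(expression.index)}
    rows = []
    for rec in promoter_map.itertuples(index=False):
        i = rec.site_index
        if rec.gene_id not in gene_row:
            continue
        hyp = hyper[i, :] & covered[i, :]
        cov = covered[i, :]
        n_hyper = int(hyp.sum())
        if n_hyper == 0:
            continue  # not a DMP here: no assignment
        grp_h = expr[gene_row[rec.gene_id], hyp]
        grp_o = expr[gene_row[rec.gene_id], cov & ~hyp]
        if len(grp_h) < min_group or len(grp_o) < min_group:
            rows.append((i, rec.gene_id, np.nan, np.nan, np.nan, n_hyper, int(cov.sum())))
            continue
        t, p = stats.ttest_ind(grp_h, grp_o)
        if np.var(grp_h) == 0 and np.var(grp_o) == 0:
            p = 1.0 if np.mean(grp_h) == np.mean(grp_o) else 0.0
        reg = 1 if (p < alpha and np.mean(grp_h) < np.mean(grp_o)) else 0
        rows.append((i, rec.gene_id, float(reg), float(t), float(p), n_hyper, int(cov.sum())))
    return pd.DataFrame(rows, columns=["site_index", "gene_id", "R", "t_statistic",
                                       "p_value", "n_hyper_samples", "n_covered_samples"])


def events_from_matrices(assignments: pd.DataFrame, hyper: np.ndarray,
                         covered: np.ndarray, samples: list[str]) -> pd.DataFrame:
    """Expand per-CpG assignments into the long (gene, cpg, sample) event
    table consumed by :func:`compute_mrmn`."""
    rows = []
    assigned = assignments.dropna(subset=["R"])
    for rec in assigned.itertuples(index=False):
        i = int(rec.site_index)
        for j, s in enumerate(samples):
            if covered[i, j]:
                rows.append((rec.gene_id, f"cpg{i}", s, bool(rec.R), bool(hyper[i, j])))
    return pd.DataFrame(rows, columns=["gene_id", "cpg_id", "sample_id",
                                       "regulatory", "hyper"])


# ---------------------------------------------------------------------------
# the ratio
# ---------------------------------------------------------------------------

def compute_mrmn(events: pd.DataFrame, mode: str = "pair") -> pd.DataFrame:
    """Per-gene M_R, M_N and their ratio with pseudocounts.

    ``events`` is long with columns gene_id, cpg_id, sample_id, regulatory
    (bool), hyper (bool): one row per covered (CpG, sample) opportunity.
    ``mode='pair'`` indexes events by those pairs; ``mode='cpg'`` collapses
    to per-CpG indicators (hyper in >= 1 sample).  Genes lacking either a
    regulatory or a nonregulatory CpG are emitted as non-calculable with a
    missing ratio.
    """
    if mode not in ("pair", "cpg"):
        raise ValueError("mode must be 'pair' or 'cpg'")
    ev = events
    if mode == "cpg":
        ev = (events.groupby(["gene_id", "cpg_id"], sort=False)
              .agg(regulatory=("regulatory", "first"), hyper=("hyper", "any"))
              .reset_index())
        ev["sample_id"] = "(cohort)"
    rows = []
    for g, grp in ev.groupby("gene_id", sort=True):
        reg = grp["regulatory"].to_numpy(dtype=bool)
        hyp = grp["hyper"].to_numpy(dtype=bool)
        has_reg_cpg = grp.loc[grp["regulatory"], "cpg_id"].nunique() > 0
        has_non_cpg = grp.loc[~grp["regulatory"], "cpg_id"].nunique() > 0
        sum_R = int(reg.sum())
        sum_N = int((~reg).sum())
        sum_HR = int((hyp & reg).sum())
        sum_HN = int((hyp & ~reg).sum())
        m_r = (sum_HR + 1) / (sum_R + 1)
        m_n = (sum_HN + 1) / (sum_N + 1)
        if has_reg_cpg and has_non_cpg:
            ratio = m_r / m_n
            cls = "calculable"
        else:
            ratio = np.nan
            cls = "non_calculable"
        rows.append((g, sum_HR, sum_R, sum_HN, sum_N, m_r, m_n, ratio,
                     np.log2(ratio) if np.isfinite(ratio) and ratio > 0 else np.nan, cls))
    return pd.DataFrame(rows, columns=["gene_id", "sum_H_R", "sum_R", "sum_H_N",
                                       "sum_N", "M_R", "M_N", "ratio", "log2_ratio",
                                       "class"])


def test_mrmn_deviation(records: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Classify calculable genes whose ratio deviates from 1.

    An exact conditional test on the 2x2 table
    [[H_R, R − H_R], [H_N, N − H_N]] gives a per-gene p (valid at small
    counts); BH across genes; class ``gt1``/``lt1`` by ratio direction at
    q < ``fdr``, else ``ns``; non-calculable genes keep their class.
    """
    out = records.reset_index(drop=True)
    pvals = np.full(len(out), np.nan)
    calculable = out["class"].to_numpy() == "calculable"
    for i in np.flatnonzero(calculable):
        row = out.iloc[i]
        table = [[row["sum_H_R"], row["sum_R"] - row["sum_H_R"]],
                 [row["sum_H_N"], row["sum_N"] - row["sum_H_N"]]]
        pvals[i] = stats.fisher_exact(table)[1]
    out["p_value"] = pvals
    out["q"] = bh_fdr(pvals)
    sig = calculable & np.isfinite(out["q"].to_numpy()) & (out["q"].to_numpy() < fdr)
    cls = np.where(~calculable, "non_calculable",
                   np.where(sig & (out["ratio"].to_numpy() > 1), "gt1",
                            np.where(sig & (out["ratio"].to_numpy() < 1), "lt1", "ns")))
    out["class"] = cls
    return out


def mrmn_table(events: pd.DataFrame, mode: str = "pair", fdr: float = 0.05) -> pd.DataFrame:
    """End-to-end: ratios plus deviation classes for one cohort/subtype."""
    return test_mrmn_deviation(compute_mrmn(events, mode=mode), fdr=fdr)


# ---------------------------------------------------------------------------
# assignment transfer (discovery -> validation)
# ---------------------------------------------------------------------------

def evaluate_assignment_transfer(discovery: pd.DataFrame, validation: pd.DataFrame,
                                 alpha: float = 1e-4) -> dict:
    """Confusion matrix of regulatory/nonregulatory direction transfer.

    Both frames come from :func:`assign_cpg_regulatory_status` on their
    cohorts.  CpGs significantly regulatory in the discovery cohort
    (p < ``alpha``, reduced expression) are checked for reduced expression in
    the validation cohort, and vice versa for significantly nonregulatory
    CpGs (increased expression).  Returns TPR/TNR/sensitivity/specificity.
    """
    disc = discovery.dropna(subset=["R"]).set_index("site_index")
    val = validation.dropna(subset=["t_statistic"]).set_index("site_index")
    shared = disc.index.intersection(val.index)
    disc, val = disc.loc[shared], val.loc[shared]
    sig_reg = (disc["p_value"] < alpha) & (disc["t_statistic"] < 0)
    sig_non = (disc["p_value"] < alpha) & (disc["t_statistic"] > 0)
    val_down = val["t_statistic"] < 0
    tp = int((sig_reg & val_down).sum())
    fn = int((sig_reg & ~val_down).sum())
    tn = int((sig_non & ~val_down).sum())
    fp = int((sig_non & val_down).sum())
    def _safe(a, b):
        return a / b if b else np.nan
    return {"tp": tp, "fn": fn, "tn": tn, "fp": fp,
            "tpr": _safe(tp, tp + fn), "tnr": _safe(tn, tn + fp),
            "sensitivity": _safe(tp, tp + fn), "specificity": _safe(tn, tn + fp),
            "n_regulatory": int(sig_reg.sum()), "n_nonregulatory": int(sig_non.sum())}
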