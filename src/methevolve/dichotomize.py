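"""Expression dichotomization: learn per-gene expression thresholds that
proxy promoter hypermethylation in a methylation-profiled subcohort, then
transfer them to expression-only samples.

Thresholding statistics (mean and quartiles of expression in the
hypermethylated and non-hypermethylated strata) are estimated by a
region-level bootstrap: each replicate samples one region per tumor so that
multi-region tumors do not dominate, and the statistics are averaged across
replicates.  A sample is predicted "low" (hypermethylation-dependent reduced
expression) when its expression falls strictly below the aggregated 75th
percentile (Q3) of the hypermethylated stratum; at the tumor level, any
"low" region marks the tumor.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_STATS = ("mean", "q25", "q50", "q75")


@dataclass
class ExpressionThresholds:
    """Aggregated per-gene statistics plus the per-replicate values.

    ``summary``: per gene, ``<stratum>_<stat>`` columns (stratum in
    {hyper, other}) averaged over replicates.  ``replicates``: long frame
    (gene_id, replicate, stratum, mean, q25, q50, q75) retained for CIs.
    """

    summary: pd.DataFrame
    replicates: pd.DataFrame
    n_bootstrap: int

    def q3(self, stratum: str = "hyper") -> pd.Series:
        return self.summary[f"{stratum}_q75"]


def _stratum_stats(values: np.ndarray):
    if len(values) == 0:
        return (np.nan,) * 4
    return (float(np.mean(values)), float(np.percentile(values, 25)),
            float(np.percentile(values, 50)), float(np.percentile(values, 75)))


def fit_expression_thresholds(expression: pd.DataFrame, hyper_status: pd.DataFrame,
                              contexts: pd.DataFrame, n_bootstrap: int = 100,
                              seed: int = 0, min_per_stratum: int = 5) -> ExpressionThresholds:
    """Bootstrap expression statistics per gene and methylation stratum.

    ``expression``/``hyper_status``: genes x tumor-sample frames (status
    boolean: promoter hypermethylated in that sample).  Genes with fewer
    than ``min_per_stratum`` tumors in either stratum are skipped with the
    reason recorded in ``summary.attrs['skipped']``.
    """
    rng = np.random.default_rng(seed)
    ctx = contexts.set_index("sample_id")
    samples = [s for s in expression.columns if s in ctx.index
               and ctx.loc[s, "tissue"] == "tumor" and s in hyper_status.columns]
    patients: dict[str, list[str]] = {}
    for s in samples:
        patients.setdefault(ctx.loc[s, "patient_id"], []).append(s)
    pat_ids = sorted(patients)

    skipped = {}
    genes = []
    for g in expression.index:
        if g not in hyper_status.index:
            skipped[g] = "no methylation status"
            continue
        status = hyper_status.loc[g, samples].astype(bool)
        pats_h = {ctx.loc[s, "patient_id"] for s in samples if status[s]}
        pats_o = {ctx.loc[s, "patient_id"] for s in samples if not status[s]}
        if len(pats_h) < min_per_stratum or len(pats_o) < min_per_stratum:
            skipped[g] = "stratum below minimum size"
            continue
        genes.append(g)

    rep_rows = []
    for b in range(n_bootstrap):
        chosen = [patients[p][rng.integers(0, len(patients[p]))] for p in pat_ids]
        expr_b = expression.loc[genes, chosen]
        stat_b = hyper_status.loc[genes, chosen].astype(bool)
        for g in genes:
            vals = expr_b.loc[g].to_numpy(dtype=float)
            mask = stat_b.loc[g].to_numpy()
            for stratum, sel in (("hyper", mask), ("other", ~mask)):
                rep_rows.append((g, b, stratum) + _stratum_stats(vals[sel]))
    replicates = pd.DataFrame(rep_rows, columns=["gene_id", "replicate", "stratum"] + list(_STATS))

    agg = (replicates.groupby(["gene_id", "stratum"])[list(_STATS)]
           .mean().unstack("stratum"))
    summary = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for stratum in ("hyper", "other"):
        for stat in _STATS:
            if (stat, stratum) in agg.columns:
                summary[f"{stratum}_{stat}"] = agg[(stat, stratum)]
    summary.attrs["skipped"] = skipped
    return ExpressionThresholds(summary=summary, replicates=replicates,
                                n_bootstrap=n_bootstrap)


def predict_methylation_status(expression: pd.DataFrame,
                               thresholds: ExpressionThresholds,
                               contexts: pd.DataFrame,
                               stratum: str = "hyper") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label expression-only samples low/high against the learned Q3.

    Region label is ``low`` iff expression < Q3 of the chosen stratum
    (strictly; a value exactly at the threshold is ``high``).  A tumor is
    classified as having hypermethylation-dependent reduced expression when
    any of its regions is ``low``.  Returns (region_labels, tumor_labels).
    """
    q3 = thresholds.q3(stratum)
    ctx = contexts.set_index("sample_id")
    samples = [s for s in expression.columns if s in ctx.index
               and ctx.loc[s, "tissue"] == "tumor"]
    genes = [g for g in expression.index if g in q3.index and np.isfinite(q3[g])]
    region_rows = []
    for g in genes:
        thr = q3[g]
        for s in samples:
            val = float(expression.at[g, s])
            region_rows.append((g, s, ctx.loc[s, "patient_id"],
                                "low" if val < thr else "high"))
    regions = pd.DataFrame(region_rows, columns=["gene_id", "sample_id", "patient_id", "label"])
    tum_rows = []
    for (g, pat), grp in regions.groupby(["gene_id", "patient_id"], sort=True):
        low = (grp["label"] == "low").any()
        conflict = grp["label"].nunique() > 1
        tum_rows.append((g, pat, "low" if low else "high", conflict))
    tumors = pd.DataFrame(tum_rows, columns=["gene_id", "patient_id", "label",
                                             "region_conflict"])
    return regions, tumors
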