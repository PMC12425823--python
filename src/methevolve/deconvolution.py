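"""Purity/CN-aware deconvolution of bulk methylation and epiallele discordance.

A bulk tumor sample is a mixture of tumor cells (fraction rho of cells,
carrying n_t copies of a locus) and normal contaminant cells (1 - rho,
carrying n_n copies, usually 2).  Reads therefore arrive from the tumor
compartment in proportion n_t*rho and from the normal compartment in
proportion n_n*(1 - rho), giving the forward mixture

    m_b = (m_t * n_t * rho + m_n * n_n * (1 - rho)) / (n_t * rho + n_n * (1 - rho))

for any per-read rate statistic.  Inverting for the cancer-cell-specific
value,

    m_t = (m_b * (n_t * rho + n_n * (1 - rho)) - m_n * n_n * (1 - rho)) / (n_t * rho).

The identical algebra applies to the proportion of discordant reads (PDR),
because a bulk PDR is the same copy-weighted average of compartment PDRs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EPS = 1e-9


class NoTumorCopiesError(ValueError):
    """Deconvolution is undefined where n_t * rho = 0 (no tumor-derived reads)."""


def _weights(n_t, n_n, rho):
    n_t = np.asarray(n_t, float)
    n_n = np.asarray(n_n, float)
    rho = np.asarray(rho, float)
    return n_t * rho, n_n * (1.0 - rho)


def mix_forward(m_t, m_n, n_t, n_n, rho):
    """Bulk rate implied by compartment rates (the brute-force oracle for the
    inversion)."""
    wt, wn = _weights(n_t, n_n, rho)
    denom = wt + wn
    if np.any(denom <= 0):
        raise ValueError("mixture weights must be positive")
    return (np.asarray(m_t, float) * wt + np.asarray(m_n, float) * wn) / denom


def _invert(bulk, normal, n_t, n_n, rho, clip=True):
    wt, wn = _weights(n_t, n_n, rho)
    if np.any(wt <= 0):
        raise NoTumorCopiesError("n_t * rho must be positive to recover a tumor rate")
    raw = (np.asarray(bulk, float) * (wt + wn) - np.asarray(normal, float) * wn) / wt
    clipped = (raw < -EPS) | (raw > 1.0 + EPS)
    est = np.clip(raw, 0.0, 1.0) if clip else raw
    return est, clipped


def deconvolve_methylation(m_b, m_n, n_t, n_n, rho, clip=True):
    """Cancer-cell-specific methylation rate estimate.

    Returns ``(m_t_hat, clipped)``; clipped flags raw estimates outside [0,1]
    by more than numerical epsilon (kept, not dropped, so downstream
    denominators retain the site).
    """
    return _invert(m_b, m_n, n_t, n_n, rho, clip=clip)


def deconvolve_pdr(pdr_b, pdr_n, n_t, n_n, rho, clip=True):
    """Cancer-cell-specific PDR estimate (same algebraic inversion)."""
    return _invert(pdr_b, pdr_n, n_t, n_n, rho, clip=clip)


def lookup_segment_cn(sites: pd.DataFrame, segments: pd.DataFrame, sample_id: str) -> np.ndarray:
    """Per-CpG tumor copy number for one sample; -1 where no segment covers
    the CpG (segment gap)."""
    seg = segments[segments["sample_id"] == sample_id]
    out = np.full(len(sites), -1, dtype=np.int64)
    pos_all = sites["pos"].to_numpy()
    chrom_all = sites["chrom"].to_numpy()
    for chrom, grp in seg.groupby("chrom", sort=False):
        mask = chrom_all == chrom
        if not mask.any():
            continue
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        nts = grp["n_t"].to_numpy()
        pos = pos_all[mask]
        k = np.searchsorted(starts, pos, side="right") - 1
        covered = (k >= 0) & (pos <= ends[np.maximum(k, 0)])
        vals = np.where(covered, nts[np.maximum(k, 0)], -1)
        out[mask] = vals
    return out


@dataclass
class DeconvolvedCohort:
    """Per-CpG x tumor-sample deconvolution output.

    ``m_t_hat`` is NaN where a CpG is uncovered in the tumor or its matched
    normal, or falls in a CN-segment gap or a homozygous deletion; ``clipped``
    and ``excluded`` record why.
    """

    sites: pd.DataFrame
    samples: list[str]
    m_t_hat: np.ndarray
    m_n_hat: np.ndarray  # matched-normal rate per CpG per tumor sample
    n_t: np.ndarray
    clipped: np.ndarray
    excluded: np.ndarray


def deconvolve_cohort(cohort, contexts: pd.DataFrame, segments: pd.DataFrame,
                      n_n: int = 2, min_total: int = 1) -> DeconvolvedCohort:
    """Deconvolve every tumor sample of a cohort against its patient-matched
    normal.

    ``cohort`` is a :class:`~methevolve.containers.CohortMethylation` holding
    tumor and normal columns; ``contexts`` supplies tissue, patient and purity.
    """
    ctx = contexts.set_index("sample_id")
    tumor_ids = [s for s in cohort.samples if ctx.loc[s, "tissue"] == "tumor"]
    normal_of = {}
    for s in tumor_ids:
        pid = ctx.loc[s, "patient_id"]
        match = contexts[(contexts["patient_id"] == pid) & (contexts["tissue"] == "normal")]
        if len(match) != 1:
            raise ValueError(f"patient {pid} needs exactly one normal sample")
        normal_of[s] = match["sample_id"].iloc[0]

    rates = cohort.rates()
    n = cohort.n_sites
    m_t_hat = np.full((n, len(tumor_ids)), np.nan)
    m_n_hat = np.full_like(m_t_hat, np.nan)
    n_t_arr = np.zeros((n, len(tumor_ids)), dtype=np.int64)
    clipped = np.zeros(m_t_hat.shape, dtype=bool)
    excluded = np.zeros(m_t_hat.shape, dtype=bool)

    for j, sid in enumerate(tumor_ids):
        jt = cohort.column(sid)
        jn = cohort.column(normal_of[sid])
        rho = float(ctx.loc[sid, "purity"])
        n_t = lookup_segment_cn(cohort.sites, segments, sid)
        n_t_arr[:, j] = n_t
        ok = (
            (cohort.total[:, jt] >= min_total)
            & (cohort.total[:, jn] >= min_total)
            & (n_t > 0)
        )
        excluded[:, j] = ~ok
        est, cl = deconvolve_methylation(
            rates[ok, jt], rates[ok, jn], n_t[ok], n_n, rho
        )
        m_t_hat[ok, j] = est
        m_n_hat[ok, j] = rates[ok, jn]
        clipped[ok, j] = cl
    return DeconvolvedCohort(cohort.sites, tumor_ids, m_t_hat, m_n_hat, n_t_arr, clipped, excluded)


# ---------------------------------------------------------------------------
# epiallele discordance
# ---------------------------------------------------------------------------

def compute_pdr(reads: pd.DataFrame, k: int = 4) -> pd.DataFrame:
    """Proportion of discordant reads per (sample, window).

    ``reads`` has columns read_id, sample_id, window_id and ``states`` — a
    string over {M, U}, one character per CpG on the read.  Reads reporting
    fewer than ``k`` CpGs are ineligible and excluded from numerator and
    denominator alike.  Windows with zero eligible reads are reported with
    PDR = NaN (missing, not 0).
    """
    if k < 2:
        raise ValueError("discordance needs at least 2 CpGs per read")
    states = reads["states"].astype(str)
    eligible = states.str.len() >= k
    discordant = states.str.contains("M") & states.str.contains("U")
    df = pd.DataFrame({
        "sample_id": reads["sample_id"],
        "window_id": reads["window_id"],
        "eligible": eligible,
        "disc": discordant & eligible,
    })
    g = df.groupby(["sample_id", "window_id"], sort=True)[["eligible", "disc"]].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        pdr = g["disc"] / g["eligible"]
    out = g.reset_index()
    out["pdr"] = np.where(out["eligible"] > 0, pdr.to_numpy(), np.nan)
    out = out.rename(columns={"eligible": "n_reads", "disc": "n_discordant"})
    return out
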