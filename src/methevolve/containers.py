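"""In-memory containers shared by all pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ValidationError


@dataclass
class CohortMethylation:
    """CpG x sample table of (methylated, total) read counts.

    ``sites`` holds one row per CpG (chrom, pos; + strand cytosine position,
    unique and sorted); ``meth``/``total`` are integer arrays of shape
    (n_sites, n_samples) aligned to ``sites`` rows and ``samples`` columns.
    A total of 0 encodes a CpG not covered in that sample.
    """

    sites: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        n, s = self.meth.shape
        if self.total.shape != (n, s) or len(self.sites) != n or len(self.samples) != s:
            raise ValidationError("CohortMethylation shapes disagree")
        if self.sites.duplicated(subset=["chrom", "pos"]).any():
            raise ValidationError("duplicate (chrom, pos) in cohort sites")
        if (self.meth < 0).any() or (self.meth > self.total).any():
            raise ValidationError("need 0 <= meth <= total")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def rates(self) -> np.ndarray:
        """meth/total with NaN where a CpG is uncovered."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.meth / self.total
        return np.where(self.total > 0, r, np.nan)

    def column(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def subset_samples(self, keep: list[str]) -> "CohortMethylation":
        idx = [self.column(s) for s in keep]
        return CohortMethylation(self.sites, list(keep), self.meth[:, idx], self.total[:, idx])

    @classmethod
    def from_tables(cls, tables: dict[str, pd.DataFrame]) -> "CohortMethylation":
        """Assemble from per-sample frames (chrom, pos, meth, total).

        The site universe is the union of all samples; absent CpGs get
        total = 0 for that sample.
        """
        samples = list(tables)
        sites = (
            pd.concat([t[["chrom", "pos"]] for t in tables.values()])
            .drop_duplicates()
            .sort_values(["chrom", "pos"])
            .reset_index(drop=True)
        )
        key = pd.MultiIndex.from_frame(sites)
        meth = np.zeros((len(sites), len(samples)), dtype=np.int64)
        total = np.zeros_like(meth)
        for j, sid in enumerate(samples):
            t = tables[sid]
            loc = key.get_indexer(pd.MultiIndex.from_frame(t[["chrom", "pos"]]))
            meth[loc, j] = t["meth"].to_numpy()
            total[loc, j] = t["total"].to_numpy()
        return cls(sites, samples, meth, total)

    def to_long(self) -> pd.DataFrame:
        frames = []
        for j, sid in enumerate(self.samples):
            cov = self.total[:, j] > 0
            f = self.sites.loc[cov, ["chrom", "pos"]].copy()
            f["sample_id"] = sid
            f["meth"] = self.meth[cov, j]
            f["total"] = self.total[cov, j]
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


@dataclass
class GroundTruth:
    """Latent quantities of a simulated cohort (what the pipeline estimates)."""

    m_n: np.ndarray                      # per-CpG normal-compartment rate
    m_t_event: np.ndarray                # per-CpG tumor rate where the event is present
    dmp_status: np.ndarray               # per-CpG: 0 none, +1 hyper, -1 hypo
    clonal: np.ndarray                   # per-CpG bool (meaningful where dmp_status != 0)
    present: np.ndarray                  # CpG x tumor-sample bool presence matrix
    regulatory: np.ndarray               # per-CpG bool (promoter hyper DMPs only)
    tumor_samples: list[str]
    site_gene: np.ndarray                # per-CpG gene index or -1 (promoter membership)
    gene_ids: list[str]
    gene_chrom: np.ndarray               # per-gene chromosome name
    gene_tss: np.ndarray                 # per-gene TSS coordinate
    baseline_expression: np.ndarray      # per-gene expected normal expression
    purity: dict[str, float] = field(default_factory=dict)
    amplicons: list[dict] = field(default_factory=list)
    # amplicon-driven methylation shifts: per-CpG signed delta, per-CpG
    # amplicon index (-1 = none), amplicon x tumor-sample amplified mask
    amp_delta: np.ndarray | None = None
    amp_of_site: np.ndarray | None = None
    amp_sample_mask: np.ndarray | None = None
    pdr_t: np.ndarray | None = None      # per-promoter true tumor PDR
    pdr_n: np.ndarray | None = None

    def tumor_rate(self, j: int) -> np.ndarray:
        """Per-CpG true tumor-compartment rate for tumor sample column j."""
        rate = np.where(self.present[:, j], self.m_t_event, self.m_n)
        if self.amp_delta is not None and self.amp_of_site is not None:
            idx = self.amp_of_site
            hit = idx >= 0
            if hit.any():
                amped = np.zeros(rate.shape, dtype=bool)
                amped[hit] = self.amp_sample_mask[idx[hit], j]
                rate = np.where(amped, np.clip(rate + self.amp_delta, 0.02, 0.98), rate)
        return rate
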