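"""Synthetic multi-region cohort generator with full ground truth.

The generator emulates the statistical structure every downstream stage
assumes:

* bulk tumor methylation as a purity/CN-weighted binomial mixture of a
  tumor and a normal compartment;
* a bimodal normal methylome (most CpGs near 0 or 1, as in real tissue);
* planted hyper-/hypomethylated DMPs with clonal (all regions) or subclonal
  (strict subset of regions) multi-region structure;
* promoter CpGs whose hypermethylation causally reduces cognate-gene
  expression (regulatory) versus not (nonregulatory);
* amplified oncogene loci whose co-amplified neighbors are methylation
  dosage-compensated;
* read-level epialleles with controllable discordance (PDR).

Determinism: one global seed; each stage draws from a substream derived as
``default_rng([seed, stage])`` so stages can be regenerated independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CohortMethylation, GroundTruth
from .io import build_promoters

_GENE_SPACING = 100_000
_GENES_PER_CHROM = 200


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_cohort`.

    Defaults encode the reference multi-region NSCLC-like design: 20 patients
    with 3 tumor regions and one matched normal each, 50,000 CpGs at mean
    coverage 30 reads, purity uniform on (0.3, 0.9), 5% of CpGs planted as
    DMPs with effect size 0.3, half of planted events clonal.
    """

    n_patients: int = 20
    regions_per_patient: int = 3
    n_cpgs: int = 50_000
    n_genes: int = 1_000
    purity_range: tuple[float, float] = (0.3, 0.9)
    coverage_mean: float = 30.0
    dmp_fraction: float = 0.05
    dmp_effect_size: float = 0.3
    fraction_regulatory: float = 0.5
    regulatory_expression_drop: float = 0.5
    clonal_fraction: float = 0.5
    # fraction of patients carrying each planted DMP; < 1 yields
    # patient-specific methylation signatures
    dmp_patient_fraction: float = 1.0
    n_amplicons: int = 2
    amplicon_span_bp: int = 20_000_000
    amplicon_effects: bool = True
    expression_sigma: float = 0.3
    cpgs_per_promoter: int = 10
    ploidy: float = 2.0
    n_n: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for name in ("dmp_fraction", "fraction_regulatory", "regulatory_expression_drop",
                     "clonal_fraction", "dmp_patient_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.dmp_fraction > 0 and self.dmp_effect_size < 0.2:
            raise ValueError("planted DMP effect sizes below 0.2 are not supported")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class SimulatedCohort:
    cohort: CohortMethylation
    contexts: pd.DataFrame
    segments: pd.DataFrame
    expression: pd.DataFrame
    promoters: pd.DataFrame
    truth: GroundTruth
    histone: pd.DataFrame | None = None
    config: SimulationConfig | None = None

    @property
    def tumor_samples(self) -> list[str]:
        return self.truth.tumor_samples


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def _genome_layout(cfg: SimulationConfig):
    """Place genes on 20-Mb chromosomes and CpGs in promoters and gene bodies."""
    n_chrom = max(1, -(-cfg.n_genes // _GENES_PER_CHROM))
    gene_ids, gene_chrom, gene_tss, strands = [], [], [], []
    for g in range(cfg.n_genes):
        c = g // _GENES_PER_CHROM
        i = g % _GENES_PER_CHROM
        gene_ids.append(f"G{g:04d}")
        gene_chrom.append(f"chr{c + 1}")
        gene_tss.append(50_000 + i * _GENE_SPACING)
        strands.append("+" if g % 2 == 0 else "-")
    promoters = build_promoters(pd.DataFrame({
        "gene_id": gene_ids, "chrom": gene_chrom, "tss": gene_tss, "strand": strands,
    }))

    n_prom = min(cfg.n_cpgs, cfg.cpgs_per_promoter * cfg.n_genes)
    per_gene = max(1, n_prom // cfg.n_genes)
    chroms, positions, site_gene = [], [], []
    for g in range(cfg.n_genes):
        ws = promoters["window_start"].iat[g]
        step = 2751 // (per_gene + 1)
        for k in range(per_gene):
            chroms.append(gene_chrom[g])
            positions.append(int(ws + (k + 1) * step))
            site_gene.append(g)
    # remaining CpGs in gene bodies (never intersecting a promoter window)
    n_rest = cfg.n_cpgs - len(positions)
    rng = np.random.default_rng([0])  # layout is deterministic per config shape
    if n_rest > 0:
        body = rng.integers(10_000, 90_000, size=n_rest)
        host = rng.integers(0, cfg.n_genes, size=n_rest)
        for h, b in zip(host, body):
            chroms.append(gene_chrom[h])
            positions.append(int(gene_tss[h] + b))
            site_gene.append(-1)
    sites = pd.DataFrame({"chrom": chroms, "pos": positions})
    # de-duplicate collisions deterministically by nudging
    while sites.duplicated(subset=["chrom", "pos"]).any():
        dup = sites.duplicated(subset=["chrom", "pos"])
        sites.loc[dup, "pos"] = sites.loc[dup, "pos"] + 1
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    site_gene = np.asarray(site_gene)[order]
    return promoters, sites, site_gene


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _normal_methylome(cfg, site_gene, rng):
    n = len(site_gene)
    low = rng.beta(1.5, 20.0, n)
    high = rng.beta(20.0, 1.5, n)
    in_promoter = site_gene >= 0
    p_low = np.where(in_promoter, 0.85, 0.25)
    return np.where(rng.random(n) < p_low, low, high)


def _plant_dmps(cfg, m_n, site_gene, rng):
    n = len(m_n)
    n_dmp = int(round(cfg.dmp_fraction * n))
    status = np.zeros(n, dtype=np.int64)
    m_t = m_n.copy()
    regulatory = np.zeros(n, dtype=bool)
    if n_dmp == 0:
        return status, m_t, regulatory
    delta = cfg.dmp_effect_size
    hyper_ok = m_n <= 1.0 - delta - 0.02
    hypo_ok = m_n >= delta + 0.02
    n_hyper = n_dmp // 2
    n_hypo = n_dmp - n_hyper
    # hyper events preferentially in promoters (where baselines are low)
    prom_pool = np.flatnonzero(hyper_ok & (site_gene >= 0))
    other_pool = np.flatnonzero(hyper_ok & (site_gene < 0))
    take_prom = min(len(prom_pool), n_hyper // 2)
    hyper_idx = np.concatenate([
        rng.choice(prom_pool, take_prom, replace=False),
        rng.choice(other_pool, min(len(other_pool), n_hyper - take_prom), replace=False),
    ])
    hypo_pool = np.setdiff1d(np.flatnonzero(hypo_ok), hyper_idx)
    hypo_idx = rng.choice(hypo_pool, min(len(hypo_pool), n_hypo), replace=False)
    status[hyper_idx] = 1
    status[hypo_idx] = -1
    m_t[hyper_idx] = m_n[hyper_idx] + delta
    m_t[hypo_idx] = m_n[hypo_idx] - delta
    prom_hyper = hyper_idx[site_gene[hyper_idx] >= 0]
    regulatory[prom_hyper] = rng.random(len(prom_hyper)) < cfg.fraction_regulatory
    return status, m_t, regulatory


def _presence(cfg, status, rng):
    """CpG x tumor-sample presence of planted events (clonal/subclonal and
    patient-prevalence structure)."""
    P, R = cfg.n_patients, cfg.regions_per_patient
    n = len(status)
    present = np.zeros((n, P * R), dtype=bool)
    is_event = status != 0
    idx = np.flatnonzero(is_event)
    if idx.size == 0:
        return present, np.zeros(n, dtype=bool)
    clonal = np.zeros(n, dtype=bool)
    clonal[idx] = rng.random(idx.size) < cfg.clonal_fraction
    affected = rng.random((idx.size, P)) < cfg.dmp_patient_fraction
    none = ~affected.any(axis=1)
    affected[none, rng.integers(0, P, none.sum())] = True
    # subclonal events occupy a strict subset of 1..R-1 regions per patient
    ranks = np.argsort(rng.random((idx.size, P, R)), axis=2)
    k_sub = rng.integers(1, max(2, R), size=(idx.size, P))
    sub_mask = ranks < k_sub[:, :, None]
    full = np.ones((idx.size, P, R), dtype=bool)
    chosen = np.where(clonal[idx][:, None, None], full, sub_mask)
    chosen &= affected[:, :, None]
    present[idx] = chosen.reshape(idx.size, P * R)
    return present, clonal


def _segments_for(cfg, sample_id, promoters, amp_window, amplified, rng):
    """Piecewise-constant total CN per chromosome, 1-3 breakpoints."""
    rows = []
    chrom_len = _GENES_PER_CHROM * _GENE_SPACING + 100_000
    base_choices = np.array([1, 2, 3, 4])
    base_probs = np.array([0.08, 0.75, 0.14, 0.03])
    for chrom in promoters["chrom"].unique():
        amp = amp_window if (amplified and amp_window and amp_window[0] == chrom) else None
        if amp is not None:
            _, a_start, a_end, n_amp = amp
            if a_start > 1:
                rows.append((sample_id, chrom, 1, a_start - 1, 2, cfg.n_n))
            rows.append((sample_id, chrom, a_start, a_end, n_amp, cfg.n_n))
            if a_end < chrom_len:
                rows.append((sample_id, chrom, a_end + 1, chrom_len, 2, cfg.n_n))
        else:
            n_bp = rng.integers(1, 4)
            bps = np.sort(rng.integers(2, chrom_len, n_bp))
            bounds = np.concatenate([[1], bps, [chrom_len + 1]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                n_t = rng.choice(base_choices, p=base_probs)
                rows.append((sample_id, chrom, int(s), int(e - 1), int(n_t), cfg.n_n))
    return rows


def plant_amplicon_with_compensation(truth: GroundTruth, oncogene_id: str,
                                     passenger_ids: list[str], n_t_amp: int,
                                     amplified_samples: list[str],
                                     meth_shift: float = 0.3,
                                     span_bp: int = 20_000_000) -> GroundTruth:
    """Plant an amplified oncogene with methylation-dosage-compensated
    passengers into the ground truth.

    In amplified samples the oncogene promoter is demethylated (open) and its
    expression scales with copy number, while each passenger promoter gains
    ``meth_shift`` (>= 0.2) methylation and its expression stays at baseline.
    Passengers must lie within ``span_bp`` of the oncogene on one chromosome.
    """
    if meth_shift < 0.2:
        raise ValueError("compensated passengers need a methylation shift >= 0.2")
    gidx = {g: i for i, g in enumerate(truth.gene_ids)}
    oi = gidx[oncogene_id]
    for p in passenger_ids:
        pi = gidx[p]
        if truth.gene_chrom[pi] != truth.gene_chrom[oi]:
            raise ValueError(f"passenger {p} on a different chromosome than {oncogene_id}")
        if abs(int(truth.gene_tss[pi]) - int(truth.gene_tss[oi])) > span_bp:
            raise ValueError(f"passenger {p} farther than {span_bp} bp from {oncogene_id}")
    n = len(truth.m_n)
    if truth.amp_delta is None:
        truth.amp_delta = np.zeros(n)
        truth.amp_of_site = np.full(n, -1, dtype=np.int64)
        truth.amp_sample_mask = np.zeros((0, len(truth.tumor_samples)), dtype=bool)
    amp_id = truth.amp_sample_mask.shape[0]
    mask = np.array([s in set(amplified_samples) for s in truth.tumor_samples])
    truth.amp_sample_mask = np.vstack([truth.amp_sample_mask, mask[None, :]])
    onco_sites = np.flatnonzero(truth.site_gene == oi)
    truth.amp_delta[onco_sites] = -0.2
    truth.amp_of_site[onco_sites] = amp_id
    for p in passenger_ids:
        psites = np.flatnonzero(truth.site_gene == gidx[p])
        truth.amp_delta[psites] = meth_shift
        truth.amp_of_site[psites] = amp_id
    truth.amplicons.append({
        "oncogene": oncogene_id,
        "passengers": list(passenger_ids),
        "n_t_amp": int(n_t_amp),
        "amplified_samples": list(amplified_samples),
    })
    return truth


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full multi-region cohort plus ground truth.

    Bulk tumor counts are binomial draws around
    ``m_b = (m_t n_t rho + m_n n_n (1-rho)) / (n_t rho + n_n (1-rho))``;
    normal counts are binomial draws around ``m_n``.  Identical config+seed
    gives identical outputs.
    """
    cfg = config
    promoters, sites, site_gene = _genome_layout(cfg)
    P, R = cfg.n_patients, cfg.regions_per_patient
    tumor_samples = [f"P{p:02d}_R{r + 1}" for p in range(P) for r in range(R)]
    normal_samples = [f"P{p:02d}_N" for p in range(P)]

    rng_m = cfg.rng(1)
    m_n = _normal_methylome(cfg, site_gene, rng_m)
    status, m_t_event, regulatory = _plant_dmps(cfg, m_n, site_gene, rng_m)
    present, clonal = _presence(cfg, status, cfg.rng(2))

    rng_s = cfg.rng(3)
    purity = {s: float(rng_s.uniform(*cfg.purity_range)) for s in tumor_samples}
    contexts = pd.DataFrame(
        [(s, s.split("_")[0], s.split("_")[1], "tumor", purity[s], "NSCLC", cfg.ploidy)
         for s in tumor_samples]
        + [(s, s.split("_")[0], "N", "normal", 1.0, "NAT", 2.0) for s in normal_samples],
        columns=["sample_id", "patient_id", "region_id", "tissue", "purity", "histology", "ploidy"],
    )

    truth = GroundTruth(
        m_n=m_n, m_t_event=m_t_event, dmp_status=status, clonal=clonal,
        present=present, regulatory=regulatory, tumor_samples=tumor_samples,
        site_gene=site_gene, gene_ids=list(promoters["gene_id"]),
        gene_chrom=promoters["chrom"].to_numpy(), gene_tss=promoters["tss"].to_numpy(),
        baseline_expression=np.zeros(cfg.n_genes), purity=purity,
    )

    # amplicons: oncogene + neighboring passengers, amplified in half the patients
    rng_a = cfg.rng(4)
    amp_windows: dict[str, tuple] = {}
    n_amp_copies = int(round(cfg.ploidy)) + 2
    if cfg.n_amplicons > 0 and cfg.n_genes >= 3:
        onco_choices = rng_a.choice(cfg.n_genes, size=cfg.n_amplicons, replace=False)
        for amp_i, oi in enumerate(sorted(onco_choices)):
            chrom = truth.gene_chrom[oi]
            tss = int(truth.gene_tss[oi])
            near = np.flatnonzero(
                (truth.gene_chrom == chrom)
                & (np.abs(truth.gene_tss.astype(np.int64) - tss) <= min(cfg.amplicon_span_bp, 2_000_000))
                & (np.arange(cfg.n_genes) != oi)
            )
            passengers = [truth.gene_ids[i] for i in near[:3]]
            amp_patients = [f"P{p:02d}" for p in rng_a.choice(P, size=P // 2, replace=False)]
            amped = [s for s in tumor_samples if s.split("_")[0] in amp_patients]
            lo = max(1, tss - 1_500_000)
            hi = tss + 2_500_000
            amp_windows[truth.gene_ids[oi]] = (chrom, lo, hi, n_amp_copies, set(amped))
            if cfg.amplicon_effects:
                plant_amplicon_with_compensation(
                    truth, truth.gene_ids[oi], passengers, n_amp_copies, amped,
                    span_bp=cfg.amplicon_span_bp,
                )
            else:
                truth.amplicons.append({
                    "oncogene": truth.gene_ids[oi], "passengers": passengers,
                    "n_t_amp": n_amp_copies, "amplified_samples": amped,
                })

    # copy-number segments
    rng_c = cfg.rng(5)
    seg_rows = []
    for s in tumor_samples:
        win = None
        for onco, (chrom, lo, hi, namp, amped) in amp_windows.items():
            if s in amped:
                win = (chrom, lo, hi, namp)
                break
        seg_rows.extend(_segments_for(cfg, s, promoters, win, win is not None, rng_c))
    segments = pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end", "n_t", "n_n"])

    # read counts
    rng_r = cfg.rng(6)
    n_sites = len(sites)
    samples = tumor_samples + normal_samples
    meth = np.zeros((n_sites, len(samples)), dtype=np.int64)
    total = np.zeros_like(meth)
    from .deconvolution import lookup_segment_cn, mix_forward

    for j, s in enumerate(tumor_samples):
        n_t = lookup_segment_cn(sites, segments, s).astype(float)
        n_t = np.where(n_t < 0, 2.0, n_t)
        rho = purity[s]
        m_t = truth.tumor_rate(j)
        wt, wn = n_t * rho, cfg.n_n * (1.0 - rho)
        m_b = np.where(wt + wn > 0, (m_t * wt + m_n * wn) / np.maximum(wt + wn, 1e-12), m_n)
        cov = rng_r.poisson(cfg.coverage_mean, n_sites)
        total[:, j] = cov
        meth[:, j] = rng_r.binomial(cov, m_b)
    for p in range(P):
        j = len(tumor_samples) + p
        cov = rng_r.poisson(cfg.coverage_mean, n_sites)
        total[:, j] = cov
        meth[:, j] = rng_r.binomial(cov, m_n)
    cohort = CohortMethylation(sites, samples, meth, total)

    # expression
    rng_e = cfg.rng(7)
    baseline = rng_e.lognormal(np.log(100.0), 1.0, cfg.n_genes)
    truth.baseline_expression = baseline
    expr = np.zeros((cfg.n_genes, len(samples)))
    reg_sites = np.flatnonzero(regulatory & (status == 1) & (site_gene >= 0))
    onco_scale = {a["oncogene"]: (a["n_t_amp"] / cfg.ploidy, set(a["amplified_samples"]))
                  for a in truth.amplicons}
    for j, s in enumerate(tumor_samples):
        mean = baseline.copy()
        hit_genes = np.unique(site_gene[reg_sites[present[reg_sites, j]]])
        mean[hit_genes] = mean[hit_genes] * cfg.regulatory_expression_drop
        if cfg.amplicon_effects:
            for onco, (scale, amped) in onco_scale.items():
                if s in amped:
                    mean[truth.gene_ids.index(onco)] *= scale
        expr[:, j] = mean * rng_e.lognormal(0.0, cfg.expression_sigma, cfg.n_genes)
    for p in range(P):
        j = len(tumor_samples) + p
        expr[:, j] = baseline * rng_e.lognormal(0.0, cfg.expression_sigma, cfg.n_genes)
    expression = pd.DataFrame(expr, index=pd.Index(truth.gene_ids, name="gene_id"),
                              columns=samples)

    histone = _histone_signals(cfg, truth, samples, cfg.rng(8)) if truth.amplicons else None
    return SimulatedCohort(cohort, contexts, segments, expression, promoters, truth,
                           histone, cfg)


def _histone_signals(cfg, truth, samples, rng):
    """TSS-window H3K4me3/H3K27me3 sums for amplicon genes: open chromatin at
    the oncogene, closed at compensated passengers, when amplified."""
    rows = []
    base = {"H3K4me3": 50.0, "H3K27me3": 30.0}
    normal_ids = [s for s in samples if s not in truth.tumor_samples]
    for amp in truth.amplicons:
        genes = [(amp["oncogene"], "onco")] + [(p, "pass") for p in amp["passengers"]]
        amped = set(amp["amplified_samples"])
        for g, role in genes:
            for s in truth.tumor_samples:
                if s in amped and cfg.amplicon_effects:
                    k4 = base["H3K4me3"] * (4.0 if role == "onco" else 0.25)
                    k27 = base["H3K27me3"] * (0.25 if role == "onco" else 4.0)
                else:
                    k4, k27 = base["H3K4me3"], base["H3K27me3"]
                rows.append((g, s, "H3K4me3", k4 * rng.lognormal(0.0, 0.2)))
                rows.append((g, s, "H3K27me3", k27 * rng.lognormal(0.0, 0.2)))
            for s in normal_ids:
                rows.append((g, s, "H3K4me3", base["H3K4me3"] * rng.lognormal(0.0, 0.2)))
                rows.append((g, s, "H3K27me3", base["H3K27me3"] * rng.lognormal(0.0, 0.2)))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "mark", "window_sum"])


# ---------------------------------------------------------------------------
# read-level epialleles
# ---------------------------------------------------------------------------

def simulate_reads_for_pdr(sim: SimulatedCohort, reads_per_window: int = 60,
                           k: int = 4, pdr_t_range=(0.15, 0.45),
                           pdr_n_range=(0.02, 0.15), seed: int | None = None) -> pd.DataFrame:
    """Read-level epiallele table for promoter windows.

    Each read covers ``k`` CpGs of one promoter; a discordant read mixes
    methylated and unmethylated CpGs, a concordant read is uniform.  Bulk
    tumor reads are drawn from the tumor compartment with probability
    n_t*rho / (n_t*rho + n_n*(1-rho)) and from the normal compartment
    otherwise, so the empirical bulk PDR follows the forward mixture of the
    true compartment PDRs.  Also fills ``sim.truth.pdr_t`` / ``pdr_n``.
    """
    if k < 2:
        raise ValueError("reads must span at least 2 CpGs")
    cfg = sim.config
    rng = np.random.default_rng([int(seed if seed is not None else cfg.seed), 9])
    n_genes = len(sim.truth.gene_ids)
    pdr_t = rng.uniform(*pdr_t_range, n_genes)
    pdr_n = rng.uniform(*pdr_n_range, n_genes)
    sim.truth.pdr_t, sim.truth.pdr_n = pdr_t, pdr_n
    from .deconvolution import lookup_segment_cn

    ctx = sim.contexts.set_index("sample_id")
    rows = []
    rid = 0
    tss_sites = sim.promoters.rename(columns={"tss": "pos"})[["chrom", "pos"]]
    for s in sim.cohort.samples:
        tissue = ctx.loc[s, "tissue"]
        if tissue == "tumor":
            rho = float(ctx.loc[s, "purity"])
            n_t = lookup_segment_cn(tss_sites, sim.segments, s).astype(float)
            n_t = np.where(n_t < 0, 2.0, n_t)
            w_t = n_t * rho
            w_n = cfg.n_n * (1.0 - rho)
            p_tumor = w_t / (w_t + w_n)
        else:
            p_tumor = np.zeros(n_genes)
        for g in range(n_genes):
            from_tumor = rng.random(reads_per_window) < p_tumor[g]
            p_disc = np.where(from_tumor, pdr_t[g], pdr_n[g])
            disc = rng.random(reads_per_window) < p_disc
            meth_all = rng.random(reads_per_window) < 0.5
            for i in range(reads_per_window):
                if disc[i]:
                    n_m = rng.integers(1, k)
                    pattern = np.array(["U"] * k)
                    pattern[rng.choice(k, n_m, replace=False)] = "M"
                    states = "".join(pattern)
                else:
                    states = ("M" if meth_all[i] else "U") * k
                rows.append((f"r{rid}", s, sim.truth.gene_ids[g], states))
                rid += 1
    return pd.DataFrame(rows, columns=["read_id", "sample_id", "window_id", "states"])


# ---------------------------------------------------------------------------
# focused generators for specific study designs
# ---------------------------------------------------------------------------

def simulate_mrmn_events(n_genes: int = 200, n_planted: int = 20, n_samples: int = 10,
                         rate_planted_regulatory: float = 0.8,
                         rate_planted_nonregulatory: float = 0.1,
                         rate_null: float = 0.3,
                         cpgs_per_class=(3, 9), seed: int = 0):
    """Per-gene regulatory/nonregulatory hypermethylation event tables.

    Planted genes hypermethylate regulatory CpGs at ``rate_planted_regulatory``
    and nonregulatory CpGs at ``rate_planted_nonregulatory`` (regulatory-
    selective silencing); null genes use ``rate_null`` for both classes.
    CpG counts per class vary across genes so null robustness to promoter CpG
    content can be assessed.  Returns (events, planted_genes) where ``events``
    has one row per (gene, cpg, sample) with ``regulatory`` and ``hyper``.
    """
    rng = np.random.default_rng([seed, 10])
    recs = []
    planted = [f"G{i:04d}" for i in range(n_planted)]
    for g in range(n_genes):
        gid = f"G{g:04d}"
        n_reg = int(rng.integers(*cpgs_per_class))
        n_non = int(rng.integers(*cpgs_per_class))
        is_planted = g < n_planted
        r_reg = rate_planted_regulatory if is_planted else rate_null
        r_non = rate_planted_nonregulatory if is_planted else rate_null
        for c in range(n_reg + n_non):
            reg = c < n_reg
            rate = r_reg if reg else r_non
            hyper = rng.random(n_samples) < rate
            for s in range(n_samples):
                recs.append((gid, f"{gid}_c{c}", f"S{s}", bool(reg), bool(hyper[s])))
    events = pd.DataFrame(recs, columns=["gene_id", "cpg_id", "sample_id", "regulatory", "hyper"])
    return events, planted


def simulate_expression_methylation_cohort(n_patients: int = 12, n_regions: int = 2,
                                           n_genes: int = 8, drop: float = 0.5,
                                           sigma: float = 0.3, seed: int = 0,
                                           prefix: str = "P"):
    """Paired expression / promoter-hypermethylation cohort for threshold
    dichotomization studies.

    Each gene keeps a fixed baseline expression (a gene property, identical
    across cohorts so fitted thresholds transfer); hypermethylated samples
    express ``drop`` times the baseline with lognormal noise ``sigma``.
    Returns (expression, hyper_status, contexts).
    """
    rng = np.random.default_rng(seed)
    samples = [f"{prefix}{p}_R{r}" for p in range(n_patients) for r in range(n_regions)]
    contexts = pd.DataFrame(
        [(s, s.split("_")[0], s.split("_")[1], "tumor", 0.7, "NSCLC", 2.0)
         for s in samples],
        columns=["sample_id", "patient_id", "region_id", "tissue", "purity",
                 "histology", "ploidy"])
    genes = [f"g{i}" for i in range(n_genes)]
    hyper = pd.DataFrame(rng.random((n_genes, len(samples))) < 0.5,
                         index=genes, columns=samples)
    base = np.random.default_rng(987).lognormal(np.log(100.0), 0.5, n_genes)
    expr = pd.DataFrame(index=genes, columns=samples, dtype=float)
    for s in samples:
        expr[s] = base * np.where(hyper[s], drop, 1.0) * rng.lognormal(0.0, sigma, n_genes)
    return expr, hyper, contexts


def simulate_allchat_candidates(n_pairs: int = 100, n_planted: int = 10,
                                n_gained: int = 10, n_not_gained: int = 10,
                                meth_effect: float = 0.25, histone_effect: float = 1.2,
                                noise_meth: float = 0.05, noise_histone: float = 0.25,
                                nongained_margin: float = 0.05, seed: int = 0):
    """Candidate oncogene-passenger pairs for chromatin-transition detection.

    Planted pairs show, in the gained stratum, oncogene tumor-normal
    methylation differential below the passenger's, higher H3K4me3 and lower
    H3K27me3 log-ratios; in the non-gained stratum the contrasts sit at (or
    slightly beyond, ``nongained_margin``) equality in the permitted
    direction.  Null pairs have identical profiles in both strata.

    Returns (pairs, data) where ``data`` maps pair_id -> dict of per-sample
    arrays keyed (gene_role, quantity, stratum).
    """
    rng = np.random.default_rng([seed, 11])
    pairs = []
    data = {}
    for i in range(n_pairs):
        pid = f"pair{i:03d}"
        planted = i < n_planted
        d = {}
        for stratum, n in (("gained", n_gained), ("not_gained", n_not_gained)):
            if planted and stratum == "gained":
                onco_m = rng.normal(-meth_effect, noise_meth, n)
                pass_m = rng.normal(+meth_effect, noise_meth, n)
                onco_k4 = rng.normal(+histone_effect, noise_histone, n)
                pass_k4 = rng.normal(-histone_effect, noise_histone, n)
                onco_k27 = rng.normal(-histone_effect, noise_histone, n)
                pass_k27 = rng.normal(+histone_effect, noise_histone, n)
            elif planted:
                onco_m = rng.normal(+nongained_margin, noise_meth, n)
                pass_m = rng.normal(0.0, noise_meth, n)
                onco_k4 = rng.normal(-nongained_margin, noise_histone, n)
                pass_k4 = rng.normal(0.0, noise_histone, n)
                onco_k27 = rng.normal(+nongained_margin, noise_histone, n)
                pass_k27 = rng.normal(0.0, noise_histone, n)
            else:
                onco_m = rng.normal(0.0, noise_meth, n)
                pass_m = rng.normal(0.0, noise_meth, n)
                onco_k4 = rng.normal(0.0, noise_histone, n)
                pass_k4 = rng.normal(0.0, noise_histone, n)
                onco_k27 = rng.normal(0.0, noise_histone, n)
                pass_k27 = rng.normal(0.0, noise_histone, n)
            d[("onco", "meth", stratum)] = onco_m
            d[("pass", "meth", stratum)] = pass_m
            d[("onco", "H3K4me3", stratum)] = onco_k4
            d[("pass", "H3K4me3", stratum)] = pass_k4
            d[("onco", "H3K27me3", stratum)] = onco_k27
            d[("pass", "H3K27me3", stratum)] = pass_k27
        data[pid] = d
        pairs.append({"pair_id": pid, "oncogene_id": f"ONC{i:03d}",
                      "passenger_id": f"PAS{i:03d}", "planted": planted})
    return pd.DataFrame(pairs), data
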