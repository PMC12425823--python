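# methevolve

Tools for studying how DNA methylation evolves alongside genomic
alterations in multi-region tumor sequencing cohorts (reduced-representation
bisulfite sequencing plus expression and copy-number data), written for
analysts working with purity- and copy-number-confounded bulk methylomes.

A bulk tumor methylation rate mixes tumor and normal cells.  With purity ρ,
tumor total copy number n_t and normal copy number n_n, the bulk rate of any
per-read statistic (methylation rate m, or the proportion of discordant
reads PDR) is

    m_b = (m_t n_t ρ + m_n n_n (1 − ρ)) / (n_t ρ + n_n (1 − ρ)),

which the package inverts exactly to recover the cancer-cell-specific
m_t (and PDR_t).  On top of the deconvolved rates it implements:

- **DMP/DMR calling** — tumor-normal differential methylation at the
  effect > 0.2, p < 0.01 thresholds, per sample and cohort-level
  (patient-pooled mid-p scores, Stouffer combination); DMRs from 100 bp
  CpG neighborhoods with ≥4 consecutive and ≥5 total DMPs; promoter status,
  multi-region ubiquity/clonality.
- **ITMD / ITED** — intratumor methylation and expression heterogeneity as
  pairwise correlation distances (1 − Pearson r) between regions.
- **Driver ranking (DHcR)** — the differentially hypermethylated cytosine
  ratio per promoter, compared against a beta-regression expectation from
  stochastic-hypermethylation covariates (promoter PDR, normal methylation,
  normal expression, CpG content).
- **M_R/M_N** — a dN/dS-style selection ratio contrasting hypermethylation
  rates at expression-regulatory vs nonregulatory promoter CpGs,
  pseudocounted, with an exact 2×2 deviation test and BH FDR.
- **CN–methylation interplay** — double-hit vs parallel classification,
  clonal/subclonal timing contingency, methylation-dependent dosage
  compensation at amplicons, and AllChAT detection (divergent
  methylation/H3K4me3/H3K27me3 response of an oncogene vs a co-amplified
  neighbor under the same CN event).
- **Dichotomization** — bootstrap expression thresholds that proxy promoter
  hypermethylation, transferable to expression-only cohorts.
- **Synthetic cohorts** — a seeded generator producing bulk methylation
  counts, CN segments, expression, promoters, epiallele reads and full
  ground truth, so every stage is testable without controlled-access data.

## Worked example

```python
from methevolve.simulate import SimulationConfig, simulate_cohort
from methevolve.deconvolution import deconvolve_cohort
from methevolve.diffmeth import call_dmps_cohort
import numpy as np

sim = simulate_cohort(SimulationConfig(seed=1))   # 20 patients x 3 regions, 50k CpGs
dec = deconvolve_cohort(sim.cohort, sim.contexts, sim.segments)
truth = np.column_stack([sim.truth.tumor_rate(j) for j in range(len(dec.samples))])
ok = np.isfinite(dec.m_t_hat)
print("r(m_t_hat, m_t) =", round(np.corrcoef(dec.m_t_hat[ok], truth[ok])[0, 1], 3))

calls = call_dmps_cohort(sim.cohort, sim.contexts, sim.segments)
planted = sim.truth.dmp_status != 0
print("DMPs called:", int((calls["status"] != 0).sum()),
      "of", int(planted.sum()), "planted")
```

prints

```
r(m_t_hat, m_t) = 0.975
DMPs called: 2621 of 2500 planted
```

i.e. the deconvolved rates track the true tumor-compartment rates at
Pearson r ≈ 0.98 despite purities down to 0.3 at 30× coverage, and the
cohort-level caller recovers the planted differential positions (the excess
over 2,500 comes from amplicon-driven promoter shifts the generator also
plants; sensitivity and false-discovery rate are quantified in
`scripts/acceptance.py` output).

A shell interface covers the file-based stages:

```sh
methevolve simulate --config cfg.toml --outdir cohort/
methevolve deconvolve --meth cohort/ --segments cohort/segments.tsv \
    --samples cohort/sample_metadata.tsv --out rates.tsv
methevolve dmp --meth cohort/ --segments cohort/segments.tsv \
    --samples cohort/sample_metadata.tsv --out dmps.tsv
methevolve dmr --dmps dmps.tsv --out dmrs.tsv
methevolve itmd --rates rates.tsv --samples cohort/sample_metadata.tsv --out itmd.tsv
methevolve mrmn --events events.tsv --out mrmn.tsv
```

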