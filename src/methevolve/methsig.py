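"""Driver-gene ranking by expected-vs-observed promoter hypermethylation.

Per tumor sample (one region per patient, the highest-purity one), the
observed promoter DHcR of each gene is compared against the DHcR expected
from covariates that drive stochastic hypermethylation — promoter epiallele
discordance (deconvolved PDR), the normal-tissue methylation level, normal
expression and promoter CpG content — via a beta regression across genes.
One-sided per-gene p-values (observed above expectation) are combined across
samples with Stouffer's method and BH-adjusted.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr

try:  # statsmodels >= 0.14
    from statsmodels.othermod.betareg import BetaModel
except ImportError:  # pragma: no cover
    BetaModel = None


def select_highest_purity(contexts: pd.DataFrame) -> list[str]:
    """One tumor sample per patient: highest purity, lexicographic sample_id
    tie-break (deterministic)."""
    tum = contexts[contexts["tissue"] == "tumor"].copy()
    tum = tum.sort_values(["patient_id", "purity", "sample_id"],
                          ascending=[True, False, True])
    return list(tum.groupby("patient_id", sort=True).head(1)["sample_id"])


def filter_genes(dhcr: pd.DataFrame, normal_expression: pd.Series,
                 min_normal_expression: float = 1.0) -> pd.DataFrame:
    """Drop genes with no coverage in all samples or silent in normal tissue
    (mean normal expression below ``min_normal_expression`` counts)."""
    covered = dhcr.notna().any(axis=1)
    expressed = normal_expression.reindex(dhcr.index).fillna(0.0) >= min_normal_expression
    return dhcr.loc[covered & expressed]


@dataclass
class MethSigResults:
    """Per-gene ranking output; ``table`` carries expected/observed DHcR,
    combined p and BH q; ``converged`` lists per-sample fit status."""

    table: pd.DataFrame
    converged: dict[str, bool]

    def top(self, q: float = 0.1) -> pd.DataFrame:
        return self.table[self.table["q"] < q].sort_values("p_combined")


def _smooth(y: np.ndarray) -> np.ndarray:
    # squeeze observed ratios off the {0,1} boundary for the beta likelihood
    n = np.isfinite(y).sum()
    return (y * (n - 1) + 0.5) / n


def methsig_rank(dhcr: pd.DataFrame, covariates: pd.DataFrame,
                 samples: list[str] | None = None) -> MethSigResults:
    """Rank genes by excess observed promoter DHcR over the beta-regression
    expectation.

    ``dhcr``: genes x samples observed tumor DHcR (NaN = not profiled).
    ``covariates``: genes x covariate frame (e.g. promoter PDR, normal
    methylation, log normal expression, promoter CpG count); constant added
    internally.  Samples whose fit fails to converge are flagged and skipped
    in the combination, not silently dropped.
    """
    if BetaModel is None:  # pragma: no cover
        raise ImportError("statsmodels with BetaModel is required")
    if samples is None:
        samples = list(dhcr.columns)
    X = covariates.reindex(dhcr.index)
    Xc = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    z_rows = {}
    expected = pd.DataFrame(index=dhcr.index, columns=samples, dtype=float)
    converged = {}
    for s in samples:
        y = dhcr[s].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.all(np.isfinite(Xc), axis=1)
        ys = _smooth(y[ok])
        try:
            fit = BetaModel(ys, Xc[ok]).fit(disp=False)
            converged[s] = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            converged[s] = False
            continue
        k = Xc.shape[1]
        mu = np.clip(special_expit(Xc[ok] @ fit.params[:k]), 1e-6, 1 - 1e-6)
        phi = np.exp(fit.params[k:]).item() if fit.params.size > k else np.exp(fit.params[-1])
        # one-sided: observed DHcR above its expected beta distribution
        p_one = stats.beta.sf(ys, mu * phi, (1.0 - mu) * phi)
        z = stats.norm.isf(np.clip(p_one, 1e-300, 1 - 1e-16))
        col = np.full(len(y), np.nan)
        col[ok] = z
        z_rows[s] = col
        exp_col = np.full(len(y), np.nan)
        exp_col[ok] = mu
        expected[s] = exp_col
    if not z_rows:
        raise RuntimeError("beta regression failed for every sample")
    Z = pd.DataFrame(z_rows, index=dhcr.index)
    n_obs = Z.notna().sum(axis=1)
    z_comb = Z.sum(axis=1, skipna=True) / np.sqrt(n_obs.clip(lower=1))
    p_comb = pd.Series(stats.norm.sf(z_comb), index=dhcr.index)
    p_comb[n_obs == 0] = np.nan
    table = pd.DataFrame({
        "expected_dhcr": expected.mean(axis=1),
        "observed_dhcr": dhcr[samples].mean(axis=1),
        "n_samples": n_obs,
        "z_combined": z_comb,
        "p_combined": p_comb,
        "q": bh_fdr(p_comb.to_numpy()),
    })
    return MethSigResults(table=table.sort_values("p_combined"), converged=converged)


def special_expit(x):
    return 1.0 / (1.0 + np.exp(-x))
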