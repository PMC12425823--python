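"""Intratumor and intertumor heterogeneity distances (ITMD / ITED).

Both metrics are correlation distances d = 1 − Pearson r (range [0, 2])
between paired sample vectors: per-CpG deconvolved methylation rates for
ITMD, normalized gene expression for ITED.  Feature sets are intersected per
pair (CpGs covered in both regions) and the number of shared features is
reported so callers can enforce a floor.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def _pair_distance(x: np.ndarray, y: np.ndarray):
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 2:
        return np.nan, n
    xs, ys = x[ok], y[ok]
    if xs.std() == 0.0 or ys.std() == 0.0:
        return np.nan, n  # correlation undefined for a constant vector
    r = np.corrcoef(xs, ys)[0, 1]
    return 1.0 - r, n


def compute_itmd(rates: pd.DataFrame, contexts: pd.DataFrame,
                 scope: str = "intra", min_features: int = 1) -> pd.DataFrame:
    """Pairwise methylation correlation distances.

    ``rates``: CpG x sample frame of (deconvolved) methylation rates, NaN
    where uncovered.  ``scope='intra'`` pairs regions within each patient,
    ``'inter'`` pairs regions across patients (all cross-patient pairs).
    Pairs with fewer than ``min_features`` shared CpGs, or an undefined
    correlation, are skipped with a warning.
    """
    if scope not in ("intra", "inter"):
        raise ValueError("scope must be 'intra' or 'inter'")
    ctx = contexts.set_index("sample_id")
    samples = [s for s in rates.columns if s in ctx.index and ctx.loc[s, "tissue"] == "tumor"]
    if scope == "intra":
        groups = {}
        for s in samples:
            groups.setdefault(ctx.loc[s, "patient_id"], []).append(s)
        if all(len(g) < 2 for g in groups.values()):
            raise ValueError("intra-patient ITMD needs >= 2 regions for some patient")
    rows = []
    vals = rates[samples].to_numpy(dtype=float)
    col = {s: i for i, s in enumerate(samples)}
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            pa, pb = ctx.loc[a, "patient_id"], ctx.loc[b, "patient_id"]
            if (scope == "intra") != (pa == pb):
                continue
            d, n = _pair_distance(vals[:, col[a]], vals[:, col[b]])
            if not np.isfinite(d) or n < min_features:
                warnings.warn(f"skipping pair ({a}, {b}): "
                              f"{'undefined correlation' if not np.isfinite(d) else 'too few shared CpGs'}")
                continue
            rows.append((pa, pb, a, b, d, n))
    return pd.DataFrame(rows, columns=["patient_a", "patient_b", "sample_a",
                                       "sample_b", "distance", "n_features"])


def itmd_per_patient(pairs: pd.DataFrame) -> pd.Series:
    """Mean intra-patient distance per patient (scope='intra' output)."""
    return pairs.groupby("patient_a")["distance"].mean()


def normalize_expression(expression: pd.DataFrame) -> pd.DataFrame:
    """log2(x+1) then per-gene z-score across the given samples."""
    x = np.log2(expression.astype(float) + 1.0)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0).replace(0.0, np.nan)
    return x.sub(mu, axis=0).div(sd, axis=0)


def compute_ited(expression: pd.DataFrame, contexts: pd.DataFrame) -> pd.DataFrame:
    """Per-region expression heterogeneity: mean 1 − r of each tumor region
    against its sibling regions, on normalized expression.

    Returns one row per region with >= 1 sibling plus the per-patient mean in
    ``.attrs['per_patient']``.
    """
    ctx = contexts.set_index("sample_id")
    samples = [s for s in expression.columns
               if s in ctx.index and ctx.loc[s, "tissue"] == "tumor"]
    norm = normalize_expression(expression[samples])
    vals = norm.to_numpy(dtype=float)
    col = {s: i for i, s in enumerate(samples)}
    groups: dict[str, list[str]] = {}
    for s in samples:
        groups.setdefault(ctx.loc[s, "patient_id"], []).append(s)
    rows = []
    for pid, members in groups.items():
        if len(members) < 2:
            continue
        for a in members:
            ds = []
            for b in members:
                if b == a:
                    continue
                d, _ = _pair_distance(vals[:, col[a]], vals[:, col[b]])
                if np.isfinite(d):
                    ds.append(d)
            if ds:
                rows.append((pid, a, float(np.mean(ds)), len(ds)))
    out = pd.DataFrame(rows, columns=["patient_id", "sample_id", "ited", "n_pairs"])
    out.attrs["per_patient"] = out.groupby("patient_id")["ited"].mean()
    return out
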