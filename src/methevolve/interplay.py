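"""Copy-number / methylation interplay: event matrices, double-hit vs
parallel classification, clonal-vs-subclonal timing, dosage-compensation
scanning and oncogene-passenger chromatin-transition (AllChAT) detection.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EVENTS = ("hyper", "hypo", "loss", "gain", "amplification", "mutation")


# ---------------------------------------------------------------------------
# gene x region event matrix
# ---------------------------------------------------------------------------

def classify_gene_events(promoter_status: pd.DataFrame, segments: pd.DataFrame,
                         contexts: pd.DataFrame, promoters: pd.DataFrame,
                         mutations: pd.DataFrame | None = None,
                         amp_offset: float = 2.0) -> pd.DataFrame:
    """Per (gene, tumor sample) boolean event calls.

    ``promoter_status``: genes x samples frame with values hyper/hypo/both/
    none/NaN.  Copy number is taken at the TSS; a gene whose promoter window
    spans a segment boundary is flagged.  loss iff n_t < round(ploidy); gain
    iff n_t > round(ploidy) (amplification, n_t >= ploidy + ``amp_offset``,
    is reported separately and excludes loss by construction).
    """
    from .deconvolution import lookup_segment_cn

    ctx = contexts.set_index("sample_id")
    tumor = [s for s in promoter_status.columns if s in ctx.index
             and ctx.loc[s, "tissue"] == "tumor"]
    tss_sites = promoters.rename(columns={"tss": "pos"})[["chrom", "pos"]].reset_index(drop=True)
    ws = promoters.rename(columns={"window_start": "pos"})[["chrom", "pos"]].reset_index(drop=True)
    we = promoters.rename(columns={"window_end": "pos"})[["chrom", "pos"]].reset_index(drop=True)
    rows = []
    mut_set = set()
    if mutations is not None:
        mut_set = set(zip(mutations["gene_id"], mutations["sample_id"]))
    for s in tumor:
        ploidy = float(ctx.loc[s, "ploidy"])
        n_t = lookup_segment_cn(tss_sites, segments, s)
        n_t_ws = lookup_segment_cn(ws, segments, s)
        n_t_we = lookup_segment_cn(we, segments, s)
        for g_i, g in enumerate(promoters["gene_id"]):
            status = promoter_status.at[g, s] if g in promoter_status.index else np.nan
            nt = int(n_t[g_i])
            if nt < 0:
                loss = gain = amp = False
            else:
                amp = nt >= ploidy + amp_offset
                loss = nt < round(ploidy)
                gain = (nt > round(ploidy)) and not amp
            boundary = (n_t_ws[g_i] != n_t_we[g_i])
            hyper = status in ("hyper", "both")
            hypo = status in ("hypo", "both")
            rows.append((g, s, ctx.loc[s, "patient_id"], ctx.loc[s, "region_id"],
                         hyper, hypo, loss, gain, amp,
                         (g, s) in mut_set, bool(boundary), nt))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "patient_id", "region_id",
                                       "hyper", "hypo", "loss", "gain", "amplification",
                                       "mutation", "boundary_flagged", "n_t"])


# ---------------------------------------------------------------------------
# double hit / parallel / concordance
# ---------------------------------------------------------------------------

def classify_interplay(events: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, patient) interplay category plus concordant fraction.

    double_hit: hyper and CN loss co-occur in >= 1 region; parallel: both
    occur in the tumor but never in the same region; single_mechanism:
    exactly one of the two mechanisms present; other: only other events
    (gain/amplification/hypo/mutation); none: no events.  Categories
    partition the (gene, patient) grid.  Concordant regions carry
    hyper+loss or hypo+(gain|amplification).
    """
    rows = []
    for (g, pat), grp in events.groupby(["gene_id", "patient_id"], sort=True):
        hyper = grp["hyper"].to_numpy()
        loss = grp["loss"].to_numpy()
        both_same = bool((hyper & loss).any())
        has_h, has_l = bool(hyper.any()), bool(loss.any())
        if both_same:
            cat = "double_hit"
        elif has_h and has_l:
            cat = "parallel"
        elif has_h or has_l:
            cat = "single_mechanism"
        elif grp[["hypo", "gain", "amplification", "mutation"]].to_numpy().any():
            cat = "other"
        else:
            cat = "none"
        concordant = (hyper & loss) | (grp["hypo"].to_numpy()
                                       & (grp["gain"].to_numpy() | grp["amplification"].to_numpy()))
        any_event = grp[["hyper", "hypo", "loss", "gain", "amplification"]].to_numpy().any(axis=1)
        frac = float(concordant.sum() / any_event.sum()) if any_event.any() else np.nan
        rows.append((g, pat, cat, frac))
    return pd.DataFrame(rows, columns=["gene_id", "patient_id", "category",
                                       "concordant_fraction"])


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------

def timing_patterns(ubiquity_hyper: pd.DataFrame, ubiquity_loss: pd.DataFrame) -> pd.DataFrame:
    """Relative-timing pattern per (gene, patient) from event clonality.

    Inputs are :func:`methevolve.diffmeth.compute_ubiquity` outputs for
    hypermethylation and CN-loss events (feature_id = gene).  Patterns:
    clonal (ubiquitous) hypermethylation with subclonal loss, the reverse,
    both clonal, both subclonal, or ``na`` when either event is absent or
    unassessable (< 2 regions).
    """
    h = ubiquity_hyper.set_index(["feature_id", "patient_id"])
    l = ubiquity_loss.set_index(["feature_id", "patient_id"])
    keys = h.index.union(l.index)
    rows = []
    for key in keys:
        pattern = "na"
        if key in h.index and key in l.index:
            ch = h.loc[key, "clonality"]
            cl = l.loc[key, "clonality"]
            hit_h = h.loc[key, "n_regions_with_event"] > 0
            hit_l = l.loc[key, "n_regions_with_event"] > 0
            if hit_h and hit_l and isinstance(ch, str) and isinstance(cl, str):
                if ch == "ubiquitous" and cl == "subclonal":
                    pattern = "clonal_hyper_subclonal_loss"
                elif ch == "subclonal" and cl == "ubiquitous":
                    pattern = "clonal_loss_subclonal_hyper"
                elif ch == cl == "ubiquitous":
                    pattern = "both_clonal"
                else:
                    pattern = "both_subclonal"
        rows.append((key[0], key[1], pattern))
    return pd.DataFrame(rows, columns=["gene_id", "patient_id", "pattern"])


def timing_contingency(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                       labels: tuple[str, str] = ("set_a", "set_b")) -> dict:
    """2x2 (clonal-hyper-first vs clonal-loss-first) x gene-set contingency.

    Chi-squared without continuity correction by default; switches to the
    exact test (with notice) when any expected cell is below 5.
    """
    def counts(calls):
        hf = int((calls["pattern"] == "clonal_hyper_subclonal_loss").sum())
        lf = int((calls["pattern"] == "clonal_loss_subclonal_hyper").sum())
        return hf, lf

    table = np.array([counts(calls_a), counts(calls_b)])
    return timing_table_test(table, labels)


def timing_table_test(table: np.ndarray, labels=("set_a", "set_b")) -> dict:
    table = np.asarray(table)
    if table.sum() == 0:
        return {"table": table, "labels": labels, "statistic": np.nan,
                "p_value": np.nan, "test": "none"}
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        p = stats.fisher_exact(table)[1]
        return {"table": table, "labels": labels, "statistic": np.nan,
                "p_value": float(p), "test": "fisher_exact",
                "notice": "expected cell < 5; exact test used"}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"table": table, "labels": labels, "statistic": float(chi2),
            "p_value": float(p), "test": "chi2"}


# ---------------------------------------------------------------------------
# dosage compensation
# ---------------------------------------------------------------------------

def dosage_compensation_scan(promoter_meth: pd.DataFrame, expression: pd.DataFrame,
                             amplified: pd.DataFrame, min_regions: int = 3,
                             delta_threshold: float = 0.2,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Methylation-dependent dosage compensation at amplified loci.

    Per gene: difference of median promoter methylation between amplified and
    non-amplified tumor regions (flagged when above ``delta_threshold``), and
    an expression class from a two-sample t-test on log2 expression —
    ``scaling`` (significantly higher when amplified), ``buffered`` (no
    significant difference), ``antiscaling`` (significantly lower).  Genes
    with fewer than ``min_regions`` regions in either stratum are missing.
    """
    rows = []
    for g in promoter_meth.index:
        if g not in amplified.index or g not in expression.index:
            continue
        amp = amplified.loc[g].astype(bool)
        meth = promoter_meth.loc[g]
        expr = np.log2(expression.loc[g, amp.index].astype(float) + 1.0)
        m_amp = meth[amp].dropna()
        m_not = meth[~amp].dropna()
        e_amp = expr[amp].dropna()
        e_not = expr[~amp].dropna()
        if min(len(m_amp), len(m_not), len(e_amp), len(e_not)) < min_regions:
            continue
        delta = float(m_amp.median() - m_not.median())
        t, p = stats.ttest_ind(e_amp, e_not)
        if p < alpha:
            expr_class = "scaling" if t > 0 else "antiscaling"
        else:
            expr_class = "buffered"
        rows.append((g, delta, expr_class, delta > delta_threshold,
                     len(m_amp), len(m_not), float(p)))
    return pd.DataFrame(rows, columns=["gene_id", "delta_median_meth", "expression_class",
                                       "flagged", "n_amplified", "n_not_amplified",
                                       "expression_p"])


# ---------------------------------------------------------------------------
# AllChAT
# ---------------------------------------------------------------------------

def filter_cnas_for_allchat(segments: pd.DataFrame, ploidy: float | dict,
                            min_span: float = 50e6) -> pd.DataFrame:
    """Keep only large CNAs (span >= ``min_span``) and label gain/loss
    relative to the ploidy estimate."""
    seg = segments.copy()
    span = seg["end"] - seg["start"] + 1
    if isinstance(ploidy, dict):
        pl = seg["sample_id"].map(ploidy)
    else:
        pl = float(ploidy)
    direction = np.where(seg["n_t"] > pl, "gain", np.where(seg["n_t"] < pl, "loss", "neutral"))
    seg["direction"] = direction
    keep = (span >= min_span) & (seg["direction"] != "neutral")
    return seg[keep].reset_index(drop=True)


def make_allchat_pairs(oncogene_ids: list[str], promoters: pd.DataFrame,
                       max_distance: float = 20e6) -> pd.DataFrame:
    """Candidate pairs: each annotated oncogene with every gene within
    ``max_distance`` bp on the same chromosome (assumed to share CN events)."""
    prom = promoters.set_index("gene_id")
    rows = []
    for onco in oncogene_ids:
        if onco not in prom.index:
            continue
        oc, ot = prom.at[onco, "chrom"], int(prom.at[onco, "tss"])
        near = promoters[(promoters["chrom"] == oc) & (promoters["gene_id"] != onco)]
        for rec in near.itertuples(index=False):
            dist = abs(int(rec.tss) - ot)
            if dist <= max_distance:
                rows.append((onco, rec.gene_id, dist))
    return pd.DataFrame(rows, columns=["oncogene_id", "passenger_id", "distance_bp"])


def _one_sided_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Paired one-sided t-test p for the per-sample contrast x - y."""
    d = np.asarray(x, float) - np.asarray(y, float)
    if len(d) < 2 or np.all(d == d[0]):
        return 1.0
    t, p_two = stats.ttest_1samp(d, 0.0)
    if alternative == "less":
        return p_two / 2.0 if t < 0 else 1.0 - p_two / 2.0
    return p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0


# (quantity, direction of the oncogene contrast in the gained stratum)
_GAINED_DIRECTIONS = {"meth": "less", "H3K4me3": "greater", "H3K27me3": "less"}
_REVERSE = {"less": "greater", "greater": "less"}


@dataclass
class AllChATVerdict:
    pair_id: str
    oncogene_id: str
    passenger_id: str
    verdict: bool
    partial: bool            # histone tracks missing; methylation-only
    tests: dict              # (quantity, stratum) -> p-value


def allchat_test_pair(pair_data: dict, alpha: float = 0.05,
                      nongained_mode: str = "absence") -> tuple[bool, bool, dict]:
    """Run the stratified one-sided tests for one candidate pair.

    ``pair_data`` maps (role, quantity, stratum) -> per-sample arrays with
    role in {onco, pass}, quantity in {meth, H3K4me3, H3K27me3}, stratum in
    {gained, not_gained}.  In the gained stratum the oncogene must show lower
    tumor-normal methylation differential, higher H3K4me3 and lower H3K27me3
    than the passenger (each one-sided test significant at ``alpha``).  In
    the non-gained stratum the contrast must be compatible with
    equal-or-reversed: mode ``absence`` (default) requires the gained-stratum
    direction NOT to be significant there; mode ``require`` demands a
    significant reverse-direction test.
    """
    if nongained_mode not in ("absence", "require"):
        raise ValueError("nongained_mode must be 'absence' or 'require'")
    quantities = [q for q in ("meth", "H3K4me3", "H3K27me3")
                  if ("onco", q, "gained") in pair_data]
    if "meth" not in quantities:
        raise ValueError("pair data must include methylation differentials")
    partial = len(quantities) < 3
    tests = {}
    ok = True
    for q in quantities:
        direction = _GAINED_DIRECTIONS[q]
        p_g = _one_sided_p(pair_data[("onco", q, "gained")],
                           pair_data[("pass", q, "gained")], direction)
        tests[(q, "gained")] = p_g
        ok &= p_g < alpha
        if ("onco", q, "not_gained") in pair_data:
            if nongained_mode == "absence":
                p_n = _one_sided_p(pair_data[("onco", q, "not_gained")],
                                   pair_data[("pass", q, "not_gained")], direction)
                tests[(q, "not_gained")] = p_n
                ok &= p_n >= alpha
            else:
                p_n = _one_sided_p(pair_data[("onco", q, "not_gained")],
                                   pair_data[("pass", q, "not_gained")], _REVERSE[direction])
                tests[(q, "not_gained")] = p_n
                ok &= p_n < alpha
    return ok, partial, tests


def detect_allchat(pairs: pd.DataFrame, data: dict, alpha: float = 0.05,
                   nongained_mode: str = "absence") -> pd.DataFrame:
    """Apply :func:`allchat_test_pair` to every candidate pair."""
    rows = []
    for rec in pairs.itertuples(index=False):
        pid = rec.pair_id if hasattr(rec, "pair_id") else f"{rec.oncogene_id}|{rec.passenger_id}"
        verdict, partial, tests = allchat_test_pair(data[pid], alpha=alpha,
                                                    nongained_mode=nongained_mode)
        rows.append((pid, rec.oncogene_id, rec.passenger_id, verdict, partial,
                     max(tests[k] for k in tests if k[1] == "gained")))
    return pd.DataFrame(rows, columns=["pair_id", "oncogene_id", "passenger_id",
                                       "verdict", "partial", "max_gained_p"])


def fisher_enrichment(hits: set, universe: set, annotation: set) -> dict:
    """Generic 2x2 Fisher enrichment of a hit set against any gene list."""
    a = len(hits & annotation)
    b = len(hits - annotation)
    c = len((universe - hits) & annotation)
    d = len((universe - hits) - annotation)
    odds, p = stats.fisher_exact([[a, b], [c, d]])
    return {"table": [[a, b], [c, d]], "odds_ratio": odds, "p_value": p}
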