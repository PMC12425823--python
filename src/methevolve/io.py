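"""Readers, writers and promoter-window geometry.

Tabular dialects
----------------
* Methylation: Bismark coverage style — ``chrom  start  end  %meth  count_meth
  count_unmeth`` (tab separated, 1-based inclusive coordinates).  The percent
  column is never trusted; rates are recomputed from the counts.
* Copy-number segments: ``sample_id  chrom  start  end  n_t  [n_n]``.
* Expression: genes (rows) x samples (columns), TSV with a ``gene_id`` column.
* Sample metadata: ``sample_id  patient_id  region_id  tissue  purity
  histology  ploidy``.
* TSS annotation: BED6 (0-based half-open), converted to 1-based at this
  boundary and nowhere else.

All writers emit one ``#``-prefixed comment line recording the tool version
and parameters, then a header line; all readers skip ``#`` lines.
"""
from __future__ import annotations

import io as _io
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__

PROMOTER_UPSTREAM = 2500
PROMOTER_DOWNSTREAM = 250


class ParseError(ValueError):
    """Malformed input row; message names the offending line number."""


class ValidationError(ValueError):
    """Structurally parseable input violating an invariant."""


def _comment(params: dict | None) -> str:
    extra = "" if not params else " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# methevolve {__version__}{extra}\n"


# ---------------------------------------------------------------------------
# methylation tables
# ---------------------------------------------------------------------------

def read_methylation_table(path, sample_id: str, min_total: int = 0) -> pd.DataFrame:
    """Parse a Bismark-coverage-style table into per-CpG observations.

    Returns a frame with columns ``chrom, pos, meth, total, rate`` and a
    ``sample_id`` attribute in ``.attrs``.  Rates are recomputed from counts.
    Rows with ``total < min_total`` are dropped; the number dropped is stored
    in ``.attrs["n_low_coverage"]`` so no row disappears silently.
    """
    rows = []
    n_low = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                pos = int(fields[1])
                end = int(fields[2])
                meth = int(fields[4])
                unmeth = int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric field ({exc})") from None
            if pos < 1 or end < pos:
                raise ParseError(f"{path}: line {lineno}: bad coordinates {pos}-{end}")
            if meth < 0 or unmeth < 0:
                raise ValidationError(f"{path}: line {lineno}: negative read count")
            total = meth + unmeth
            if total < min_total:
                n_low += 1
                continue
            rows.append((chrom, pos, meth, total))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        first = df.loc[dup, ["chrom", "pos"]].iloc[0]
        raise ValidationError(
            f"{path}: duplicate CpG ({first.chrom}, {first.pos}) for sample {sample_id}"
        )
    with np.errstate(invalid="ignore"):
        df["rate"] = np.where(df["total"] > 0, df["meth"] / df["total"], np.nan)
    df.attrs["sample_id"] = sample_id
    df.attrs["n_low_coverage"] = n_low
    return df


def write_methylation_table(df: pd.DataFrame, path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(params))
        for row in df.itertuples(index=False):
            pct = 100.0 * row.meth / row.total if row.total else 0.0
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos}\t{pct:.10g}\t{row.meth}\t{row.total - row.meth}\n"
            )


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

def validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Sort segments and enforce non-overlap per sample/chromosome."""
    seg = segments.sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True)
    if (seg["start"] > seg["end"]).any():
        bad = seg[seg["start"] > seg["end"]].iloc[0]
        raise ValidationError(f"segment start > end: {bad.sample_id} {bad.chrom}:{bad.start}-{bad.end}")
    if (seg["n_t"] < 0).any():
        raise ValidationError("negative tumor copy number")
    for (sid, chrom), grp in seg.groupby(["sample_id", "chrom"], sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        overlap = starts[1:] <= ends[:-1]
        if overlap.any():
            i = int(np.argmax(overlap))
            raise ValidationError(
                f"overlapping segments for {sid} {chrom}: "
                f"[{starts[i]},{ends[i]}] and [{starts[i+1]},{ends[i+1]}]"
            )
    return seg


def read_segments(path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "chrom", "start", "end", "n_t"}
    missing = required - set(seg.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if "n_n" not in seg.columns:
        seg["n_n"] = 2
    return validate_segments(seg)


def write_segments(seg: pd.DataFrame, path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(params))
        seg.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression and sample metadata
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", comment="#").set_index("gene_id")
    if (expr.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative expression values")
    return expr


def write_expression(expr: pd.DataFrame, path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(params))
        expr.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_contexts(path) -> pd.DataFrame:
    ctx = pd.read_csv(path, sep="\t", comment="#")
    return validate_contexts(ctx)


def validate_contexts(ctx: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "patient_id", "region_id", "tissue", "purity", "ploidy"}
    missing = required - set(ctx.columns)
    if missing:
        raise ValidationError(f"sample metadata missing columns {sorted(missing)}")
    bad_tissue = ~ctx["tissue"].isin(["tumor", "normal"])
    if bad_tissue.any():
        raise ValidationError(f"tissue must be tumor|normal, got {ctx.loc[bad_tissue, 'tissue'].iloc[0]!r}")
    tum = ctx["tissue"] == "tumor"
    if ((ctx.loc[tum, "purity"] <= 0) | (ctx.loc[tum, "purity"] > 1)).any():
        raise ValidationError("tumor purity must lie in (0, 1]")
    normals = ctx[ctx["tissue"] == "normal"].groupby("patient_id").size()
    if (normals > 1).any():
        pid = normals[normals > 1].index[0]
        raise ValidationError(f"patient {pid} has more than one normal reference sample")
    if ctx["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    return ctx


def write_contexts(ctx: pd.DataFrame, path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment(params))
        ctx.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def promoter_window(tss: int, strand: str) -> tuple[int, int]:
    """2,500 bp upstream through 250 bp downstream of the TSS, in
    transcription orientation, 1-based inclusive (always 2,751 bp long)."""
    if strand == "+":
        return tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    if strand == "-":
        return tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM
    raise ValidationError(f"promoter strand must be '+' or '-', got {strand!r}")


def build_promoters(genes: pd.DataFrame) -> pd.DataFrame:
    """Attach window_start/window_end to a frame with gene_id, chrom, tss, strand."""
    out = genes.copy()
    windows = [promoter_window(t, s) for t, s in zip(out["tss"], out["strand"])]
    out["window_start"] = [w[0] for w in windows]
    out["window_end"] = [w[1] for w in windows]
    return out


def read_tss_bed(path) -> pd.DataFrame:
    """BED6 TSS annotation -> promoter table (1-based TSS, strand-aware window)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: BED6 requires 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}: line {lineno}: promoter without strand")
            # BED is 0-based half-open; the TSS is the first transcribed base.
            tss = int(start) + 1 if strand == "+" else int(end)
            rows.append((name, chrom, tss, strand))
    return build_promoters(pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]))


def map_cpgs_to_promoters(sites: pd.DataFrame, promoters: pd.DataFrame) -> pd.DataFrame:
    """Assign CpGs to every promoter window containing them.

    ``sites`` needs chrom/pos columns; ``promoters`` needs gene_id, chrom,
    window_start, window_end (see :func:`build_promoters`).  Returns a long
    frame (gene_id, chrom, pos, site_index) where ``site_index`` is the
    positional index into ``sites``; a CpG inside two overlapping windows
    appears once per gene.
    """
    if "strand" in promoters.columns and promoters["strand"].isna().any():
        raise ValidationError("promoter without strand")
    out = []
    sites_sorted = sites.reset_index(drop=True)
    order = np.lexsort((sites_sorted["pos"].to_numpy(), sites_sorted["chrom"].to_numpy()))
    chrom_arr = sites_sorted["chrom"].to_numpy()[order]
    pos_arr = sites_sorted["pos"].to_numpy()[order]
    for chrom, grp in promoters.groupby("chrom", sort=False):
        mask = chrom_arr == chrom
        if not mask.any():
            continue
        cpos = pos_arr[mask]
        cidx = order[mask]
        for row in grp.itertuples(index=False):
            lo = np.searchsorted(cpos, row.window_start, side="left")
            hi = np.searchsorted(cpos, row.window_end, side="right")
            for j in range(lo, hi):
                out.append((row.gene_id, chrom, int(cpos[j]), int(cidx[j])))
    return pd.DataFrame(out, columns=["gene_id", "chrom", "pos", "site_index"])
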