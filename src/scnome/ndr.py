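"""Nucleosome-depleted-region (NDR) detection and differential openness.

Single cells of a group are pooled into one GCH count track. The genome is
scanned with 100-bp windows advanced in 20-bp steps; each covered window's
methylated/unmethylated GCH read counts are compared to the whole-genome
background by a one-sided 2x2 chi-square test (1 df, no continuity
correction). The test is one-sided in the sense that a window whose GCH
rate does not exceed the background rate gets p = 1 — accessibility shows
up only as *elevated* GpC methylation. Overlapping or book-ended
significant windows (p <= 1e-20) are merged, and merged candidates longer
than 140 bp with at least five covered GCH sites are reported as NDRs.

Because genome-scale p-values underflow double precision, all p-values are
handled in log10 space throughout.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .config import AnalysisConfig
from .contexts import region_levels
from .intervals import total_bases, overlap_bases

_LN10 = np.log(10.0)


@dataclass
class PooledGchTrack:
    """Per-site GCH counts summed over the cells of one group."""

    sites: dict[str, pd.DataFrame]  # chrom -> DataFrame(pos, c, t), pos-sorted
    group: str = ""
    c_total: int = 0
    t_total: int = 0

    @property
    def background_rate(self) -> float:
        return self.c_total / (self.c_total + self.t_total)


def pool_group(
    cells: Iterable[pd.DataFrame], group: str = "", classes: Iterable[str] = ("GCH",)
) -> PooledGchTrack:
    """Sum per-site methylated/unmethylated counts over a group of cells."""
    cells = list(cells)
    if not cells:
        raise ValueError("cannot pool an empty group")
    cls = set(classes)
    frames = [c[c["context"].isin(cls)] for c in cells]
    cat = pd.concat(frames, ignore_index=True)
    if cat.empty:
        return PooledGchTrack(sites={}, group=group)
    # strand kept implicit: sites on the two strands have distinct positions
    agg = (
        cat.groupby(["chrom", "pos"], sort=True)[["n_meth", "n_unmeth"]]
        .sum()
        .reset_index()
    )
    sites = {
        chrom: sub.rename(columns={"n_meth": "c", "n_unmeth": "t"})[
            ["pos", "c", "t"]
        ].reset_index(drop=True)
        for chrom, sub in agg.groupby("chrom")
    }
    return PooledGchTrack(
        sites=sites,
        group=group,
        c_total=int(agg["n_meth"].sum()),
        t_total=int(agg["n_unmeth"].sum()),
    )


def window_chisq(
    window_c, window_t, background_c: int, background_t: int
) -> np.ndarray:
    """log10 p of the one-sided window-vs-background chi-square test.

    Accepts scalars or arrays for the window counts. The 2x2 table is
    {window C, T; background C, T} with the background being whole-genome
    totals (window included — it is a negligible fraction of the genome,
    and keeping it makes the background identical across windows). Windows
    whose rate does not exceed the background rate return 0.0 (p = 1).
    """
    if background_c + background_t <= 0:
        raise ValueError("background has zero reads")
    wc = np.asarray(window_c, dtype=float)
    wt = np.asarray(window_t, dtype=float)
    if np.any(wc + wt < 1):
        raise ValueError("window has zero reads")
    bc, bt = float(background_c), float(background_t)
    n = wc + wt + bc + bt
    # Pearson statistic for the 2x2 table, 1 df, no continuity correction
    num = n * (wc * bt - wt * bc) ** 2
    den = (wc + wt) * (bc + bt) * (wc + bc) * (wt + bt)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den > 0, num / den, 0.0)
    # 1-df upper tail via the normal tail: P(X > s) = 2*Phi(-sqrt(s));
    # log_ndtr stays accurate where chi2.sf underflows (stat >> 1500)
    log10p = (np.log(2.0) + log_ndtr(-np.sqrt(stat))) / _LN10
    higher = wc / (wc + wt) > bc / (bc + bt)
    out = np.where(higher, log10p, 0.0)
    return out if out.ndim else float(out)


@dataclass
class NdrCallSet:
    """Called NDRs plus the scan context they came from."""

    ndrs: pd.DataFrame  # chrom, start, end, n_gch, pooled_level, log10_p
    group: str = ""


def call_ndrs(
    track: PooledGchTrack,
    cfg: AnalysisConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Scan a pooled GCH track for NDRs.

    Returns an interval DataFrame with columns ``chrom, start, end, n_gch,
    pooled_level, log10_p`` where ``log10_p`` is the most significant
    window p-value inside the region. Windows with zero covered GCH reads
    are skipped (untestable, not closed).
    """
    cfg = cfg or AnalysisConfig()
    if track.c_total + track.t_total == 0:
        return _empty_ndrs()
    log10_thresh = np.log10(cfg.ndr_p)
    rows = []
    for chrom, sub in track.sites.items():
        pos = sub["pos"].to_numpy()
        c = sub["c"].to_numpy(dtype=float)
        t = sub["t"].to_numpy(dtype=float)
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else int(pos[-1]) + 1
        )
        starts = np.arange(0, max(length - cfg.ndr_window, 0) + 1, cfg.ndr_step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + cfg.ndr_window, side="left")
        cum_c = np.concatenate([[0.0], np.cumsum(c)])
        cum_t = np.concatenate([[0.0], np.cumsum(t)])
        wc = cum_c[hi] - cum_c[lo]
        wt = cum_t[hi] - cum_t[lo]
        covered = wc + wt >= 1
        log10p = np.zeros(len(starts))
        log10p[covered] = window_chisq(
            wc[covered], wt[covered], track.c_total, track.t_total
        )
        sig = covered & (log10p <= log10_thresh)
        if not sig.any():
            continue
        # merge overlapping/book-ended significant window spans
        sig_idx = np.flatnonzero(sig)
        span_start = starts[sig_idx]
        span_end = span_start + cfg.ndr_window
        breaks = np.flatnonzero(span_start[1:] > span_end[:-1]) + 1
        for seg in np.split(np.arange(len(sig_idx)), breaks):
            s, e = int(span_start[seg[0]]), int(span_end[seg[-1]])
            if e - s <= cfg.ndr_min_len:  # strict: longer than min_len
                continue
            i0, i1 = np.searchsorted(pos, [s, e], side="left")
            n_gch = int(i1 - i0)
            if n_gch < cfg.ndr_min_gch:
                continue
            cc, tt = c[i0:i1].sum(), t[i0:i1].sum()
            rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "n_gch": n_gch,
                    "pooled_level": cc / (cc + tt),
                    "log10_p": float(log10p[sig_idx[seg]].min()),
                }
            )
    if not rows:
        return _empty_ndrs()
    return (
        pd.DataFrame(rows)
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )


def _empty_ndrs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "n_gch", "pooled_level", "log10_p"]
    )


def classify_ndrs(
    ndrs: pd.DataFrame, tss_table: pd.DataFrame, proximal_radius: int = 2000
) -> pd.DataFrame:
    """Label each NDR proximal or distal by its centre-to-TSS distance.

    Proximal: the region centre lies within ``proximal_radius`` of any TSS
    (inclusive); distal otherwise.
    """
    out = ndrs.copy()
    if out.empty:
        out["ndr_class"] = pd.Series(dtype=str)
        return out
    centers = (out["start"].to_numpy() + out["end"].to_numpy()) / 2.0
    cls = np.full(len(out), "distal", dtype=object)
    for chrom, sub in tss_table.groupby("chrom"):
        sel = out["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        tss = np.sort(sub["tss"].to_numpy(dtype=float))
        c = centers[sel]
        idx = np.clip(np.searchsorted(tss, c), 1, len(tss))
        nearest = np.minimum(
            np.abs(c - tss[idx - 1]), np.abs(c - tss[np.minimum(idx, len(tss) - 1)])
        )
        cls[np.flatnonzero(sel)[nearest <= proximal_radius]] = "proximal"
    out["ndr_class"] = cls
    return out


def differential_open(
    regions: pd.DataFrame,
    cells_a: list[pd.DataFrame],
    cells_b: list[pd.DataFrame],
    cfg: AnalysisConfig | None = None,
    groups: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Call differentially open regions between two cell groups.

    A region is called when (i) it is covered (>= 1 GCH site) in strictly
    more than 40% of cells in *both* groups, (ii) the group-mean GCH levels
    differ by strictly more than 0.2, and (iii) more than half of the
    covered cells are open (level >= 0.5) in exactly one group. Cells at
    level <= 0.3 are closed; levels in between count as covered but
    neither open nor closed.
    """
    cfg = cfg or AnalysisConfig()
    if not cells_a or not cells_b:
        raise ValueError("both groups must be non-empty")
    lev_a = np.vstack([region_levels(c, regions).to_numpy() for c in cells_a])
    lev_b = np.vstack([region_levels(c, regions).to_numpy() for c in cells_b])

    def summarize(lev):
        cov = ~np.isnan(lev)
        n_cov = cov.sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(lev, axis=0)
        n_open = np.nansum(lev >= cfg.do_open_level, axis=0)
        n_closed = np.nansum(lev <= cfg.do_closed_level, axis=0)
        return n_cov, mean, n_open, n_closed

    ncov_a, mean_a, nopen_a, nclosed_a = summarize(lev_a)
    ncov_b, mean_b, nopen_b, nclosed_b = summarize(lev_b)
    frac_a = ncov_a / len(cells_a)
    frac_b = ncov_b / len(cells_b)

    covered_ok = (frac_a > cfg.do_min_cell_frac) & (frac_b > cfg.do_min_cell_frac)
    with np.errstate(invalid="ignore"):
        diff_ok = np.abs(mean_a - mean_b) > cfg.do_min_diff
        maj_a = nopen_a > ncov_a / 2.0
        maj_b = nopen_b > ncov_b / 2.0
    one_sided = maj_a ^ maj_b
    called = covered_ok & diff_ok & one_sided

    out = regions.copy().reset_index(drop=True)
    out["mean_" + groups[0].lower()] = mean_a
    out["mean_" + groups[1].lower()] = mean_b
    out["frac_covered_" + groups[0].lower()] = frac_a
    out["frac_covered_" + groups[1].lower()] = frac_b
    out["n_open_" + groups[0].lower()] = nopen_a.astype(int)
    out["n_open_" + groups[1].lower()] = nopen_b.astype(int)
    direction = np.where(maj_a, f"{groups[0]}-open", f"{groups[1]}-open")
    out["direction"] = direction
    return out[called].reset_index(drop=True)


def open_enrichment(
    ndrs: pd.DataFrame,
    annotation_sets: Mapping[str, pd.DataFrame],
    genome_size: int,
) -> pd.DataFrame:
    """Relative enrichment of NDR bases in each annotation class.

    enrichment = log2( (NDR bases in class / total NDR bases)
                       / (class bases / genome bases) ),
    with all overlaps computed on merged intervals. Classes with zero
    genomic bases get NaN with a warning.
    """
    ndr_total = total_bases(ndrs[["chrom", "start", "end"]]) if len(ndrs) else 0
    rows = []
    for name, ann in annotation_sets.items():
        class_bases = total_bases(ann[["chrom", "start", "end"]]) if len(ann) else 0
        if class_bases == 0:
            warnings.warn(f"annotation class {name!r} covers zero bases")
            rows.append({"annotation": name, "ndr_bases": 0, "class_bases": 0,
                         "enrichment": np.nan})
            continue
        ov = overlap_bases(ndrs[["chrom", "start", "end"]], ann) if ndr_total else 0
        expected = class_bases / genome_size
        observed = ov / ndr_total if ndr_total else np.nan
        with np.errstate(divide="ignore"):
            enr = np.log2(observed / expected) if ndr_total else np.nan
        rows.append(
            {
                "annotation": name,
                "ndr_bases": ov,
                "class_bases": class_bases,
                "enrichment": enr,
            }
        )
    return pd.DataFrame(rows)
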