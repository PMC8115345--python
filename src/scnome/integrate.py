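"""Promoter classes, promoter signals, and three-omics integration.

Promoters are classified by CpG density over a strand-oriented window from
1 kb upstream to 0.5 kb downstream of the TSS, using the field-standard
sliding-subwindow criteria: a promoter is a high-CpG promoter (HCP) when
any 500-bp subwindow has CpG observed/expected ratio > 0.75 *and* GC
fraction > 0.55; a low-CpG promoter (LCP) when no subwindow reaches
observed/expected > 0.48; intermediate (ICP) otherwise.

Promoter methylation is the mean pooled WCG level over [TSS-1000, TSS+500)
and promoter accessibility the mean pooled GCH level over
[TSS-200, TSS+100), both oriented by gene strand (upstream = 5').

The phase-specific-gene screen pools cells per phase, assigns each
proximal NDR to its nearest TSS within 2 kb, and selects (gene, NDR) pairs
whose expression and NDR accessibility correlate across phases with a
Pearson coefficient strictly greater than 0.6.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .contexts import ACC_CONTEXTS, METH_CONTEXTS
from .ndr import PooledGchTrack, pool_group

logger = logging.getLogger(__name__)


def _oriented_window(tss: int, strand: str, up: int, down: int) -> tuple[int, int]:
    """Genomic [start, end) of the window spanning ``up`` bp 5' of the TSS
    to ``down`` bp 3' of it."""
    if strand == "+":
        return tss - up, tss + down
    return tss - down + 1, tss + up + 1


def cpg_obs_exp(seq: str) -> float:
    """CpG observed/expected ratio of a sequence: #CpG * L / (#C * #G)."""
    n_c, n_g = seq.count("C"), seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    return seq.count("CG") * len(seq) / (n_c * n_g)


def classify_promoters(
    genome: Mapping[str, str],
    tss_table: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
) -> pd.Series:
    """HCP / ICP / LCP class per gene (CpG statistics are strand-symmetric,
    so the plus-strand sequence of the oriented window is scanned)."""
    cfg = cfg or AnalysisConfig()
    out = {}
    for _, row in tss_table.iterrows():
        s, e = _oriented_window(
            int(row["tss"]), row["strand"], cfg.prom_meth_up, cfg.prom_meth_down
        )
        chrom_seq = genome[row["chrom"]]
        if s < 0 or e > len(chrom_seq):
            warnings.warn(f"promoter window of {row['gene']} truncated at chromosome end")
            s, e = max(s, 0), min(e, len(chrom_seq))
        seq = chrom_seq[s:e]
        sub = cfg.cpg_subwindow
        if len(seq) <= sub:
            windows = [seq] if seq else []
        else:
            windows = [
                seq[i : i + sub]
                for i in range(0, len(seq) - sub + 1, cfg.cpg_subwindow_step)
            ]
        ratios = [cpg_obs_exp(w) for w in windows]
        gcs = [(w.count("G") + w.count("C")) / len(w) for w in windows if w]
        if any(r > cfg.hcp_obs_exp and gc > cfg.hcp_gc for r, gc in zip(ratios, gcs)):
            out[row["gene"]] = "HCP"
        elif all(r <= cfg.lcp_obs_exp for r in ratios):
            out[row["gene"]] = "LCP"
        else:
            out[row["gene"]] = "ICP"
    return pd.Series(out, name="promoter_class")


def _pooled_site_table(track: PooledGchTrack) -> pd.DataFrame:
    rows = [
        pd.DataFrame({"chrom": chrom, "pos": sub["pos"],
                      "level": sub["c"] / (sub["c"] + sub["t"])})
        for chrom, sub in track.sites.items()
    ]
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "level"])
    return pd.concat(rows, ignore_index=True)


def _window_means(
    sites: pd.DataFrame, windows: pd.DataFrame
) -> np.ndarray:
    out = np.full(len(windows), np.nan)
    for i, (_, w) in enumerate(windows.iterrows()):
        sub = sites[
            (sites["chrom"] == w["chrom"])
            & (sites["pos"] >= w["start"])
            & (sites["pos"] < w["end"])
        ]
        if len(sub):
            out[i] = sub["level"].mean()
    return out


def promoter_signals(
    grouped_cells: Mapping[str, list[pd.DataFrame]],
    tss_table: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-gene, per-group promoter methylation and accessibility.

    Cells of each group are pooled site-wise; each signal is the mean of
    per-site pooled levels inside the oriented window (NaN when no site is
    covered). Returns a tidy frame: gene, group, meth_level, acc_level.
    """
    cfg = cfg or AnalysisConfig()
    meth_w = tss_table.apply(
        lambda r: _oriented_window(int(r["tss"]), r["strand"],
                                   cfg.prom_meth_up, cfg.prom_meth_down),
        axis=1,
    )
    acc_w = tss_table.apply(
        lambda r: _oriented_window(int(r["tss"]), r["strand"],
                                   cfg.prom_acc_up, cfg.prom_acc_down),
        axis=1,
    )
    meth_windows = pd.DataFrame(
        {"chrom": tss_table["chrom"],
         "start": [w[0] for w in meth_w], "end": [w[1] for w in meth_w]}
    )
    acc_windows = pd.DataFrame(
        {"chrom": tss_table["chrom"],
         "start": [w[0] for w in acc_w], "end": [w[1] for w in acc_w]}
    )
    rows = []
    for group, cells in grouped_cells.items():
        meth_sites = _pooled_site_table(pool_group(cells, group, METH_CONTEXTS))
        acc_sites = _pooled_site_table(pool_group(cells, group, ACC_CONTEXTS))
        meth = _window_means(meth_sites, meth_windows)
        acc = _window_means(acc_sites, acc_windows)
        for gene, m, a in zip(tss_table["gene"], meth, acc):
            rows.append({"gene": gene, "group": group,
                         "meth_level": m, "acc_level": a})
    return pd.DataFrame(rows)


def omics_correlation(
    signals: pd.DataFrame,
    expression: pd.Series,
    promoter_classes: pd.Series,
) -> pd.DataFrame:
    """Pairwise Spearman correlation among the three omics per promoter class.

    ``signals`` carries one row per gene (columns ``meth_level``,
    ``acc_level``, index = gene); ``expression`` is per-gene. Within each
    class, rho is computed across genes for each pair of modalities over
    genes with all three values present; classes with fewer than 3 such
    genes get NaN with a warning.
    """
    df = pd.DataFrame(
        {
            "expr": expression,
            "meth": signals["meth_level"],
            "acc": signals["acc_level"],
            "cls": promoter_classes,
        }
    )
    pairs = [("expr", "meth"), ("expr", "acc"), ("meth", "acc")]
    rows = []
    for cls, sub in df.groupby("cls"):
        complete = sub.dropna(subset=["expr", "meth", "acc"])
        row = {"promoter_class": cls, "n_genes": len(complete)}
        for x, y in pairs:
            key = f"rho_{x}_{y}"
            if len(complete) < 3:
                warnings.warn(f"class {cls}: fewer than 3 complete genes")
                row[key] = np.nan
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = stats.spearmanr(complete[x], complete[y]).statistic
            row[key] = float(rho) if np.isfinite(rho) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def assign_ndrs_to_genes(
    ndrs: pd.DataFrame, tss_table: pd.DataFrame, proximal_radius: int = 2000
) -> pd.Series:
    """Nearest TSS (by NDR centre) within the proximal radius, per NDR.

    Ties on distance resolve to the lexicographically smaller gene id.
    Returns a Series of gene ids (None where no TSS is in range).
    """
    genes = np.full(len(ndrs), None, dtype=object)
    centers = (ndrs["start"].to_numpy() + ndrs["end"].to_numpy()) / 2.0
    for i, (chrom, center) in enumerate(zip(ndrs["chrom"], centers)):
        sub = tss_table[tss_table["chrom"] == chrom]
        if sub.empty:
            continue
        dist = np.abs(sub["tss"].to_numpy() - center)
        in_range = dist <= proximal_radius
        if not in_range.any():
            continue
        best = dist[in_range].min()
        tied = sub["gene"].to_numpy()[in_range][dist[in_range] == best]
        genes[i] = min(tied)
    return pd.Series(genes, index=ndrs.index, name="gene")


def phase_specific_genes(
    ndrs: pd.DataFrame,
    acc_by_phase: pd.DataFrame,
    tss_table: pd.DataFrame,
    expression: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Screen for genes whose expression tracks proximal-NDR openness.

    ``acc_by_phase`` has one row per NDR (aligned with ``ndrs``) and one
    column per phase holding the pooled GCH level of that region;
    ``expression`` is genes x phases. For every proximal NDR assigned to a
    gene, the Pearson r between the two phase-vectors is computed over the
    shared phases (at least 3 required); pairs with missing accessibility
    in any phase are skipped with a log entry. ``selected`` is strict:
    r must exceed the threshold.
    """
    cfg = cfg or AnalysisConfig()
    phases = [p for p in expression.columns if p in acc_by_phase.columns]
    if len(phases) < 3:
        raise ValueError("need at least 3 shared phases for the correlation screen")
    genes = assign_ndrs_to_genes(ndrs, tss_table, cfg.proximal_radius)
    rows = []
    for idx, gene in genes.items():
        if gene is None or gene not in expression.index:
            continue
        acc = acc_by_phase.loc[idx, phases].to_numpy(dtype=float)
        if np.isnan(acc).any():
            logger.info("NDR %s skipped: accessibility missing in some phase", idx)
            continue
        expr = expression.loc[gene, phases].to_numpy(dtype=float)
        if np.std(acc) == 0 or np.std(expr) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(expr, acc).statistic)
        rows.append(
            {
                "gene": gene,
                "chrom": ndrs.loc[idx, "chrom"],
                "start": ndrs.loc[idx, "start"],
                "end": ndrs.loc[idx, "end"],
                "r": r,
                "selected": bool(r > cfg.corr_r) if np.isfinite(r) else False,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "r", "selected"]
    )
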