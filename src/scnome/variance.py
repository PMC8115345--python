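"""Cell-to-cell epigenetic heterogeneity in sliding windows.

For each window the per-cell statistic is the mean of per-site levels of
the modality's context class within the window; a cell counts as covered
only when it has strictly more than the minimum number of sites there
(> 3 CpG for methylation, > 5 GCH for accessibility). Heterogeneity is the
unbiased sample variance s^2 of the covered cells' window means, and the
reported summary is the lower endpoint of the two-sided chi-squared
confidence interval for the variance at confidence 0.95:

    lower = (n - 1) * s^2 / chi2_quantile(1 - alpha/2, n - 1)

which penalizes windows where a large s^2 rests on few cells. Groups with
fewer than 10 cells are rejected (too few for a meaningful variance).
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .config import AnalysisConfig
from .contexts import ACC_CONTEXTS, METH_CONTEXTS, site_levels
from .intervals import merge_intervals, points_in_intervals


def chisq_var_lower(s2: np.ndarray | float, n: np.ndarray | int, conf: float = 0.95):
    """Lower bound of the two-sided chi-squared CI of a sample variance."""
    alpha = 1.0 - conf
    n = np.asarray(n)
    q = chi2.ppf(1.0 - alpha / 2.0, n - 1)
    out = (n - 1) * np.asarray(s2) / q
    return out


def _cell_window_stats(
    calls: pd.DataFrame,
    classes: set[str],
    starts_by_chrom: Mapping[str, np.ndarray],
    window: int,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chrom: (site count, mean level) of one cell in each grid window."""
    sub = calls[calls["context"].isin(classes)]
    levels = site_levels(sub).to_numpy() if len(sub) else np.empty(0)
    out = {}
    for chrom, starts in starts_by_chrom.items():
        csel = sub["chrom"].to_numpy() == chrom if len(sub) else np.zeros(0, bool)
        pos = sub["pos"].to_numpy()[csel]
        lev = levels[csel]
        order = np.argsort(pos)
        pos, lev = pos[order], lev[order]
        cum = np.concatenate([[0.0], np.cumsum(lev)])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            mean = (cum[hi] - cum[lo]) / n
        out[chrom] = (n, mean)
    return out


def _variance_track(
    cells: list[pd.DataFrame],
    classes: set[str],
    window: int,
    step: int,
    min_sites: int,
    min_cell_frac: float | None,
    conf: float,
    min_cells: int,
    modality: str,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    if len(cells) < min_cells:
        raise ValueError(
            f"group has {len(cells)} cells, fewer than the required {min_cells}"
        )
    if chrom_lengths is None:
        chrom_lengths = {}
        for c in cells:
            for chrom, sub in c.groupby("chrom"):
                chrom_lengths[chrom] = max(
                    chrom_lengths.get(chrom, 0), int(sub["pos"].max()) + 1
                )
    starts_by_chrom = {
        chrom: np.arange(0, max(length - window, 0) + 1, step)
        for chrom, length in chrom_lengths.items()
    }
    rows = []
    per_cell = [
        _cell_window_stats(c, classes, starts_by_chrom, window) for c in cells
    ]
    for chrom, starts in starts_by_chrom.items():
        counts = np.vstack([pc[chrom][0] for pc in per_cell])
        means = np.vstack([pc[chrom][1] for pc in per_cell])
        covered = counts > min_sites  # strict "more than N sites"
        n_cov = covered.sum(axis=0)
        keep = n_cov >= 2
        if min_cell_frac is not None:
            keep &= n_cov / len(cells) > min_cell_frac
        if not keep.any():
            continue
        m = np.where(covered, means, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s2 = np.nanvar(m, axis=0, ddof=1)
        lower = chisq_var_lower(s2, n_cov, conf)
        for j in np.flatnonzero(keep):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[j]),
                    "end": int(starts[j]) + window,
                    "n_cells": int(n_cov[j]),
                    "s2": float(s2[j]),
                    "var_lower": float(lower[j]),
                    "modality": modality,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_cells", "s2", "var_lower", "modality"],
    )


def methylation_variance(
    cells: list[pd.DataFrame],
    cfg: AnalysisConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    classes: Iterable[str] = METH_CONTEXTS,
) -> pd.DataFrame:
    """Methylation heterogeneity track: 3000-bp windows, 600-bp steps.

    A cell is covered in a window with > 3 CpG sites; windows covered in
    strictly more than 30% of the cells are retained.
    """
    cfg = cfg or AnalysisConfig()
    return _variance_track(
        cells, set(classes), cfg.meth_var_window, cfg.meth_var_step,
        cfg.meth_var_min_cpg, cfg.meth_var_min_cell_frac, cfg.var_conf,
        cfg.var_min_cells, "methylation", chrom_lengths,
    )


def accessibility_variance(
    cells: list[pd.DataFrame],
    cfg: AnalysisConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    classes: Iterable[str] = ACC_CONTEXTS,
) -> pd.DataFrame:
    """Accessibility heterogeneity track: 200-bp windows, 100-bp steps.

    A cell is covered in a window with > 5 GCH sites; a window needs at
    least two covered cells for the variance to exist.
    """
    cfg = cfg or AnalysisConfig()
    return _variance_track(
        cells, set(classes), cfg.acc_var_window, cfg.acc_var_step,
        cfg.acc_var_min_gch, None, cfg.var_conf,
        cfg.var_min_cells, "accessibility", chrom_lengths,
    )


def variance_by_element(
    track: pd.DataFrame, annotation_sets: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Distribution of window variance lower bounds per annotation class.

    A window belongs to a class when its centre falls inside the merged
    class intervals. Classes with no windows are reported with NaN summary.
    """
    centers = ((track["start"] + track["end"]) // 2).to_numpy()
    rows = []
    for name, ann in annotation_sets.items():
        merged = merge_intervals(ann[["chrom", "start", "end"]])
        if merged.empty or track.empty:
            inside = np.zeros(len(track), dtype=bool)
        else:
            inside = points_in_intervals(track["chrom"], centers, merged)
        vals = track.loc[inside, "var_lower"]
        rows.append(
            {
                "annotation": name,
                "n_windows": int(inside.sum()),
                "median": float(vals.median()) if len(vals) else np.nan,
                "q25": float(vals.quantile(0.25)) if len(vals) else np.nan,
                "q75": float(vals.quantile(0.75)) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows)
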