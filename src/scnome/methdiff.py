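"""Tile-level differential methylation and annotation enrichment.

DMRs are 500-bp tiles compared between two cell groups: a tile is
*demethylated* when the first group's mean level is > 0.75, the second's
is < 0.25 and the Benjamini-Hochberg-adjusted p-value is <= 0.05;
*de novo* methylated for the mirrored condition; *stable* otherwise. Only
tiles covered in strictly more than 10% of cells in both groups enter the
comparison, and the FDR adjustment runs over exactly those eligible tiles.

The per-tile p-value comes from a two-sample comparison of per-cell tile
levels — by default a two-sided Wilcoxon rank-sum (exact when the smaller
group has fewer than 8 covered cells), with Welch's t-test selectable.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .contexts import parse_tile_id, region_levels
from .intervals import merge_intervals


def _tile_pvalue(a: np.ndarray, b: np.ndarray, stat: str) -> float:
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    if stat == "ttest":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    method = "exact" if min(len(a), len(b)) < 8 else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def call_dmrs(
    tiles_a: pd.DataFrame,
    tiles_b: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Call demethylated / de novo / stable tiles between two groups.

    ``tiles_a`` / ``tiles_b`` are cells x tiles level matrices (NaN =
    tile missing in that cell), as produced by
    :func:`scnome.contexts.build_tile_matrix`. Returns one row per
    eligible tile: tile, per-group means and covered fractions, p, q, call.
    """
    cfg = cfg or AnalysisConfig()
    common = tiles_a.columns.union(tiles_b.columns)
    a = tiles_a.reindex(columns=common)
    b = tiles_b.reindex(columns=common)
    frac_a = a.notna().mean(axis=0)
    frac_b = b.notna().mean(axis=0)
    eligible = (frac_a > cfg.dmr_min_cell_frac) & (frac_b > cfg.dmr_min_cell_frac)
    tiles = common[eligible]
    if len(tiles) == 0:
        warnings.warn("no tiles eligible for DMR comparison")
        return pd.DataFrame(
            columns=["tile", "mean_former", "mean_latter", "frac_former",
                     "frac_latter", "p", "q", "call"]
        )
    rows = []
    for tile in tiles:
        va = a[tile].dropna().to_numpy()
        vb = b[tile].dropna().to_numpy()
        rows.append(
            {
                "tile": tile,
                "mean_former": va.mean(),
                "mean_latter": vb.mean(),
                "frac_former": frac_a[tile],
                "frac_latter": frac_b[tile],
                "p": _tile_pvalue(va, vb, cfg.dmr_stat),
            }
        )
    out = pd.DataFrame(rows)
    testable = out["p"].notna()
    out["q"] = np.nan
    if testable.any():
        out.loc[testable, "q"] = multipletests(
            out.loc[testable, "p"], method="fdr_bh"
        )[1]
    sig = out["q"] <= cfg.dmr_alpha
    demeth = sig & (out["mean_former"] > cfg.dmr_hi) & (out["mean_latter"] < cfg.dmr_lo)
    denovo = sig & (out["mean_former"] < cfg.dmr_lo) & (out["mean_latter"] > cfg.dmr_hi)
    out["call"] = np.select([demeth, denovo], ["demethylated", "de_novo"], "stable")
    return out


def residual_tiles(
    stage_matrices: Mapping[str, pd.DataFrame],
    level_threshold: float = 0.4,
    min_cell_frac: float = 0.10,
) -> list[str]:
    """Tiles whose group-mean level stays >= the threshold at every stage.

    ``stage_matrices`` maps stage name to a cells x tiles level matrix.
    A tile must be eligible (covered in strictly more than ``min_cell_frac``
    of cells) at *all* stages and meet the level threshold at all of them.
    """
    if len(stage_matrices) < 2:
        raise ValueError("need at least 2 stages")
    keep: pd.Index | None = None
    means: list[pd.Series] = []
    for mat in stage_matrices.values():
        frac = mat.notna().mean(axis=0)
        eligible = frac.index[frac > min_cell_frac]
        keep = eligible if keep is None else keep.intersection(eligible)
        means.append(mat.mean(axis=0, skipna=True))
    assert keep is not None
    retained = [
        t for t in keep if all(m.get(t, np.nan) >= level_threshold for m in means)
    ]
    return sorted(retained, key=parse_tile_id)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and k <= min(K, n)):
        raise ValueError("invalid hypergeometric parameters")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    candidates: Iterable[str],
    background: Iterable[str],
    annotation: pd.DataFrame,
    name: str = "",
) -> pd.Series:
    """Hypergeometric enrichment of candidate tiles in one annotation.

    A tile overlaps the annotation when it shares at least one base with
    the merged annotation intervals. With N background tiles, K of them
    overlapping, and n candidates of which k overlap, the upper-tail
    p-value is P(X >= k) for X ~ Hypergeometric(N, K, n), and the fold
    change is (k/n) / (K/N). Candidates must be a subset of the background.
    """
    cand = list(dict.fromkeys(candidates))
    bg = list(dict.fromkeys(background))
    if not set(cand) <= set(bg):
        raise ValueError("candidate tiles must be a subset of the background")
    merged = merge_intervals(annotation[["chrom", "start", "end"]])

    def overlaps(tile: str) -> bool:
        chrom, s, e = parse_tile_id(tile)
        sub = merged[merged["chrom"] == chrom]
        return bool(((sub["start"] < e) & (sub["end"] > s)).any())

    bg_hits = {t: overlaps(t) for t in bg}
    N, K = len(bg), sum(bg_hits.values())
    n, k = len(cand), sum(bg_hits[t] for t in cand)
    if n == 0 or K == 0:
        warnings.warn(f"enrichment undefined for {name!r} (n={n}, K={K})")
        p = fold = np.nan
    else:
        p = hypergeom_tail(N, K, n, k)
        fold = (k / n) / (K / N)
    return pd.Series(
        {"annotation": name, "N": N, "K": K, "n": n, "k": k, "fold": fold, "p": p}
    )


def icr_profile(
    grouped_cells: Mapping[str, list[pd.DataFrame]],
    icr_bed: pd.DataFrame,
    classes: Iterable[str] = ("WCG", "CpG"),
) -> pd.DataFrame:
    """Mean pooled methylation level per imprinting control region per group.

    For each group the cells are pooled site-wise (counts summed) and each
    ICR's level is the mean of per-site pooled levels inside the interval;
    NaN when the group covers no site there. Rows are ICRs (named from the
    BED name column when present), columns are groups.
    """
    from .ndr import pool_group  # site-wise pooling is modality-agnostic

    names = (
        icr_bed["name"].astype(str)
        if "name" in icr_bed.columns
        else pd.Series(
            [f"{c}:{s}-{e}" for c, s, e in
             zip(icr_bed["chrom"], icr_bed["start"], icr_bed["end"])]
        )
    )
    out = pd.DataFrame(index=names.to_numpy())
    for group, cells in grouped_cells.items():
        track = pool_group(cells, group=group, classes=classes)
        pooled_rows = []
        for chrom, sub in track.sites.items():
            pooled_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": sub["pos"],
                        "context": "WCG",
                        "n_meth": sub["c"],
                        "n_unmeth": sub["t"],
                    }
                )
            )
        pooled = (
            pd.concat(pooled_rows, ignore_index=True)
            if pooled_rows
            else pd.DataFrame(columns=["chrom", "pos", "context", "n_meth", "n_unmeth"])
        )
        out[group] = region_levels(
            pooled, icr_bed.reset_index(drop=True), classes=("WCG",)
        ).to_numpy()
    return out
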