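"""Small interval utilities on 0-based half-open genomic intervals.

Intervals are pandas DataFrames with columns ``chrom``, ``start``, ``end``
(plus optional extras). Only three primitives are needed by the pipeline:
merging, total covered bases, and overlap bases between two merged sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLS = ["chrom", "start", "end"]


def validate_intervals(df: pd.DataFrame) -> pd.DataFrame:
    for col in INTERVAL_COLS:
        if col not in df.columns:
            raise ValueError(f"interval table missing column {col!r}")
    if len(df) and not (df["start"] < df["end"]).all():
        bad = df[~(df["start"] < df["end"])].iloc[0]
        raise ValueError(
            f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']} "
            "(start must be < end)"
        )
    return df


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: overlapping or book-ended intervals are merged."""
    validate_intervals(df)
    if df.empty:
        return df[INTERVAL_COLS].copy()
    out = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # book-ended counts as contiguous
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLS)


def total_bases(df: pd.DataFrame) -> int:
    """Total bases covered by the union of the intervals."""
    m = merge_intervals(df)
    return int((m["end"] - m["start"]).sum())


def overlap_bases(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Bases in the intersection of the unions of two interval sets."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    total = 0
    for chrom, sa in ma.groupby("chrom"):
        sb = mb[mb["chrom"] == chrom]
        if sb.empty:
            continue
        s1 = sa["start"].to_numpy()[:, None]
        e1 = sa["end"].to_numpy()[:, None]
        s2 = sb["start"].to_numpy()[None, :]
        e2 = sb["end"].to_numpy()[None, :]
        ov = np.minimum(e1, e2) - np.maximum(s1, s2)
        total += int(np.clip(ov, 0, None).sum())
    return total


def points_in_intervals(
    chroms: np.ndarray | pd.Series,
    pos: np.ndarray | pd.Series,
    intervals: pd.DataFrame,
) -> np.ndarray:
    """Boolean mask: which (chrom, pos) points fall inside the merged set."""
    chroms = np.asarray(chroms)
    pos = np.asarray(pos)
    mask = np.zeros(len(pos), dtype=bool)
    merged = merge_intervals(intervals)
    for chrom, sub in merged.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        p = pos[sel]
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
        mask[np.flatnonzero(sel)] = ok
    return mask


def reciprocal_overlap(
    a: tuple[int, int], b: tuple[int, int], frac: float = 0.5
) -> bool:
    """True when two same-chromosome intervals overlap by >= frac of each."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return False
    return ov >= frac * (a[1] - a[0]) and ov >= frac * (b[1] - b[0])
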