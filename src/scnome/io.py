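"""Readers and writers for the pipeline's file formats.

Formats
-------
Site-call TSV (per cell)
    Columns ``chrom  pos  strand  context  n_meth  n_unmeth`` with 1-based
    positions (bismark-coverage dialect) and context in
    {WCG, GCH, GCG, CpG, other}. In memory positions are 0-based.
BED
    Standard BED6, 0-based half-open.
Cell manifest TSV
    Columns ``cell_id  assay  sex  week  phase  path``; assay is ``scbs``
    or ``cool``; cells are grouped downstream by (sex, week, phase).
Tile-matrix TSV
    Tiles as rows named ``chrom:start-end``, cells as columns, empty cell
    for missing values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import validate_intervals

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
KNOWN_CONTEXTS = frozenset({"WCG", "GCH", "GCG", "CpG", "other"})


class ParseError(ValueError):
    pass


def read_site_calls(
    path: str | Path, expected_contexts: frozenset[str] | set[str] = KNOWN_CONTEXTS
) -> pd.DataFrame:
    """Read a per-cell site-call TSV into a 0-based, sorted call table.

    Rows with zero total reads are dropped. Raises :class:`ParseError`
    naming the offending line for malformed rows, and a validation error
    for contexts outside ``expected_contexts``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CALL_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
            },
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return empty_call_table()
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    for col in ("pos", "n_meth", "n_unmeth"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            lineno = int(np.flatnonzero(bad | df[col].isna())[0]) + 1
            raise ParseError(f"{path}: malformed {col!r} at line {lineno}")
        df[col] = coerced.astype(np.int64)
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        lineno = int(np.flatnonzero((df["n_meth"] < 0) | (df["n_unmeth"] < 0))[0]) + 1
        raise ParseError(f"{path}: negative count at line {lineno}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        lineno = int(np.flatnonzero(bad_strand)[0]) + 1
        raise ParseError(f"{path}: invalid strand at line {lineno}")
    unexpected = set(df["context"].unique()) - set(expected_contexts)
    if unexpected:
        raise ValueError(
            f"{path}: unexpected context(s) {sorted(unexpected)}; "
            f"expected one of {sorted(expected_contexts)}"
        )

    df["pos"] = df["pos"] - 1  # 1-based TSV -> 0-based in memory
    df = df[df["n_meth"] + df["n_unmeth"] > 0]
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_site_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Inverse of :func:`read_site_calls` (positions written 1-based)."""
    out = calls[CALL_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def empty_call_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "n_meth": pd.Series(dtype=np.int64),
            "n_unmeth": pd.Series(dtype=np.int64),
        }
    )


def write_bed(intervals: pd.DataFrame, path: str | Path, score_field: str | None = None) -> None:
    """Write BED6. ``name``/``strand`` default to ``.``; score from
    ``score_field`` (0 when absent). Extra columns after the six are kept."""
    validate_intervals(intervals)
    df = intervals.copy()
    if "name" not in df.columns:
        df["name"] = "."
    df["score"] = df[score_field] if score_field else 0
    if "strand" not in df.columns:
        df["strand"] = "."
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    extra = [c for c in intervals.columns if c not in cols and c != score_field]
    df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/4/5/6 into an interval DataFrame (0-based half-open)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]] + [
        f"extra_{i}" for i in range(max(0, df.shape[1] - 6))
    ]
    df["chrom"] = df["chrom"].astype(str)
    return validate_intervals(df)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "phase": str, "sex": str})
    required = ["cell_id", "assay", "sex", "week", "phase", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing column(s) {missing}")
    bad = ~df["assay"].isin(["scbs", "cool"])
    if bad.any():
        raise ParseError(f"{path}: assay must be 'scbs' or 'cool'")
    return df


def write_tile_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a cells x tiles matrix as tiles-as-rows TSV, '' for missing."""
    out = matrix.T
    out.index.name = "tile"
    out.to_csv(path, sep="\t", na_rep="")


def read_tile_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV: columns gene, chrom, tss (0-based), strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    required = ["gene", "chrom", "tss", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: TSS table missing column(s) {missing}")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x groups expression TSV with a leading gene-id column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: expression values must be nonnegative")
    return df
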