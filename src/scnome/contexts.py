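"""Cytosine context classification, methylation estimation, tiles, QC.

In NOMe-seq-style data two cytosine contexts carry unambiguous signal:

* **WCG** (ACG/TCG) — CpG sites not preceded by G, reporting endogenous
  DNA methylation.
* **GCH** (GCA/GCC/GCT) — GpC sites not followed by G, reporting the GpC
  methyltransferase footprint, i.e. chromatin accessibility.

**GCG** sites are both GpC and CpG and therefore ambiguous (endogenous vs
enzymatic methylation); they are classified but excluded from both
analyses. **CCG** sites are CpG but not WCG and are labelled ``CpG``.
Everything else, including cytosines whose trinucleotide contains N or
falls off a chromosome end, is ``other``.

A methylation *level* is always the proportion of methylated reads at a
site, and region/cell levels are unweighted means of per-site levels over
covered sites of the requested context class.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

# context classes that are CpG dinucleotides on their own strand
CPG_CLASSES = frozenset({"WCG", "GCG", "CpG"})
METH_CONTEXTS = frozenset({"WCG", "CpG"})   # endogenous-methylation classes
ACC_CONTEXTS = frozenset({"GCH"})

_CODE = np.full(256, 4, dtype=np.int8)  # everything unknown -> 4 (N-like)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i
_A, _C, _G, _T, _N = 0, 1, 2, 3, 4
_COMP = np.array([_T, _G, _C, _A, _N], dtype=np.int8)


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA into a chrom -> uppercase-sequence dict."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def _classify_strand(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Class codes for cytosines given their 5' and 3' neighbours.

    Returns int codes: 0=WCG 1=GCH 2=GCG 3=CpG 4=other.
    """
    cls = np.full(left.shape, 4, dtype=np.int8)
    valid = (left != _N) & (right != _N)
    cpg = valid & (right == _G)
    cls[cpg & ((left == _A) | (left == _T))] = 0          # WCG
    cls[cpg & (left == _G)] = 2                           # GCG
    cls[cpg & (left == _C)] = 3                           # CCG -> CpG class
    cls[valid & ~cpg & (left == _G)] = 1                  # GCH
    return cls


_CLASS_NAMES = np.array(["WCG", "GCH", "GCG", "CpG", "other"])


def classify_contexts(genome: Mapping[str, str]) -> dict[str, pd.DataFrame]:
    """Assign every genomic cytosine (both strands) to exactly one class.

    The plus-strand class of a C at position i is decided by the
    trinucleotide (i-1, i, i+1); a minus-strand cytosine (genomic G) by the
    reverse-complement trinucleotide. Returns, per chromosome, a DataFrame
    with columns ``pos`` (0-based), ``strand``, ``cls`` sorted by position.
    """
    out: dict[str, pd.DataFrame] = {}
    for chrom, seq in genome.items():
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if bytes(seq, "ascii").translate(None, b"ACGTNacgtn"):
            raise ValueError(f"{chrom}: non-IUPAC character in sequence")
        n = len(codes)
        left = np.full(n, _N, dtype=np.int8)
        right = np.full(n, _N, dtype=np.int8)
        left[1:] = codes[:-1]
        right[:-1] = codes[1:]

        plus = np.flatnonzero(codes == _C)
        plus_cls = _classify_strand(left[plus], right[plus])
        minus = np.flatnonzero(codes == _G)
        # minus-strand trinucleotide: revcomp of (i-1, i, i+1)
        minus_cls = _classify_strand(_COMP[right[minus]], _COMP[left[minus]])

        df = pd.DataFrame(
            {
                "pos": np.concatenate([plus, minus]),
                "strand": np.concatenate(
                    [np.full(len(plus), "+"), np.full(len(minus), "-")]
                ),
                "cls": _CLASS_NAMES[np.concatenate([plus_cls, minus_cls])],
            }
        )
        out[chrom] = df.sort_values(["pos", "strand"], kind="mergesort").reset_index(
            drop=True
        )
    return out


def classify_trinucleotide(tri: str) -> str:
    """Class of the centre cytosine of one plus-strand trinucleotide."""
    if len(tri) != 3 or tri[1].upper() != "C":
        raise ValueError("expected a trinucleotide with centre C")
    left, right = (_CODE[ord(tri[0].upper())], _CODE[ord(tri[2].upper())])
    return str(_CLASS_NAMES[_classify_strand(np.array([left]), np.array([right]))[0]])


# ---------------------------------------------------------------------------
# levels


def site_levels(calls: pd.DataFrame) -> pd.Series:
    """Per-site methylation level: n_meth / (n_meth + n_unmeth)."""
    if (calls["n_meth"] < 0).any() or (calls["n_unmeth"] < 0).any():
        raise ValueError("negative read counts")
    depth = calls["n_meth"] + calls["n_unmeth"]
    if (depth < 1).any():
        raise ValueError("site with zero reads; drop uncovered rows first")
    return calls["n_meth"] / depth


def global_level(calls: pd.DataFrame, classes: Iterable[str] = ("WCG",)) -> float:
    """Unweighted mean of per-site levels over covered sites of the class."""
    sub = calls[calls["context"].isin(set(classes))]
    if sub.empty:
        import warnings

        warnings.warn("no covered sites of requested class; level undefined")
        return float("nan")
    return float(site_levels(sub).mean())


def tile_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def parse_tile_id(tid: str) -> tuple[str, int, int]:
    chrom, span = tid.rsplit(":", 1)
    start, end = span.split("-")
    return chrom, int(start), int(end)


def aggregate_tiles(
    calls: pd.DataFrame,
    classes: Iterable[str] = ("WCG",),
    tile_size: int = 500,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Mean per-site level per fixed tile (windows [k*size, (k+1)*size)).

    Tiles with fewer than ``min_sites`` covered sites of the class are
    omitted (missing for this cell). Returns columns chrom, start, end,
    n_sites, mean_level.
    """
    sub = calls[calls["context"].isin(set(classes))]
    if sub.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_sites", "mean_level"])
    levels = site_levels(sub)
    grp = pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy(),
            "tile": sub["pos"].to_numpy() // tile_size,
            "level": levels.to_numpy(),
        }
    ).groupby(["chrom", "tile"], sort=True)["level"]
    agg = grp.agg(["count", "mean"]).reset_index()
    agg = agg[agg["count"] >= min_sites]
    return pd.DataFrame(
        {
            "chrom": agg["chrom"],
            "start": agg["tile"] * tile_size,
            "end": (agg["tile"] + 1) * tile_size,
            "n_sites": agg["count"].astype(int),
            "mean_level": agg["mean"],
        }
    ).reset_index(drop=True)


def region_levels(
    calls: pd.DataFrame,
    regions: pd.DataFrame,
    classes: Iterable[str] = ("GCH",),
    min_sites: int = 1,
) -> pd.Series:
    """Mean per-site level of one cell inside each region (NaN if under-covered).

    ``regions`` is an interval DataFrame; the result is indexed like it.
    """
    sub = calls[calls["context"].isin(set(classes))]
    out = np.full(len(regions), np.nan)
    if sub.empty:
        return pd.Series(out, index=regions.index)
    levels = site_levels(sub).to_numpy()
    for chrom, rsub in regions.groupby("chrom"):
        csel = sub["chrom"].to_numpy() == chrom
        if not csel.any():
            continue
        pos = sub["pos"].to_numpy()[csel]
        lev = levels[csel]
        order = np.argsort(pos)
        pos, lev = pos[order], lev[order]
        cum = np.concatenate([[0.0], np.cumsum(lev)])
        lo = np.searchsorted(pos, rsub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, rsub["end"].to_numpy(), side="left")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            means = (cum[hi] - cum[lo]) / n
        means[n < min_sites] = np.nan
        out[regions.index.get_indexer(rsub.index)] = means
    return pd.Series(out, index=regions.index)


def build_tile_matrix(
    cell_tiles: Mapping[str, pd.DataFrame],
    min_cell_frac: float = 0.70,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-cell tile levels into a cells x tiles matrix.

    ``cell_tiles`` maps cell id to the output of :func:`aggregate_tiles`.
    Returns ``(matrix, filtered)`` where *matrix* covers every tile seen in
    any cell (NaN = missing) and *filtered* keeps tiles whose covered-cell
    fraction is strictly greater than ``min_cell_frac`` — the clustering
    export ("covered in more than 70% of cells").
    """
    if len(cell_tiles) < 2:
        raise ValueError("need at least 2 cells for a tile matrix")
    series = {}
    for cell, tiles in cell_tiles.items():
        idx = [tile_id(c, s, e) for c, s, e in zip(tiles["chrom"], tiles["start"], tiles["end"])]
        series[cell] = pd.Series(tiles["mean_level"].to_numpy(), index=idx)
    matrix = pd.DataFrame(series).T  # cells x tiles
    matrix = matrix[sorted(matrix.columns, key=parse_tile_id)]
    covered_frac = matrix.notna().mean(axis=0)
    filtered = matrix.loc[:, covered_frac > min_cell_frac]
    if filtered.shape[1] == 0:
        import warnings

        warnings.warn("no tiles pass the covered-cell-fraction filter")
    return matrix, filtered


# ---------------------------------------------------------------------------
# library QC


def qc_filter(stats: pd.DataFrame, assay: str, cfg) -> pd.DataFrame:
    """Apply library-level QC gates; returns pass flag plus reasons.

    ``stats`` must provide, per cell: ``map_rate``, ``global_meth``,
    ``cell_class`` (``fgc`` or ``soma``) and, for scBS libraries,
    ``conversion``, ``non_cpg_meth``, ``n_cpg``; for COOL libraries,
    ``n_wcg``, ``n_gch``. FGC cells additionally require a global
    methylation level <= the FGC ceiling; somatic cells are exempt.
    """
    if assay == "scbs":
        t = cfg.qc_scbs
        checks = [
            # (reason, stat column, predicate on the stat value)
            ("map_rate", "map_rate", lambda v: v >= t.map_rate),
            ("conversion", "conversion", lambda v: v >= t.conversion),
            ("non_cpg_meth", "non_cpg_meth", lambda v: v <= t.non_cpg_meth),
            ("min_cpg_sites", "n_cpg", lambda v: v > t.min_cpg_sites),
        ]
        fgc_ceiling = t.fgc_max_meth
    elif assay == "cool":
        t = cfg.qc_cool
        checks = [
            ("map_rate", "map_rate", lambda v: v >= t.map_rate),
            ("min_wcg", "n_wcg", lambda v: v > t.min_wcg),
            ("min_gch", "n_gch", lambda v: v > t.min_gch),
        ]
        fgc_ceiling = t.fgc_max_meth
    else:
        raise ValueError(f"unknown assay {assay!r}")

    rows = []
    for _, s in stats.iterrows():
        reasons = []
        for name, key, pred in checks:
            val = s.get(key, float("nan"))
            if pd.isna(val):
                reasons.append("missing")
            elif not pred(val):
                reasons.append(name)
        if str(s.get("cell_class", "")).lower() == "fgc":
            gm = s.get("global_meth", float("nan"))
            if pd.isna(gm):
                reasons.append("missing")
            elif not gm <= fgc_ceiling:
                reasons.append("fgc_max_meth")
        rows.append({"pass": not reasons, "reasons": ";".join(reasons)})
    return pd.DataFrame(rows, index=stats.index)
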