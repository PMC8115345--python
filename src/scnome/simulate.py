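"""Synthetic single-cell bisulfite / NOMe-seq cohort generator.

Generates a small random genome with non-overlapping promoters, plants
fully accessible nucleosome-depleted regions (NDRs) at a phase-specific
subset of promoters, and emits per-cell site-call tables with the
statistical structure of real single-cell data:

* sparse per-cell coverage — each site is seen with probability
  ``site_coverage_prob`` (default 0.12, matching the ~10-15% of CpG sites
  a real single cell covers) at depth ``1 + Poisson(mean_read_depth - 1)``
  so the default regime is 1x;
* phase-dependent global CpG methylation — per (phase, tile) a level is
  drawn from a Beta centred at the phase mean (hypermethylated ~0.67 for
  somatic cells, 0.05-0.15 for fetal germ cells), and per-cell site calls
  are binomial at that level;
* a two-state accessibility model — GCH sites inside a planted NDR of the
  cell's phase are methylated by the GpC enzyme at rate
  ``enzyme_efficiency`` (< 1, imperfect labelling), all other GCH sites at
  ``background_gch`` (non-conversion plus nonspecific labelling, folded
  into one rate);
* phase-matched expression — genes whose promoter is open in a phase are
  high (10x baseline) in exactly that phase.

Everything planted is recorded in :class:`SimTruth`, so recall/precision
of the downstream callers is well defined.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .contexts import classify_contexts

OPEN_EXPR = 10.0   # expression of a gene in the phase that opens its promoter
BASE_EXPR = 1.0


@dataclass
class PhaseSpec:
    """One cohort phase (cell population) and its generative parameters."""

    name: str
    n_cells: int = 15
    mean_cpg_meth: float = 0.10
    open_genes: list[str] = field(default_factory=list)
    cell_class: str = "fgc"   # 'fgc' or 'soma'
    sex: str = "F"
    week: int = 10


@dataclass
class SimConfig:
    n_chroms: int = 1
    chrom_len: int = 200_000
    gc_fraction: float = 0.45
    n_genes: int = 20
    promoter_ndr_width: int = 300
    phases: list[PhaseSpec] = field(default_factory=lambda: _default_phases())
    tile_meth_dispersion: float = 0.05   # Beta dispersion 1/(a+b); 0 = no spread
    tile_size: int = 500
    enzyme_efficiency: float = 0.85
    background_gch: float = 0.02
    site_coverage_prob: float = 0.12
    mean_read_depth: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "tile_meth_dispersion", "enzyme_efficiency",
                     "background_gch", "site_coverage_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.enzyme_efficiency <= self.background_gch:
            import warnings

            warnings.warn(
                "enzyme_efficiency <= background_gch: planted accessibility "
                "is unrecoverable from the calls"
            )
        if sum(p.n_cells for p in self.phases) <= 0:
            raise ValueError("cohort has no cells")
        if self.mean_read_depth < 1:
            raise ValueError("mean_read_depth must be >= 1")


def _default_phases() -> list[PhaseSpec]:
    """Three-population default: two hypomethylated germ-cell phases with
    distinct open promoters, one hypermethylated somatic population."""
    return [
        PhaseSpec("mitotic", 15, 0.15, [f"gene{i:03d}" for i in range(0, 5)],
                  "fgc", "F", 10),
        PhaseSpec("meiotic", 15, 0.08, [f"gene{i:03d}" for i in range(5, 10)],
                  "fgc", "F", 17),
        PhaseSpec("soma", 15, 0.67, [f"gene{i:03d}" for i in range(10, 15)],
                  "soma", "F", 10),
    ]


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    ndr_truth: dict[str, pd.DataFrame]          # phase -> planted intervals
    tile_truth_meth: dict[str, dict[str, list]]  # phase -> chrom -> tile levels
    cell_params: pd.DataFrame                   # per-cell realized global level
    expression: pd.DataFrame                    # genes x phases
    tile_size: int = 500

    def to_json(self, path: str | Path) -> None:
        obj = {
            "tile_size": self.tile_size,
            "ndr_truth": {
                ph: df.to_dict(orient="list") for ph, df in self.ndr_truth.items()
            },
            "tile_truth_meth": self.tile_truth_meth,
            "cell_params": self.cell_params.to_dict(orient="list"),
            "expression": {
                "genes": list(self.expression.index),
                "phases": list(self.expression.columns),
                "values": self.expression.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        obj = json.loads(Path(path).read_text())
        expr = pd.DataFrame(
            obj["expression"]["values"],
            index=obj["expression"]["genes"],
            columns=obj["expression"]["phases"],
        )
        return cls(
            ndr_truth={ph: pd.DataFrame(d) for ph, d in obj["ndr_truth"].items()},
            tile_truth_meth=obj["tile_truth_meth"],
            cell_params=pd.DataFrame(obj["cell_params"]),
            expression=expr,
            tile_size=obj["tile_size"],
        )


# ---------------------------------------------------------------------------


def simulate_genome(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], pd.DataFrame, dict[str, pd.DataFrame]]:
    """Random genome, non-overlapping promoters, and annotation sets.

    Promoter +/-2 kb windows never overlap; infeasible spacing raises.
    Annotation sets: two repeat-like interval families and an ICR-like set
    placed clear of promoters.
    """
    per_chrom = np.array_split(np.arange(cfg.n_genes), cfg.n_chroms)
    margin = 2500
    for genes in per_chrom:
        need = (len(genes) + 1) * 2 * margin
        if need > cfg.chrom_len:
            raise ValueError(
                f"{len(genes)} genes do not fit in {cfg.chrom_len} bp with "
                "non-overlapping +/-2 kb promoter windows"
            )
    p = np.array(
        [(1 - cfg.gc_fraction) / 2, cfg.gc_fraction / 2,
         cfg.gc_fraction / 2, (1 - cfg.gc_fraction) / 2]
    )
    genome: dict[str, str] = {}
    tss_rows = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                           size=cfg.chrom_len, p=p)
        genome[chrom] = bases.tobytes().decode("ascii")
        genes = per_chrom[ci]
        spacing = cfg.chrom_len // (len(genes) + 1)
        for j, g in enumerate(genes):
            tss_rows.append(
                {
                    "gene": f"gene{g:03d}",
                    "chrom": chrom,
                    "tss": (j + 1) * spacing,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
    tss = pd.DataFrame(tss_rows)

    def random_intervals(n: int, width: int) -> pd.DataFrame:
        rows = []
        for _ in range(n):
            chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
            s = int(rng.integers(0, cfg.chrom_len - width))
            rows.append({"chrom": chrom, "start": s, "end": s + width})
        return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)

    annotations = {
        "LINE_like": random_intervals(max(4, cfg.n_genes // 2), 1500),
        "SINE_like": random_intervals(max(8, cfg.n_genes), 300),
    }
    # ICR-like intervals midway between consecutive promoters
    icr_rows = []
    for chrom, sub in tss.groupby("chrom"):
        pos = np.sort(sub["tss"].to_numpy())
        for a, b in zip(pos[:-1], pos[1:]):
            mid = int((a + b) // 2)
            icr_rows.append({"chrom": chrom, "start": mid - 250, "end": mid + 250})
    annotations["ICR_like"] = pd.DataFrame(icr_rows)
    return genome, tss, annotations


def _draw_tile_levels(
    mean: float, n_tiles: int, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if dispersion <= 0 or mean in (0.0, 1.0):
        return np.full(n_tiles, mean)
    conc = 1.0 / dispersion
    return rng.beta(mean * conc, (1.0 - mean) * conc, size=n_tiles)


def _plant_ndrs(cfg: SimConfig, tss: pd.DataFrame) -> dict[str, pd.DataFrame]:
    out = {}
    half = cfg.promoter_ndr_width // 2
    for phase in cfg.phases:
        sub = tss[tss["gene"].isin(phase.open_genes)]
        out[phase.name] = pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "start": sub["tss"].to_numpy() - half,
                "end": sub["tss"].to_numpy() + (cfg.promoter_ndr_width - half),
                "name": sub["gene"].to_numpy(),
            }
        ).reset_index(drop=True)
    return out


def simulate_cell(
    ctx: dict[str, pd.DataFrame],
    tile_levels: dict[str, np.ndarray],
    ndrs: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator,
    assay: str = "cool",
) -> pd.DataFrame:
    """One cell's site-call table.

    ``cool`` cells report WCG (endogenous), GCH (accessibility) and GCG
    (ambiguous, emitted for exclusion testing); ``scbs`` cells report all
    CpG-class sites (WCG/CpG/GCG) as endogenous methylation.
    """
    meth_classes = {"WCG", "GCG"} if assay == "cool" else {"WCG", "CpG", "GCG"}
    frames = []
    for chrom, sites in ctx.items():
        levels = tile_levels[chrom]
        for classes, enzymatic in ((meth_classes, False), ({"GCH"}, True)):
            if enzymatic and assay != "cool":
                continue
            sub = sites[sites["cls"].isin(classes)]
            covered = rng.random(len(sub)) < cfg.site_coverage_prob
            sub = sub[covered]
            if sub.empty:
                continue
            depth = 1 + rng.poisson(cfg.mean_read_depth - 1.0, size=len(sub))
            pos = sub["pos"].to_numpy()
            if enzymatic:
                rate = np.full(len(sub), cfg.background_gch)
                nsub = ndrs[ndrs["chrom"] == chrom]
                for _, nd in nsub.iterrows():
                    rate[(pos >= nd["start"]) & (pos < nd["end"])] = (
                        cfg.enzyme_efficiency
                    )
            else:
                rate = levels[pos // cfg.tile_size]
            n_meth = rng.binomial(depth, rate)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": sub["strand"].to_numpy(),
                        "context": sub["cls"].to_numpy(),
                        "n_meth": n_meth,
                        "n_unmeth": depth - n_meth,
                    }
                )
            )
    if not frames:
        return sio.empty_call_table()
    return (
        pd.concat(frames, ignore_index=True)
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )


def _expression(cfg: SimConfig, tss: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    genes = list(tss["gene"])
    expr = pd.DataFrame(BASE_EXPR, index=genes,
                        columns=[p.name for p in cfg.phases])
    for phase in cfg.phases:
        for g in phase.open_genes:
            if g in expr.index:
                expr.loc[g, phase.name] = OPEN_EXPR
    noise = rng.lognormal(mean=0.0, sigma=0.05, size=expr.shape)
    return expr * noise


def simulate_cohort(cfg: SimConfig, outdir: str | Path) -> SimTruth:
    """Write a full synthetic cohort: genome, annotations, per-cell call
    tables, manifest, cell stats, expression, and the truth JSON."""
    outdir = Path(outdir)
    (outdir / "cells").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genome, tss, annotations = simulate_genome(cfg, rng)
    ctx = classify_contexts(genome)
    ndr_truth = _plant_ndrs(cfg, tss)
    n_tiles = {c: (len(s) + cfg.tile_size - 1) // cfg.tile_size
               for c, s in genome.items()}

    tile_truth: dict[str, dict[str, np.ndarray]] = {}
    for phase in cfg.phases:
        tile_truth[phase.name] = {
            chrom: _draw_tile_levels(
                phase.mean_cpg_meth, n, cfg.tile_meth_dispersion, rng
            )
            for chrom, n in n_tiles.items()
        }

    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    tss.to_csv(outdir / "tss.tsv", sep="\t", index=False)
    for name, ann in annotations.items():
        sio.write_bed(ann, outdir / f"{name}.bed")
    for phase_name, df in ndr_truth.items():
        sio.write_bed(df, outdir / f"truth_ndr_{phase_name}.bed")

    manifest_rows, stats_rows, cell_rows = [], [], []
    cell_idx = 0
    for phase in cfg.phases:
        for _ in range(phase.n_cells):
            cell_id = f"{phase.name}_c{cell_idx:03d}"
            cell_rng = np.random.default_rng([cfg.seed, cell_idx])
            calls = simulate_cell(
                ctx, tile_truth[phase.name], ndr_truth[phase.name],
                cfg, cell_rng, assay="cool",
            )
            path = outdir / "cells" / f"{cell_id}.tsv"
            sio.write_site_calls(calls, path)
            wcg = calls[calls["context"] == "WCG"]
            gch = calls[calls["context"] == "GCH"]
            global_meth = (
                float((wcg["n_meth"] / (wcg["n_meth"] + wcg["n_unmeth"])).mean())
                if len(wcg)
                else float("nan")
            )
            manifest_rows.append(
                {
                    "cell_id": cell_id, "assay": "cool", "sex": phase.sex,
                    "week": phase.week, "phase": phase.name,
                    "path": str(path.relative_to(outdir)),
                }
            )
            stats_rows.append(
                {
                    "cell_id": cell_id,
                    "map_rate": 0.30,
                    "conversion": 0.995,
                    "non_cpg_meth": cfg.background_gch,
                    "n_cpg": len(wcg),
                    "n_wcg": len(wcg),
                    "n_gch": len(gch),
                    "global_meth": global_meth,
                    "cell_class": phase.cell_class,
                }
            )
            cell_rows.append(
                {"cell_id": cell_id, "phase": phase.name,
                 "true_mean": phase.mean_cpg_meth, "realized_global": global_meth}
            )
            cell_idx += 1

    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(stats_rows).to_csv(outdir / "cell_stats.tsv", sep="\t", index=False)
    expression = _expression(cfg, tss, rng)
    expression.rename_axis("gene").to_csv(outdir / "expression.tsv", sep="\t")

    truth = SimTruth(
        ndr_truth=ndr_truth,
        tile_truth_meth={
            ph: {c: v.tolist() for c, v in d.items()} for ph, d in tile_truth.items()
        },
        cell_params=pd.DataFrame(cell_rows),
        expression=expression,
        tile_size=cfg.tile_size,
    )
    truth.to_json(outdir / "truth.json")
    return truth
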