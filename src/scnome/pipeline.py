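"""End-to-end analysis pipeline over a cell manifest.

Stage order mirrors the analysis flow: library QC -> methylation tile
matrix -> per-group NDR calling -> differential methylation and
differential openness between consecutive groups -> enrichment ->
promoter/expression integration -> cell-to-cell variance. Cells are
grouped by (sex, week, phase); the phase string links a group to its
column in the expression table. Every run writes the resolved
configuration and a log of the thresholds used.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io as sio
from .config import AnalysisConfig
from .contexts import (
    METH_CONTEXTS,
    aggregate_tiles,
    build_tile_matrix,
    global_level,
    load_genome,
    qc_filter,
)
from .integrate import (
    classify_promoters,
    omics_correlation,
    phase_specific_genes,
    promoter_signals,
)
from .methdiff import call_dmrs, hypergeom_enrichment, icr_profile, residual_tiles
from .ndr import (
    call_ndrs,
    classify_ndrs,
    differential_open,
    open_enrichment,
    pool_group,
)
from .variance import accessibility_variance, methylation_variance, variance_by_element

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def _group_key(row: pd.Series) -> str:
    return f"{row['sex']}_wk{row['week']}_{row['phase']}"


def run_pipeline(
    cfg: AnalysisConfig,
    manifest_path: str | Path,
    outdir: str | Path,
    data_dir: str | Path | None = None,
) -> Path:
    """Run every stage; returns the result directory.

    ``data_dir`` (default: the manifest's directory) must contain
    ``genome.fa``, ``tss.tsv``, ``expression.tsv``, ``cell_stats.tsv`` and
    any annotation ``*.bed`` sets (files named ``truth_*`` are ignored).
    """
    manifest_path = Path(manifest_path)
    data_dir = Path(data_dir) if data_dir else manifest_path.parent
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    (outdir / "run_config.txt").write_text(cfg.to_text())
    logger.info("resolved configuration:\n%s", cfg.to_text())

    manifest = sio.read_manifest(manifest_path)
    for _, row in manifest.iterrows():
        if not (data_dir / row["path"]).exists():
            raise PipelineError(f"missing call file for cell {row['cell_id']}")

    genome = load_genome(data_dir / "genome.fa")
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    genome_size = sum(chrom_lengths.values())
    tss = sio.read_tss_table(data_dir / "tss.tsv")
    expression = sio.read_expression(data_dir / "expression.tsv")
    annotations = {
        p.stem: sio.read_bed(p)
        for p in sorted(data_dir.glob("*.bed"))
        if not p.stem.startswith("truth_")
    }

    # ---- stage 1: QC -----------------------------------------------------
    stats = pd.read_csv(data_dir / "cell_stats.tsv", sep="\t", index_col="cell_id")
    qc_parts = []
    for assay, sub in manifest.groupby("assay"):
        part = qc_filter(stats.loc[sub["cell_id"]], assay, cfg)
        qc_parts.append(part)
    qc = pd.concat(qc_parts)
    qc.rename_axis("cell_id").to_csv(outdir / "qc_report.tsv", sep="\t")
    passing = set(qc.index[qc["pass"]])
    logger.info("QC: %d/%d cells pass", len(passing), len(manifest))
    manifest = manifest[manifest["cell_id"].isin(passing)].reset_index(drop=True)
    if manifest.empty:
        raise PipelineError("no cells pass QC")

    calls = {
        row["cell_id"]: sio.read_site_calls(data_dir / row["path"])
        for _, row in manifest.iterrows()
    }
    manifest["group"] = manifest.apply(_group_key, axis=1)
    groups = list(dict.fromkeys(manifest["group"]))
    cells_by_group = {
        g: [calls[c] for c in manifest.loc[manifest["group"] == g, "cell_id"]]
        for g in groups
    }
    phase_of_group = dict(zip(manifest["group"], manifest["phase"]))

    # ---- stage 2: methylation tile matrix --------------------------------
    cell_tiles = {
        cid: aggregate_tiles(df, METH_CONTEXTS, cfg.tile_size, cfg.tile_min_cpg)
        for cid, df in calls.items()
    }
    matrix, filtered = build_tile_matrix(cell_tiles, cfg.cluster_min_cell_frac)
    sio.write_tile_matrix(matrix, outdir / "tile_matrix.tsv")
    sio.write_tile_matrix(filtered, outdir / "tile_matrix_filtered.tsv")
    group_matrices = {
        g: matrix.loc[manifest.loc[manifest["group"] == g, "cell_id"]]
        for g in groups
    }

    # ---- stage 3: NDR calling per group ----------------------------------
    ndrs_by_group = {}
    for g in groups:
        track = pool_group(cells_by_group[g], group=g)
        ndrs = classify_ndrs(call_ndrs(track, cfg, chrom_lengths), tss,
                             cfg.proximal_radius)
        ndrs["name"] = [f"NDR_{g}_{i}" for i in range(len(ndrs))]
        sio.write_bed(ndrs, outdir / f"ndr_{g}.bed", score_field="n_gch")
        ndrs_by_group[g] = ndrs
        logger.info("NDRs in %s: %d", g, len(ndrs))

    # ---- stage 4: differential methylation (consecutive group pairs) -----
    demeth_by_pair = {}
    for ga, gb in zip(groups[:-1], groups[1:]):
        dmrs = call_dmrs(group_matrices[ga], group_matrices[gb], cfg)
        dmrs.to_csv(outdir / f"dmr_{ga}_vs_{gb}.tsv", sep="\t", index=False)
        demeth_by_pair[(ga, gb)] = dmrs
        logger.info(
            "DMRs %s vs %s: %d demethylated, %d de novo",
            ga, gb,
            int((dmrs["call"] == "demethylated").sum()),
            int((dmrs["call"] == "de_novo").sum()),
        )

    # ---- stage 5: differential openness ----------------------------------
    for ga, gb in zip(groups[:-1], groups[1:]):
        union = pd.concat(
            [ndrs_by_group[ga], ndrs_by_group[gb]], ignore_index=True
        )[["chrom", "start", "end"]].drop_duplicates().reset_index(drop=True)
        if union.empty:
            pd.DataFrame().to_csv(outdir / f"diffopen_{ga}_vs_{gb}.tsv", sep="\t")
            continue
        do = differential_open(
            union, cells_by_group[ga], cells_by_group[gb], cfg, (ga, gb)
        )
        do.to_csv(outdir / f"diffopen_{ga}_vs_{gb}.tsv", sep="\t", index=False)

    # ---- stage 6: enrichment ---------------------------------------------
    for g in groups:
        enr = open_enrichment(ndrs_by_group[g], annotations, genome_size)
        enr.to_csv(outdir / f"enrichment_open_{g}.tsv", sep="\t", index=False)
    for (ga, gb), dmrs in demeth_by_pair.items():
        cand = list(dmrs.loc[dmrs["call"] == "demethylated", "tile"])
        bg = list(dmrs["tile"])
        rows = [
            hypergeom_enrichment(cand, bg, ann, name)
            for name, ann in annotations.items()
        ]
        pd.DataFrame(rows).to_csv(
            outdir / f"enrichment_demeth_{ga}_vs_{gb}.tsv", sep="\t", index=False
        )

    # residual-methylation screen and ICR profile over all groups
    residual = residual_tiles(
        group_matrices, cfg.residual_level, cfg.dmr_min_cell_frac
    ) if len(groups) >= 2 else []
    Path(outdir / "residual_tiles.txt").write_text("\n".join(residual) + "\n")
    if "ICR_like" in annotations:
        icr = icr_profile(cells_by_group, annotations["ICR_like"])
        icr.rename_axis("icr").to_csv(outdir / "icr_profile.tsv", sep="\t")

    # ---- stage 7: promoter classes / three-omics integration -------------
    prom_classes = classify_promoters(genome, tss, cfg)
    prom_classes.rename_axis("gene").to_csv(outdir / "promoter_classes.tsv", sep="\t")
    signals = promoter_signals(cells_by_group, tss, cfg)
    signals.to_csv(outdir / "promoter_signals.tsv", sep="\t", index=False)
    rho_rows = []
    for g in groups:
        phase = phase_of_group[g]
        if phase not in expression.columns:
            logger.info("group %s: phase %s absent from expression table", g, phase)
            continue
        sig = signals[signals["group"] == g].set_index("gene")
        rho = omics_correlation(sig, expression[phase], prom_classes)
        rho.insert(0, "group", g)
        rho_rows.append(rho)
    if rho_rows:
        pd.concat(rho_rows).to_csv(outdir / "omics_correlation.tsv", sep="\t",
                                   index=False)

    # phase-specific gene screen over proximal NDRs (needs >= 3 phases)
    prox_parts = [
        df.loc[df["ndr_class"] == "proximal", ["chrom", "start", "end"]]
        for df in ndrs_by_group.values()
    ]
    prox_parts = [p for p in prox_parts if not p.empty]
    proximal = (
        pd.concat(prox_parts, ignore_index=True).drop_duplicates().reset_index(drop=True)
        if prox_parts
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    acc_cols = {}
    for g in groups:
        phase = phase_of_group[g]
        track = pool_group(cells_by_group[g], group=g)
        pooled = _pooled_calls(track)
        from .contexts import region_levels

        acc_cols[phase] = region_levels(pooled, proximal, classes=("GCH",)).to_numpy()
    acc_by_phase = pd.DataFrame(acc_cols, index=proximal.index)
    shared = [p for p in expression.columns if p in acc_by_phase.columns]
    if len(shared) >= 3 and len(proximal):
        screen = phase_specific_genes(proximal, acc_by_phase, tss, expression, cfg)
        screen.to_csv(outdir / "phase_specific_genes.tsv", sep="\t", index=False)
    else:
        logger.info("phase-specific screen skipped: %d shared phases", len(shared))
        pd.DataFrame(
            columns=["gene", "chrom", "start", "end", "r", "selected"]
        ).to_csv(outdir / "phase_specific_genes.tsv", sep="\t", index=False)

    # ---- stage 8: cell-to-cell variance ----------------------------------
    for g in groups:
        for fn, tag in ((methylation_variance, "meth"), (accessibility_variance, "acc")):
            try:
                track = fn(cells_by_group[g], cfg, chrom_lengths)
            except ValueError as exc:
                logger.info("variance (%s) skipped for %s: %s", tag, g, exc)
                continue
            track.to_csv(outdir / f"variance_{tag}_{g}.tsv", sep="\t", index=False)
            if annotations:
                variance_by_element(track, annotations).to_csv(
                    outdir / f"variance_{tag}_{g}_by_element.tsv", sep="\t",
                    index=False,
                )
    return outdir


def _pooled_calls(track) -> pd.DataFrame:
    rows = []
    for chrom, sub in track.sites.items():
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": sub["pos"],
                    "strand": "+",
                    "context": "GCH",
                    "n_meth": sub["c"],
                    "n_unmeth": sub["t"],
                }
            )
        )
    if not rows:
        return sio.empty_call_table()
    return pd.concat(rows, ignore_index=True)
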