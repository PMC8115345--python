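"""Self-contained evaluation scenarios for the pipeline's callers.

Each function builds a synthetic dataset with the generator's study-like
defaults, runs the relevant caller, and returns summary metrics against
the planted truth. They back both the test suite and the reproduction
script, so the numbers reported there are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .contexts import classify_contexts
from .integrate import phase_specific_genes
from .intervals import reciprocal_overlap
from .methdiff import call_dmrs
from .ndr import call_ndrs, classify_ndrs, pool_group
from .simulate import PhaseSpec, SimConfig, simulate_cell, simulate_genome
from .variance import chisq_var_lower


def _cohort_cells(cfg: SimConfig, phase: PhaseSpec, ctx, tile_levels, ndrs, seed):
    return [
        simulate_cell(ctx, tile_levels, ndrs, cfg, np.random.default_rng([seed, i]))
        for i in range(phase.n_cells)
    ]


def ndr_recovery(seed: int = 0, n_cells: int = 20) -> dict:
    """Recall/precision of the NDR caller on 20 planted 300-bp regions.

    One 200-kb chromosome, 20 promoters all open (enzyme efficiency 0.85,
    background 0.02), default per-cell sparsity; matching requires 50%
    reciprocal overlap.
    """
    genes = [f"gene{i:03d}" for i in range(20)]
    cfg = SimConfig(
        seed=seed, chrom_len=200_000, n_genes=20, promoter_ndr_width=300,
        phases=[PhaseSpec("p", n_cells, 0.10, genes)],
    )
    rng = np.random.default_rng(seed)
    genome, tss, _ = simulate_genome(cfg, rng)
    ctx = classify_contexts(genome)
    half = cfg.promoter_ndr_width // 2
    truth = pd.DataFrame(
        {"chrom": tss["chrom"], "start": tss["tss"] - half,
         "end": tss["tss"] + half}
    )
    n_tiles = {c: len(s) // cfg.tile_size + 1 for c, s in genome.items()}
    tiles = {c: np.full(n, 0.10) for c, n in n_tiles.items()}
    cells = _cohort_cells(cfg, cfg.phases[0], ctx, tiles, truth, seed)
    track = pool_group(cells)
    called = call_ndrs(track, AnalysisConfig(), {c: len(s) for c, s in genome.items()})

    t_ivals = list(zip(truth["start"], truth["end"]))
    c_ivals = list(zip(called["start"], called["end"]))
    matched_truth = sum(
        any(reciprocal_overlap(t, c) for c in c_ivals) for t in t_ivals
    )
    matched_called = sum(
        any(reciprocal_overlap(c, t) for t in t_ivals) for c in c_ivals
    )
    return {
        "recall": matched_truth / len(t_ivals),
        "precision": matched_called / len(c_ivals) if c_ivals else float("nan"),
        "n_truth": len(t_ivals),
        "n_called": len(c_ivals),
    }


def ndr_null_calls(seed: int = 0, n_sims: int = 100, n_cells: int = 10) -> dict:
    """Total NDR calls across background-only simulations (no planted NDRs)."""
    total = 0
    for s in range(n_sims):
        cfg = SimConfig(
            seed=seed, chrom_len=50_000, n_genes=4,
            phases=[PhaseSpec("p", n_cells, 0.10, [])],
        )
        rng = np.random.default_rng([seed, 7919, s])
        genome, _, _ = simulate_genome(cfg, rng)
        ctx = classify_contexts(genome)
        tiles = {c: np.full(len(q) // cfg.tile_size + 1, 0.10)
                 for c, q in genome.items()}
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        cells = [
            simulate_cell(ctx, tiles, empty, cfg,
                          np.random.default_rng([seed, 7919, s, i]))
            for i in range(n_cells)
        ]
        called = call_ndrs(pool_group(cells), AnalysisConfig(),
                           {c: len(q) for c, q in genome.items()})
        total += len(called)
    return {"total_calls": total, "n_sims": n_sims}


def _tile_matrix_from_levels(levels, n_cells, n_sites, rng, tag):
    obs = rng.binomial(n_sites, np.tile(levels, (n_cells, 1))) / n_sites
    return pd.DataFrame(
        obs,
        index=[f"{tag}{i}" for i in range(n_cells)],
        columns=[f"chr1:{i * 500}-{(i + 1) * 500}" for i in range(len(levels))],
    )


def dmr_null_calibration(seed: int = 0, n_sims: int = 50, n_tiles: int = 500,
                         n_cells: int = 20) -> dict:
    """Fraction of non-stable calls per simulation when both groups share
    identical Beta(2, 8) tile levels."""
    fracs = []
    for s in range(n_sims):
        rng = np.random.default_rng([seed, 104729, s])
        levels = rng.beta(2, 8, n_tiles)
        a = _tile_matrix_from_levels(levels, n_cells, 4, rng, "a")
        b = _tile_matrix_from_levels(levels, n_cells, 4, rng, "b")
        out = call_dmrs(a, b)
        fracs.append(float((out["call"] != "stable").mean()) if len(out) else 0.0)
    return {"nonstable_fracs": fracs, "n_sims": n_sims}


def dmr_power(seed: int = 0, n_sims: int = 50, n_tiles: int = 100,
              n_cells: int = 10) -> dict:
    """Fraction of truly 0.9-vs-0.1 tiles called demethylated."""
    called = 0
    total = 0
    for s in range(n_sims):
        rng = np.random.default_rng([seed, 1299709, s])
        a = _tile_matrix_from_levels(np.full(n_tiles, 0.9), n_cells, 4, rng, "a")
        b = _tile_matrix_from_levels(np.full(n_tiles, 0.1), n_cells, 4, rng, "b")
        out = call_dmrs(a, b)
        called += int((out["call"] == "demethylated").sum())
        total += n_tiles
    return {"power": called / total, "n_tiles_total": total}


def variance_ci_coverage(seed: int = 0, n_windows: int = 1000, n_cells: int = 20,
                         sigma2: float = 0.01) -> dict:
    """Coverage of the chi-squared variance lower bound on normal windows."""
    rng = np.random.default_rng(seed)
    samples = rng.normal(0.5, np.sqrt(sigma2), size=(n_windows, n_cells))
    s2 = samples.var(axis=1, ddof=1)
    lower = chisq_var_lower(s2, n_cells)
    return {
        "coverage": float((lower <= sigma2).mean()),
        "lower_exceeds_s2": int((lower > s2 + 1e-12).sum()),
        "n_windows": n_windows,
    }


def phase_specific_recovery(seed: int = 0, n_cells: int = 15) -> dict:
    """End-to-end screen on a 3-phase cohort with phase-specific promoters.

    18 genes are opened six-per-phase, 6 stay closed everywhere; expression
    mirrors the truth. Reports the fraction of truth genes selected and the
    number of selected truth-closed controls.
    """
    genes = [f"gene{i:03d}" for i in range(24)]
    open_sets = {"p1": genes[0:6], "p2": genes[6:12], "p3": genes[12:18]}
    controls = set(genes[18:24])
    cfg = SimConfig(
        seed=seed, chrom_len=250_000, n_genes=24, promoter_ndr_width=300,
        phases=[
            PhaseSpec("p1", n_cells, 0.15, open_sets["p1"]),
            PhaseSpec("p2", n_cells, 0.08, open_sets["p2"]),
            PhaseSpec("p3", n_cells, 0.67, open_sets["p3"], "soma"),
        ],
    )
    rng = np.random.default_rng(seed)
    genome, tss, _ = simulate_genome(cfg, rng)
    ctx = classify_contexts(genome)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    half = cfg.promoter_ndr_width // 2

    acfg = AnalysisConfig()
    tracks = {}
    truth_ndrs = {}
    for pi, phase in enumerate(cfg.phases):
        sub = tss[tss["gene"].isin(open_sets[phase.name])]
        truth_ndrs[phase.name] = pd.DataFrame(
            {"chrom": sub["chrom"].to_numpy(),
             "start": sub["tss"].to_numpy() - half,
             "end": sub["tss"].to_numpy() + half}
        ).reset_index(drop=True)
        n_tiles = {c: len(s) // cfg.tile_size + 1 for c, s in genome.items()}
        tiles = {c: np.full(n, phase.mean_cpg_meth) for c, n in n_tiles.items()}
        cells = [
            simulate_cell(ctx, tiles, truth_ndrs[phase.name], cfg,
                          np.random.default_rng([seed, pi, i]))
            for i in range(phase.n_cells)
        ]
        tracks[phase.name] = pool_group(cells)

    proximal_parts = []
    for name, track in tracks.items():
        called = classify_ndrs(call_ndrs(track, acfg, chrom_lengths), tss)
        proximal_parts.append(
            called.loc[called["ndr_class"] == "proximal", ["chrom", "start", "end"]]
        )
    proximal = (
        pd.concat(proximal_parts, ignore_index=True)
        .drop_duplicates()
        .reset_index(drop=True)
    )
    from .contexts import region_levels
    from .pipeline import _pooled_calls

    acc = pd.DataFrame(
        {name: region_levels(_pooled_calls(track), proximal, ("GCH",)).to_numpy()
         for name, track in tracks.items()},
        index=proximal.index,
    )
    expr = pd.DataFrame(1.0, index=genes, columns=list(open_sets))
    for ph, open_genes in open_sets.items():
        expr.loc[open_genes, ph] = 10.0

    screen = phase_specific_genes(proximal, acc, tss, expr, acfg)
    selected = set(screen.loc[screen["selected"], "gene"])
    truth_genes = set(genes[:18])
    return {
        "truth_selected_frac": len(selected & truth_genes) / len(truth_genes),
        "false_control_selected": len(selected & controls),
        "n_truth": len(truth_genes),
        "n_controls": len(controls),
    }
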