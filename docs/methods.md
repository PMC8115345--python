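# Methods

This note records the models, conventions and design choices behind
`scnome`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the synthetic cohorts do and do not show
about real data.

## Coordinates, contexts and levels

Internally everything is 0-based half-open; BED output follows the same
convention, while per-cell call-table TSVs are 1-based (bismark-coverage
dialect), converted on read. Cytosines on the two strands are independent
records and are never collapsed into a single CpG unit.

Every genomic cytosine receives exactly one context class from its
trinucleotide (reverse-complemented for minus-strand cytosines): `WCG`
(ACG/TCG — endogenous CpG methylation), `GCH` (GCA/GCC/GCT — enzymatic
accessibility), `GCG` (both a GpC and a CpG; ambiguous, classified but
excluded from both analyses), `CpG` (CCG — a CpG outside the WCG
definition, used for scBS-style methylation but never for accessibility),
and `other`. A trinucleotide containing N, or truncated at a chromosome
end, is `other`.

A site's level is C/(C+T) at whatever depth exists; a region or cell
level is the unweighted mean of per-site levels over covered sites of the
requested class. "1×" data are therefore handled identically to
multi-read sites — the two interpretations (use every read vs binarize)
coincide at depth 1, which dominates single-cell libraries, and the
proportion definition extends naturally where depth is higher.

Threshold boundary conventions follow the printed wording of the study
design throughout: "more than" is strict (tile covered in > 10% of cells;
window covered in > 30% of cells; > 3 CpG / > 5 GCH per cell per window;
> 2M CpG sites; regions > 140 bp), while "at least"/"≥"/"≤" are inclusive
(≥ 3 CpG per tile, ≥ 5 GCH per NDR, map rate ≥ 20%, FGC global
methylation ≤ 0.2, window p ≤ 1e-20, q ≤ 0.05, open ≥ 0.5, closed ≤ 0.3).
All thresholds live in `AnalysisConfig`, are logged with every run, and
may be overridden via a flat `key = value` file.

## NDR detection

Cells of a group are pooled site-wise (counts summed) because no single
sparse cell supports region calling. Each 100-bp window (20-bp step,
grid anchored at coordinate 0) is tested against the whole-genome GCH
totals by a 2×2 Pearson chi-square with 1 df and no continuity
correction. Choices worth recording:

* **One-sidedness** is a pre-gate: a window whose GCH rate does not
  exceed the background rate gets p = 1. Accessibility only ever raises
  GpC methylation.
* **Background composition**: genome totals *include* the window. The
  window is a negligible fraction of the genome, and a fixed background
  keeps the statistic identical across windows and runs.
* **Log-space p-values**: the 1-df tail is computed as
  `log(2) + log_ndtr(-sqrt(stat))`, which stays accurate far below the
  smallest double (a pooled track easily reaches p ~ 1e-300).
* **Merging**: overlapping or book-ended significant windows are unioned;
  the merged span (not a trimmed core) is the candidate. Candidates must
  be strictly longer than 140 bp — so a single isolated window (100 bp)
  can never become an NDR, which is what keeps the empty-genome false-call
  rate at zero — and must contain ≥ 5 covered GCH sites.
* **Untestable windows** (zero covered GCH reads) are skipped, not
  treated as closed.

This construction is monotone: loosening the p threshold can only grow
the significant-window set, so every stricter-threshold NDR is contained
in a looser-threshold NDR (asserted by test).

NDR centres within 2 kb of any TSS (inclusive) are proximal, else distal.

## Differential calls

**Methylation (tiles).** The study design fixes the level/FDR gates but
not the per-tile test; we use a two-sided Wilcoxon rank-sum across
per-cell tile levels — robust at single-cell group sizes, no normality
assumption — switching to the exact null distribution when the smaller
group has < 8 covered cells, with Welch's t selectable in config
(`dmr_stat = ttest`). BH-FDR runs over exactly the eligible tiles
(covered in > 10% of cells in both groups, computed against each group's
own post-QC cell count). Note the call gates are a conjunction: extreme
means alone never produce a call without q ≤ 0.05, which is what
calibrates the null (identically distributed groups produce ~0 calls).

**Openness (regions).** Candidate regions come from the union of both
groups' NDR calls. Per-cell region levels are mean per-site GCH levels;
cells between 0.3 and 0.5 count toward coverage but are neither open nor
closed, and the "open in only one group" criterion is an exclusive-or of
per-group open majorities. Swapping the groups flips the direction label
and nothing else.

## Enrichment

Open-chromatin enrichment per annotation class is
log2((NDR bases in class / NDR bases) / (class bases / genome bases)) on
merged intervals. Tile-set enrichment uses the exact hypergeometric upper
tail P(X ≥ k) with any-bp overlap against merged annotation intervals;
fold change is (k/n)/(K/N). Residual-methylation screening keeps tiles
whose group mean stays ≥ 0.4 at every stage where the tile is eligible,
requiring eligibility at all stages.

## Cell-to-cell variance

The per-cell window statistic is the mean of per-site levels (matching
the region-level definition above, rather than a pooled C/(C+T), which
would weight cells by depth). Heterogeneity is summarized by the lower
endpoint of the two-sided 95% chi-squared CI of the unbiased sample
variance, lower = (n−1)s²/χ²(0.975, n−1), which discounts windows where a
large s² rests on few covered cells; plain s² is emitted alongside so
either convention is available downstream. The same summary is applied to
both modalities for internal consistency (the accessibility side of the
published design is under-specified). Groups under 10 cells are skipped:
a variance lower bound over fewer cells is dominated by the χ² quantile,
not the data. The accessibility track has no published covered-cell
fraction gate; windows simply need ≥ 2 covered cells for s² to exist.

## Promoter classes and integration

HCP/ICP/LCP criteria are not part of the published design (only the class
names are); we adopt the field-standard sliding-subwindow definition:
HCP if any 500-bp subwindow (5-bp step) of the TSS−1000..+500 window has
CpG obs/exp > 0.75 *and* GC fraction > 0.55; LCP if no subwindow exceeds
obs/exp 0.48; ICP otherwise. CpG statistics are strand-symmetric, so the
plus-strand sequence is scanned regardless of gene orientation; the
window coordinates themselves are strand-oriented (upstream = 5').

For the phase-specific screen each proximal NDR is assigned to the
nearest TSS within 2 kb (distance from NDR centre; ties resolve to the
lexicographically smaller gene id — the published design names no
mapping). The screen is region-level: a gene with several proximal NDRs
contributes several records. Pearson r is computed across the shared
phases of the expression table and the pooled accessibility vectors
(≥ 3 phases required); the r > 0.6 selection is strict, and regions with
missing accessibility in any phase are skipped rather than imputed.

## Synthetic cohorts

The generator emulates the statistical structure the callers rely on, at
desk scale:

* **Genome**: i.i.d. bases at a configurable GC fraction (default 0.45,
  ~7.8 GCH sites per 100 bp on the two strands); one TSS per gene, spaced
  so ±2-kb promoter windows never overlap.
* **Methylation**: per (phase, tile) a level is drawn from a Beta centred
  on the phase mean with dispersion 1/(α+β) (default 0.05); per-cell site
  calls are Binomial(depth, tile level). Phase means default to 0.15/0.08
  (germ-cell phases) and 0.67 (soma), the hypo/hyper split of the tissue.
* **Accessibility**: a two-state model — GCH sites inside a planted
  300-bp promoter NDR emit methylated calls at the enzyme efficiency
  (default 0.85; GpC labelling is imperfect), all other GCH sites at a
  single background rate (default 0.02) that folds together bisulfite
  non-conversion and nonspecific labelling, which are indistinguishable
  in call tables. Two states suffice because the caller needs rate
  separation, and they make recall/precision well defined.
* **Sparsity**: each site is covered with probability 0.12 (the ~10–15%
  per-cell coverage of real libraries) at depth 1 + Poisson(d−1), d = 1
  by default, so the dominant regime is single-read.
* **Expression**: genes opened in a phase are 10× baseline there, with
  5% lognormal noise — enough signal that the r > 0.6 screen's expected
  output is derivable from truth.

What the synthetic cohorts do *not* model: mappability and GC bias,
PCR duplicates, continuous nucleosome occupancy profiles, correlated
methylation along reads, copy-number structure, imprinted (parent-of-
origin) asymmetry, and realistic repeat sequence content (annotation
"repeat" sets are interval families only). Passing tests therefore
demonstrate correctness of the statistics and calling logic under the
stated generative assumptions, not robustness to alignment artefacts.

## Verification scenarios and problem sizes

`scnome.benchmarks` fixes the evaluation scenarios used by the test suite
and `scripts/acceptance.py`: NDR recovery on a 200-kb chromosome with 20
planted 300-bp NDRs pooled over 20 cells (~19 GCH reads per 100-bp
window) matched at 50% reciprocal overlap; 100 background-only 50-kb
cohorts for the null; 50 simulations of 500-tile / 20-cell
identical-Beta(2,8) groups for DMR calibration and 50 × 100 tiles at
0.9-vs-0.1 with 10 cells per group for power; 1000 Normal(0.5, 0.01)
windows of 20 cells for CI coverage; and a 250-kb, 24-gene, 3-phase
cohort (6 promoters opened per phase, 6 never opened) for the end-to-end
expression screen. Exact statistics are checked against independent
oracles: the chi-square tail against an arbitrary-precision erfc
evaluation over 1000 count configurations, the hypergeometric tail
against integer-arithmetic enumeration of every parameter set with
N ≤ 60, and the context classifier against a literal rule table over all
64 trinucleotides on both strands.

## Known limitations

* The per-tile DMR p-value could alternatively be computed from pooled
  read counts (Fisher); the per-cell-level reading is implemented because
  eligibility is defined in terms of cells, but the choice is exposed via
  the test-statistic config rather than hidden.
* QC statistics (mapping rate, conversion rate) are accepted as provided
  per library; the package does not estimate conversion from spike-ins.
* Sex chromosomes receive no special treatment; synthetic genomes are
  autosome-like.
* The pipeline compares consecutive manifest groups for differential
  stages; arbitrary pair selection is available through the library API
  and the `dmr`/`diffopen` subcommands.
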