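"""Analysis configuration.

Every numeric threshold used by the pipeline is a named field here, with
defaults equal to the published single-cell methylome/chromatin study design:
500-bp methylation tiles with >= 3 CpG sites, the 0.75/0.25 DMR levels at
FDR 0.05, the 100-bp/20-bp chi-square NDR scan at p <= 1e-20 with the
> 140 bp / >= 5 GCH region filter, the 0.2 difference / 0.5-open / 0.3-closed
differential-openness rules, the r > 0.6 expression-accessibility screen, and
the 3000/600 (methylation) and 200/100 (accessibility) variance windows.

Boundary strictness follows the printed wording exactly: "more than" is a
strict inequality, "at least" / ">=" / "<=" are inclusive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class QcScbsThresholds:
    """Library-level QC gates for single-cell bisulfite libraries."""

    map_rate: float = 0.20        # mapping rate, inclusive minimum
    conversion: float = 0.99      # bisulfite conversion rate, inclusive minimum
    non_cpg_meth: float = 0.02    # non-CpG methylation, inclusive maximum
    min_cpg_sites: float = 2e6    # covered CpG sites, strict minimum ("more than")
    fgc_max_meth: float = 0.2     # global CpG methylation ceiling, FGC cells only


@dataclass
class QcCoolThresholds:
    """Library-level QC gates for single-cell NOMe-seq (COOL-seq) libraries."""

    map_rate: float = 0.20
    min_wcg: float = 1e6          # covered WCG sites, strict minimum
    min_gch: float = 1e7          # covered GCH sites, strict minimum
    fgc_max_meth: float = 0.2


@dataclass
class AnalysisConfig:
    # methylation tiles
    tile_size: int = 500
    tile_min_cpg: int = 3
    cluster_min_cell_frac: float = 0.70   # strict > for the clustering export

    # differential methylation
    dmr_hi: float = 0.75
    dmr_lo: float = 0.25
    dmr_alpha: float = 0.05
    dmr_min_cell_frac: float = 0.10       # strict > in both groups
    dmr_stat: str = "wilcoxon"            # or "ttest"

    # NDR detection
    ndr_window: int = 100
    ndr_step: int = 20
    ndr_p: float = 1e-20
    ndr_min_len: int = 140                # strict > ("longer than 140 bp")
    ndr_min_gch: int = 5                  # inclusive ("at least five")
    proximal_radius: int = 2000

    # differential openness
    do_min_cell_frac: float = 0.40        # strict > in both groups
    do_min_diff: float = 0.2              # strict >
    do_open_level: float = 0.5            # inclusive ("open regions were >= 0.5")
    do_closed_level: float = 0.3          # inclusive ("closed regions were <= 0.3")

    # expression/accessibility screen and residual-methylation screen
    corr_r: float = 0.6                   # strict >
    residual_level: float = 0.4           # inclusive (">= 0.4")

    # cell-to-cell variance
    meth_var_window: int = 3000
    meth_var_step: int = 600
    meth_var_min_cpg: int = 3             # per-cell per-window, strict >
    meth_var_min_cell_frac: float = 0.30  # strict >
    var_conf: float = 0.95
    acc_var_window: int = 200
    acc_var_step: int = 100
    acc_var_min_gch: int = 5              # per-cell per-window, strict >
    var_min_cells: int = 10               # groups below this are skipped

    # promoter windows (strand-oriented; upstream/downstream of the TSS)
    prom_meth_up: int = 1000
    prom_meth_down: int = 500
    prom_acc_up: int = 200
    prom_acc_down: int = 100

    # promoter CpG-density classes (field-standard sliding-subwindow criteria)
    hcp_obs_exp: float = 0.75
    hcp_gc: float = 0.55
    lcp_obs_exp: float = 0.48
    cpg_subwindow: int = 500
    cpg_subwindow_step: int = 5

    qc_scbs: QcScbsThresholds = field(default_factory=QcScbsThresholds)
    qc_cool: QcCoolThresholds = field(default_factory=QcCoolThresholds)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fracs = [
            "cluster_min_cell_frac", "dmr_hi", "dmr_lo", "dmr_alpha",
            "dmr_min_cell_frac", "do_min_cell_frac", "do_min_diff",
            "do_open_level", "do_closed_level", "corr_r", "residual_level",
            "meth_var_min_cell_frac", "var_conf",
        ]
        for name in fracs:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        positives = [
            "tile_size", "tile_min_cpg", "ndr_window", "ndr_step",
            "ndr_min_len", "ndr_min_gch", "proximal_radius",
            "meth_var_window", "meth_var_step", "meth_var_min_cpg",
            "acc_var_window", "acc_var_step", "acc_var_min_gch",
            "var_min_cells", "prom_meth_up", "prom_meth_down",
            "prom_acc_up", "prom_acc_down", "cpg_subwindow",
            "cpg_subwindow_step",
        ]
        for name in positives:
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v > 0):
                raise ValueError(f"{name}={v!r} must be a positive integer")
        if not (0.0 < self.ndr_p <= 1.0):
            raise ValueError(f"ndr_p={self.ndr_p} outside (0, 1]")
        if self.dmr_stat not in ("wilcoxon", "ttest"):
            raise ValueError(f"unknown dmr_stat {self.dmr_stat!r}")

    # -- flat key=value config file ------------------------------------

    _INT_FIELDS = frozenset(
        n for n in (
            "tile_size tile_min_cpg ndr_window ndr_step ndr_min_len "
            "ndr_min_gch proximal_radius meth_var_window meth_var_step "
            "meth_var_min_cpg acc_var_window acc_var_step acc_var_min_gch "
            "var_min_cells prom_meth_up prom_meth_down prom_acc_up "
            "prom_acc_down cpg_subwindow cpg_subwindow_step"
        ).split()
    )

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a flat ``key = value`` text file; unknown keys are errors.

        Nested QC thresholds use dotted keys, e.g. ``qc_scbs.map_rate = 0.2``.
        """
        cfg = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            cfg._set(key, val, f"{path}:{lineno}")
        cfg.validate()
        return cfg

    def _set(self, key: str, val: str, where: str) -> None:
        if "." in key:
            group, sub = key.split(".", 1)
            if group not in ("qc_scbs", "qc_cool"):
                raise ValueError(f"{where}: unknown config group {group!r}")
            obj = getattr(self, group)
            if not hasattr(obj, sub):
                raise ValueError(f"{where}: unknown key {key!r}")
            setattr(obj, sub, float(val))
            return
        if not hasattr(self, key) or key.startswith("_"):
            raise ValueError(f"{where}: unknown key {key!r}")
        if key == "dmr_stat":
            setattr(self, key, val)
        elif key in self._INT_FIELDS:
            setattr(self, key, int(val))
        else:
            setattr(self, key, float(val))

    def to_text(self) -> str:
        """Serialize as the same flat format (used for run logging)."""
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                for sub in dataclasses.fields(v):
                    lines.append(f"{f.name}.{sub.name} = {getattr(v, sub.name)}")
            else:
                lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"
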