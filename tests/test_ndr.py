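import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from scnome.config import AnalysisConfig
from scnome.ndr import (
    PooledGchTrack,
    call_ndrs,
    classify_ndrs,
    differential_open,
    open_enrichment,
    pool_group,
    window_chisq,
)


def make_track(pos, c, t, extra_bg=(0, 0)):
    """Hand-built pooled track on chr1 with optional extra background counts."""
    sites = {
        "chr1": pd.DataFrame({"pos": np.asarray(pos), "c": np.asarray(c),
                              "t": np.asarray(t)})
    }
    return PooledGchTrack(
        sites=sites,
        group="g",
        c_total=int(np.sum(c)) + extra_bg[0],
        t_total=int(np.sum(t)) + extra_bg[1],
    )


class TestPoolGroup:
    def test_counts_add(self, make_calls):
        a = make_calls([("chr1", 10, "+", "GCH", 1, 0)])
        b = make_calls([("chr1", 10, "+", "GCH", 2, 1)])
        track = pool_group([a, b])
        site = track.sites["chr1"].iloc[0]
        assert (site["c"], site["t"]) == (3, 1)

    def test_single_cell_identity(self, make_calls):
        a = make_calls(
            [("chr1", 10, "+", "GCH", 1, 2), ("chr2", 5, "-", "GCH", 0, 1)]
        )
        track = pool_group([a])
        assert track.sites["chr1"].iloc[0].tolist() == [10, 1, 2]
        assert track.sites["chr2"].iloc[0].tolist() == [5, 0, 1]

    def test_totals_match_concat_and_sum(self, make_calls, rng):
        cells = []
        for _ in range(5):
            n = 30
            cells.append(
                make_calls(
                    [
                        ("chr1", int(p), "+", "GCH", int(m), int(u))
                        for p, m, u in zip(
                            rng.integers(0, 200, n),
                            rng.integers(0, 3, n),
                            rng.integers(0, 3, n),
                        )
                        if m + u > 0
                    ]
                )
            )
        track = pool_group(cells)
        cat = pd.concat(cells)
        assert track.c_total == cat["n_meth"].sum()
        assert track.t_total == cat["n_unmeth"].sum()
        brute = cat.groupby("pos")[["n_meth", "n_unmeth"]].sum()
        sites = track.sites["chr1"].set_index("pos")
        assert (sites["c"] == brute["n_meth"]).all()
        assert (sites["t"] == brute["n_unmeth"]).all()

    def test_other_contexts_excluded(self, make_calls):
        a = make_calls(
            [("chr1", 10, "+", "GCH", 1, 0), ("chr1", 12, "+", "WCG", 5, 0)]
        )
        track = pool_group([a])
        assert len(track.sites["chr1"]) == 1 and track.c_total == 1


class TestWindowChisq:
    def test_wrong_direction_gives_p_one(self):
        # window fully unmethylated, background rate 3%
        assert window_chisq(0, 10, 3_000, 97_000) == 0.0

    def test_monotone_in_methylated_count(self):
        ps = [window_chisq(k, 0, 30_000, 970_000) for k in (2, 5, 10, 20, 40)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_against_direct_2x2_evaluation(self):
        wc, wt, bc, bt = 40, 10, 30_000, 970_000
        # direct Pearson statistic from expected counts of the 2x2 table
        obs = np.array([[wc, wt], [bc, bt]], dtype=float)
        rowsum = obs.sum(axis=1, keepdims=True)
        colsum = obs.sum(axis=0, keepdims=True)
        exp = rowsum * colsum / obs.sum()
        stat = ((obs - exp) ** 2 / exp).sum()
        expected_log10p = chi2.logsf(stat, 1) / np.log(10)
        got = window_chisq(wc, wt, bc, bt)
        assert got == pytest.approx(expected_log10p, rel=1e-10)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            window_chisq(1, 0, 0, 0)

    def test_underflow_handled_in_log_space(self):
        lp = window_chisq(5000, 0, 100_000, 9_900_000)
        assert lp < -300 and np.isfinite(lp)


class TestCallNdrs:
    def test_no_significant_windows_empty(self):
        pos = np.arange(0, 2000, 25)
        track = make_track(pos, np.zeros(len(pos), int), np.full(len(pos), 3))
        assert call_ndrs(track, chrom_lengths={"chr1": 2000}).empty

    def test_merged_span_of_consecutive_windows(self):
        # 5 highly methylated GCH sites at 0..80: every covered window
        # starts in 0..80, so the merged span is [0, 180)
        pos = np.arange(0, 100, 20)
        track = make_track(
            pos, np.full(len(pos), 30), np.zeros(len(pos), int),
            extra_bg=(10_000, 990_000),
        )
        ndrs = call_ndrs(track, chrom_lengths={"chr1": 10_000})
        assert len(ndrs) == 1
        ndr = ndrs.iloc[0]
        assert (ndr["start"], ndr["end"]) == (0, 180)
        assert ndr["n_gch"] == 5
        assert ndr["end"] - ndr["start"] > 140

    def test_single_window_too_short(self):
        # one isolated significant window: span 100 <= 140 -> no NDR
        pos = np.arange(100, 200, 15)
        track = make_track(
            pos, np.full(len(pos), 30), np.zeros(len(pos), int),
            extra_bg=(10_000, 990_000),
        )
        cfg = AnalysisConfig(ndr_step=100)  # non-overlapping windows
        ndrs = call_ndrs(track, cfg, chrom_lengths={"chr1": 10_000})
        assert ndrs.empty

    def test_min_gch_site_filter(self):
        # long significant span carried by only 4 covered sites
        pos = np.array([0, 60, 120, 180])
        track = make_track(
            pos, np.full(4, 80), np.zeros(4, int), extra_bg=(10_000, 990_000)
        )
        ndrs = call_ndrs(track, chrom_lengths={"chr1": 10_000})
        assert ndrs.empty
        cfg = AnalysisConfig(ndr_min_gch=4)
        ndrs = call_ndrs(track, cfg, chrom_lengths={"chr1": 10_000})
        assert len(ndrs) == 1

    def test_threshold_monotonicity(self, rng):
        """Loosening the p threshold never loses called territory."""
        n = 300
        pos = np.sort(rng.choice(20_000, n, replace=False))
        hot = (pos > 5_000) & (pos < 5_400)
        c = np.where(hot, rng.binomial(8, 0.8, n), rng.binomial(8, 0.02, n))
        t = 8 - c
        track = make_track(pos, c, t, extra_bg=(10_000, 2_000_000))
        strict = call_ndrs(track, AnalysisConfig(ndr_p=1e-20),
                           chrom_lengths={"chr1": 20_000})
        loose = call_ndrs(track, AnalysisConfig(ndr_p=1e-5),
                          chrom_lengths={"chr1": 20_000})
        for _, nd in strict.iterrows():
            contained = (
                (loose["start"] <= nd["start"]) & (loose["end"] >= nd["end"])
            ).any()
            assert contained


class TestClassifyNdrs:
    TSS = pd.DataFrame(
        {"gene": ["g1", "g2"], "chrom": ["chr1", "chr1"],
         "tss": [10_000, 50_000], "strand": ["+", "-"]}
    )

    def _one(self, start, end):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [start], "end": [end],
             "n_gch": [10], "pooled_level": [0.5], "log10_p": [-30.0]}
        )

    def test_center_at_tss_is_proximal(self):
        out = classify_ndrs(self._one(9_900, 10_100), self.TSS)
        assert out["ndr_class"].iloc[0] == "proximal"

    def test_center_beyond_radius_is_distal(self):
        out = classify_ndrs(self._one(12_001, 12_003), self.TSS)  # centre 12002
        assert out["ndr_class"].iloc[0] == "distal"

    def test_center_exactly_at_radius_is_proximal(self):
        out = classify_ndrs(self._one(11_999, 12_001), self.TSS)  # centre 12000
        assert out["ndr_class"].iloc[0] == "proximal"

    def test_matches_all_pairs_brute_force(self, rng):
        starts = rng.choice(100_000, 60, replace=False)
        ndrs = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 200,
             "n_gch": 10, "pooled_level": 0.5, "log10_p": -25.0}
        )
        tss = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(8)], "chrom": "chr1",
             "tss": rng.choice(100_000, 8, replace=False), "strand": "+"}
        )
        got = classify_ndrs(ndrs, tss)["ndr_class"]
        centers = (ndrs["start"] + ndrs["end"]) / 2
        brute = [
            "proximal" if (abs(tss["tss"] - c) <= 2000).any() else "distal"
            for c in centers
        ]
        assert got.tolist() == brute


class TestDifferentialOpen:
    REGION = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})

    def _cells(self, levels, n_sites=3):
        """One cell per level; NaN level = uncovered cell."""
        cells = []
        for lev in levels:
            if np.isnan(lev):
                cells.append(
                    pd.DataFrame(
                        {"chrom": ["chr2"], "pos": [5], "strand": "+",
                         "context": "GCH", "n_meth": [1], "n_unmeth": [0]}
                    )
                )
                continue
            n_meth = int(round(lev * 10))
            rows = [
                ("chr1", 10 * (i + 1), "+", "GCH", n_meth, 10 - n_meth)
                for i in range(n_sites)
            ]
            cells.append(
                pd.DataFrame(
                    rows,
                    columns=["chrom", "pos", "strand", "context",
                             "n_meth", "n_unmeth"],
                )
            )
        return cells

    def test_low_coverage_not_called(self):
        nan = float("nan")
        a = self._cells([0.9, 0.9] + [nan] * 3)      # 2/5 covered = 0.4, not > 0.4
        b = self._cells([0.1] * 5)
        out = differential_open(self.REGION, a, b)
        assert out.empty

    def test_clear_difference_called_with_direction(self):
        a = self._cells([0.9, 0.8, 0.7, 0.9, 0.6])
        b = self._cells([0.1, 0.2, 0.0, 0.15, 0.1])
        out = differential_open(self.REGION, a, b)
        assert len(out) == 1
        assert out["direction"].iloc[0] == "A-open"

    def test_symmetry_swapping_groups_flips_direction(self):
        a = self._cells([0.9, 0.8, 0.7, 0.9, 0.6])
        b = self._cells([0.1, 0.2, 0.0, 0.15, 0.1])
        fwd = differential_open(self.REGION, a, b, groups=("A", "B"))
        rev = differential_open(self.REGION, b, a, groups=("A", "B"))
        assert len(fwd) == len(rev) == 1
        assert fwd["direction"].iloc[0] == "A-open"
        assert rev["direction"].iloc[0] == "B-open"

    def test_intermediate_cells_break_majority(self):
        # group A covered but cells in (0.3, 0.5): neither open nor closed
        a = self._cells([0.4, 0.4, 0.4, 0.4, 0.4])
        b = self._cells([0.1, 0.1, 0.1, 0.1, 0.1])
        out = differential_open(self.REGION, a, b)
        assert out.empty  # no open majority anywhere

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            differential_open(self.REGION, [], self._cells([0.1]))

    def test_null_permutation_calibration(self, rng):
        """Label-permuted identical groups yield few calls (<= 5%)."""
        n_regions, n_cells = 200, 15
        regions = pd.DataFrame(
            {"chrom": "chr1",
             "start": np.arange(n_regions) * 1000,
             "end": np.arange(n_regions) * 1000 + 500}
        )
        def sim_cell():
            rows = []
            for r in range(n_regions):
                base = r * 1000
                for j in range(4):
                    if rng.random() < 0.8:
                        m = rng.binomial(1, 0.3)
                        rows.append(("chr1", base + 50 + j * 100, "+", "GCH",
                                     m, 1 - m))
            return pd.DataFrame(
                rows, columns=["chrom", "pos", "strand", "context",
                               "n_meth", "n_unmeth"])
        cells = [sim_cell() for _ in range(2 * n_cells)]
        perm = rng.permutation(2 * n_cells)
        a = [cells[i] for i in perm[:n_cells]]
        b = [cells[i] for i in perm[n_cells:]]
        out = differential_open(regions, a, b)
        assert len(out) <= 0.05 * n_regions


class TestOpenEnrichment:
    def test_whole_genome_annotation_zero_enrichment(self):
        ndrs = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [400]})
        ann = {"all": pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})}
        out = open_enrichment(ndrs, ann, 10_000)
        assert out["enrichment"].iloc[0] == pytest.approx(0.0)

    def test_quarter_genome_containment_gives_two(self):
        ndrs = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [400]})
        ann = {"q": pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2_500]})}
        out = open_enrichment(ndrs, ann, 10_000)
        assert out["enrichment"].iloc[0] == pytest.approx(2.0)

    def test_zero_base_class_missing_with_warning(self):
        ndrs = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [400]})
        with pytest.warns(UserWarning):
            out = open_enrichment(
                ndrs, {"none": pd.DataFrame(columns=["chrom", "start", "end"])},
                10_000,
            )
        assert np.isnan(out["enrichment"].iloc[0])

    def test_base_level_recount_on_toy_genome(self, rng):
        genome_size = 10_000
        starts = np.sort(rng.choice(genome_size - 100, 15, replace=False))
        ndrs = pd.DataFrame(
            {"chrom": "chr1", "start": starts,
             "end": starts + rng.integers(20, 100, 15)}
        )
        astarts = np.sort(rng.choice(genome_size - 200, 10, replace=False))
        ann = pd.DataFrame(
            {"chrom": "chr1", "start": astarts,
             "end": astarts + rng.integers(50, 200, 10)}
        )
        out = open_enrichment(ndrs, {"x": ann}, genome_size)
        # brute force base-by-base
        in_ndr = np.zeros(genome_size, bool)
        for _, r in ndrs.iterrows():
            in_ndr[r["start"]:r["end"]] = True
        in_ann = np.zeros(genome_size, bool)
        for _, r in ann.iterrows():
            in_ann[r["start"]:r["end"]] = True
        expected = np.log2(
            ((in_ndr & in_ann).sum() / in_ndr.sum()) / (in_ann.sum() / genome_size)
        )
        assert out["enrichment"].iloc[0] == pytest.approx(expected)
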