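import itertools

import numpy as np
import pandas as pd
import pytest

from scnome.config import AnalysisConfig
from scnome.contexts import (
    METH_CONTEXTS,
    aggregate_tiles,
    build_tile_matrix,
    classify_contexts,
    classify_trinucleotide,
    global_level,
    qc_filter,
    region_levels,
    site_levels,
)

# independent brute-force classifier: literal lookup from the definitions
BRUTE = {}
for left, right in itertools.product("ACGT", repeat=2):
    tri = left + "C" + right
    if tri in ("ACG", "TCG"):
        BRUTE[tri] = "WCG"
    elif tri in ("GCA", "GCC", "GCT"):
        BRUTE[tri] = "GCH"
    elif tri == "GCG":
        BRUTE[tri] = "GCG"
    elif right == "G":  # CCG: CpG but not WCG
        BRUTE[tri] = "CpG"
    else:
        BRUTE[tri] = "other"

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(_RC)[::-1]


class TestClassifyContexts:
    def test_all_trinucleotides_both_strands(self):
        """Exhaustive check of the 16 centre-C trinucleotides on + and -."""
        for tri, expected in BRUTE.items():
            plus = classify_contexts({"c": f"AA{tri}AA"})["c"]
            rec = plus[(plus["pos"] == 3) & (plus["strand"] == "+")]
            assert rec["cls"].iloc[0] == expected, tri
            minus = classify_contexts({"c": f"AA{revcomp(tri)}AA"})["c"]
            rec = minus[(minus["pos"] == 3) & (minus["strand"] == "-")]
            assert rec["cls"].iloc[0] == expected, tri

    def test_spec_sequences(self):
        cm = classify_contexts({"c": "TACGT"})["c"]
        assert cm.set_index(["pos", "strand"])["cls"].to_dict() == {
            (2, "+"): "WCG",
            (3, "-"): "WCG",
        }
        cm = classify_contexts({"c": "AGCAT"})["c"]
        assert cm[(cm["pos"] == 2) & (cm["strand"] == "+")]["cls"].iloc[0] == "GCH"

    def test_edges_and_n_are_other(self):
        cm = classify_contexts({"c": "CGNCGC"})["c"]
        by = cm.set_index(["pos", "strand"])["cls"]
        assert by[(0, "+")] == "other"  # no 5' neighbour
        assert by[(5, "+")] == "other"  # no 3' neighbour
        assert by[(3, "+")] == "other"  # N in trinucleotide
        assert by[(1, "-")] == "other"  # N in minus-strand trinucleotide
        assert by[(4, "-")] == "GCG"    # revcomp(CGC) = GCG

    def test_partition_every_cytosine_exactly_once(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=3000, p=[0.3, 0.2, 0.2, 0.28, 0.02]))
        cm = classify_contexts({"c": seq})["c"]
        n_c = seq.count("C")
        n_g = seq.count("G")
        assert len(cm) == n_c + n_g
        assert not cm.duplicated(["pos", "strand"]).any()
        assert cm["cls"].isin(["WCG", "GCH", "GCG", "CpG", "other"]).all()

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            classify_contexts({"c": "ACXGT"})

    def test_trinucleotide_helper_matches_table(self):
        for tri, expected in BRUTE.items():
            assert classify_trinucleotide(tri) == expected


class TestLevels:
    @pytest.mark.parametrize(
        "n_meth,n_unmeth,expected", [(3, 1, 0.75), (0, 5, 0.0), (7, 0, 1.0)]
    )
    def test_site_level_is_meth_fraction(self, n_meth, n_unmeth, expected, make_calls):
        calls = make_calls([("chr1", 0, "+", "WCG", n_meth, n_unmeth)])
        assert site_levels(calls).iloc[0] == expected

    def test_global_level_unweighted_mean(self, make_calls):
        calls = make_calls(
            [
                ("chr1", 0, "+", "WCG", 2, 0),   # 1.0
                ("chr1", 5, "+", "WCG", 0, 9),   # 0.0  (depth ignored)
                ("chr1", 9, "+", "WCG", 1, 1),   # 0.5
                ("chr1", 12, "+", "GCH", 5, 0),  # other class, excluded
            ]
        )
        assert global_level(calls, ("WCG",)) == pytest.approx(0.5)

    def test_global_level_no_sites_warns_nan(self, make_calls):
        calls = make_calls([("chr1", 0, "+", "GCH", 1, 0)])
        with pytest.warns(UserWarning):
            assert np.isnan(global_level(calls, ("WCG",)))

    def test_binomial_sampling_recovers_rate(self, rng):
        n = 10_000
        true = 0.67
        meth = rng.binomial(1, true, size=n)
        calls = pd.DataFrame(
            {
                "chrom": "chr1", "pos": np.arange(n), "strand": "+",
                "context": "WCG", "n_meth": meth, "n_unmeth": 1 - meth,
            }
        )
        se = np.sqrt(true * (1 - true) / n)
        assert abs(global_level(calls) - true) <= 3 * se


class TestTiles:
    def test_tile_mean_and_min_sites(self, make_calls):
        calls = make_calls(
            [
                ("chr1", 10, "+", "WCG", 1, 0),
                ("chr1", 200, "+", "WCG", 1, 0),
                ("chr1", 499, "-", "WCG", 0, 1),
                ("chr1", 600, "+", "WCG", 1, 0),  # tile 2: only 2 sites
                ("chr1", 700, "+", "WCG", 1, 0),
            ]
        )
        tiles = aggregate_tiles(calls, ("WCG",), 500, 3)
        assert len(tiles) == 1
        assert tiles.iloc[0]["start"] == 0
        assert tiles.iloc[0]["mean_level"] == pytest.approx(2 / 3)

    def test_hand_computed_five_tile_chromosome(self, make_calls):
        records = []
        # tile k holds 3 sites at levels k/4, 1, 0
        for k in range(5):
            records += [
                ("chr1", k * 500 + 10, "+", "WCG", k, 4 - k),
                ("chr1", k * 500 + 20, "+", "WCG", 1, 0),
                ("chr1", k * 500 + 30, "+", "WCG", 0, 1),
            ]
        tiles = aggregate_tiles(make_calls(records), ("WCG",), 500, 3)
        expected = [(k / 4 + 1.0 + 0.0) / 3 for k in range(5)]
        assert tiles["mean_level"].tolist() == pytest.approx(expected)

    def test_tile_means_invariant_to_row_order(self, make_calls, rng):
        records = [
            ("chr1", int(p), "+", "WCG", int(m), 1)
            for p, m in zip(rng.choice(5000, 60, replace=False), rng.integers(0, 3, 60))
        ]
        a = aggregate_tiles(make_calls(records), ("WCG",), 500, 3)
        shuffled = make_calls([records[i] for i in rng.permutation(60)])
        b = aggregate_tiles(shuffled, ("WCG",), 500, 3)
        pd.testing.assert_frame_equal(a, b)

    def test_matrix_cell_fraction_strictness(self):
        def tiles_for(covered):
            return pd.DataFrame(
                {
                    "chrom": ["chr1"] if covered else [],
                    "start": [0] if covered else [],
                    "end": [500] if covered else [],
                    "n_sites": [3] if covered else [],
                    "mean_level": [0.5] if covered else [],
                }
            )

        # covered in 7/10 cells: fraction 0.7 is NOT > 0.7 -> excluded
        cells = {f"c{i}": tiles_for(i < 7) for i in range(10)}
        _, filtered = build_tile_matrix(cells, 0.70)
        assert filtered.shape[1] == 0
        # covered in 8/10 -> retained
        cells = {f"c{i}": tiles_for(i < 8) for i in range(10)}
        matrix, filtered = build_tile_matrix(cells, 0.70)
        assert filtered.shape[1] == 1
        assert matrix.shape == (10, 1)

    def test_retained_count_matches_brute_force(self, rng):
        n_cells, n_tiles = 12, 40
        present = rng.random((n_cells, n_tiles)) < 0.6
        cells = {}
        for i in range(n_cells):
            idx = np.flatnonzero(present[i])
            cells[f"c{i}"] = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": idx * 500,
                    "end": (idx + 1) * 500,
                    "n_sites": 3,
                    "mean_level": 0.5,
                }
            )
        _, filtered = build_tile_matrix(cells, 0.70)
        brute = sum(present[:, t].sum() / n_cells > 0.70 for t in range(n_tiles))
        assert filtered.shape[1] == brute

    def test_region_levels_brute_force(self, make_calls, rng):
        records = [
            ("chr1", int(p), "+", "GCH", int(m), 1)
            for p, m in zip(rng.choice(3000, 80, replace=False), rng.integers(0, 2, 80))
        ]
        calls = make_calls(records).sort_values("pos").reset_index(drop=True)
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 1000, 2500], "end": [900, 1001, 3000]}
        )
        got = region_levels(calls, regions, ("GCH",))
        for i, (_, r) in enumerate(regions.iterrows()):
            sub = calls[(calls["pos"] >= r["start"]) & (calls["pos"] < r["end"])]
            exp = (sub["n_meth"] / (sub["n_meth"] + sub["n_unmeth"])).mean()
            if np.isnan(exp):
                assert np.isnan(got.iloc[i])
            else:
                assert got.iloc[i] == pytest.approx(exp)


class TestQcFilter:
    def test_fgc_pass_and_fail_reasons(self):
        cfg = AnalysisConfig()
        stats = pd.DataFrame(
            [
                # all thresholds met
                dict(map_rate=0.25, conversion=0.995, non_cpg_meth=0.01,
                     n_cpg=2.1e6, global_meth=0.15, cell_class="fgc"),
                # hypermethylated FGC
                dict(map_rate=0.25, conversion=0.995, non_cpg_meth=0.01,
                     n_cpg=2.1e6, global_meth=0.25, cell_class="fgc"),
                # soma exempt from the methylation ceiling
                dict(map_rate=0.25, conversion=0.995, non_cpg_meth=0.01,
                     n_cpg=2.1e6, global_meth=0.67, cell_class="soma"),
            ]
        )
        out = qc_filter(stats, "scbs", cfg)
        assert out["pass"].tolist() == [True, False, True]
        assert out.loc[1, "reasons"] == "fgc_max_meth"

    def test_cool_gch_boundary(self):
        cfg = AnalysisConfig()
        stats = pd.DataFrame(
            [
                dict(map_rate=0.3, n_wcg=2e6, n_gch=9.9e6, global_meth=0.1,
                     cell_class="fgc"),
                dict(map_rate=0.3, n_wcg=2e6, n_gch=1.1e7, global_meth=0.1,
                     cell_class="fgc"),
            ]
        )
        out = qc_filter(stats, "cool", cfg)
        assert out["pass"].tolist() == [False, True]
        assert out.loc[0, "reasons"] == "min_gch"

    def test_missing_stat_fails_with_reason(self):
        cfg = AnalysisConfig()
        stats = pd.DataFrame(
            [dict(map_rate=0.3, conversion=np.nan, non_cpg_meth=0.01,
                  n_cpg=3e6, global_meth=0.1, cell_class="soma")]
        )
        out = qc_filter(stats, "scbs", cfg)
        assert not out["pass"].iloc[0]
        assert "missing" in out["reasons"].iloc[0]
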