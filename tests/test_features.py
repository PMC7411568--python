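"""Window conventions, the overlap engine and feature-table assembly."""

import numpy as np
import pandas as pd
import pytest

import varbuf
from varbuf.features import (
    _distal_windows,
    _overlap_counts_1d,
    count_track_overlaps,
    make_tss_windows,
)
from varbuf.pipeline import generate_fixture
from varbuf.synthetic import DHS_CONDITIONS


def ann(**rows):
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["contig", "strand", "tss"])


class TestWindows:
    def test_plus_strand_convention(self):
        w = make_tss_windows(ann(g=("c", "+", 1000)), 500, 500)
        assert (w.loc["g", "start"], w.loc["g", "end"]) == (499, 1500)

    def test_minus_strand_mirrors(self):
        w = make_tss_windows(ann(g=("c", "-", 1000)), 100, 50)
        # covers 1-based 950..1100
        assert (w.loc["g", "start"], w.loc["g", "end"]) == (949, 1100)

    def test_symmetric_window_strand_independent(self):
        wp = make_tss_windows(ann(g=("c", "+", 777)), 300, 300)
        wm = make_tss_windows(ann(g=("c", "-", 777)), 300, 300)
        pd.testing.assert_frame_equal(wp, wm)

    def test_clipped_at_contig_start(self):
        w = make_tss_windows(ann(g=("c", "+", 10)), 500, 500)
        assert w.loc["g", "start"] == 0


class TestOverlapEngine:
    def test_single_bp_boundary_cases(self):
        w = pd.DataFrame({"contig": ["c"], "start": [499], "end": [1500]},
                         index=["g"])
        inside = pd.DataFrame({"contig": ["c"], "start": [1499], "end": [1600],
                               "condition": ["x"]})
        outside = pd.DataFrame({"contig": ["c"], "start": [1500], "end": [1600],
                                "condition": ["x"]})
        assert count_track_overlaps(inside, w, "count")["g"] == 1
        assert count_track_overlaps(outside, w, "count")["g"] == 0

    def test_hand_enumerated_fixture(self):
        fx = generate_fixture("overlap_enum")
        w = make_tss_windows(fx["annotation.tsv"], 500, 500)
        with pytest.warns(RuntimeWarning, match="skipped"):
            counts = count_track_overlaps(fx["track.bed"], w, "count")
            conds = count_track_overlaps(fx["track.bed"], w, "conditions")
        expected = fx["expected_counts.tsv"]
        assert counts.loc[expected.index].tolist() == expected["count"].tolist()
        assert conds.loc[expected.index].tolist() == expected["conditions"].tolist()

    def test_agrees_with_brute_force_oracle(self):
        gen = np.random.default_rng(0)
        for _ in range(300):
            n_iv, n_w = gen.integers(1, 30, 2)
            istart = gen.integers(0, 500, n_iv)
            iend = istart + gen.integers(1, 80, n_iv)
            wstart = gen.integers(0, 500, n_w)
            wend = wstart + gen.integers(1, 120, n_w)
            fast = _overlap_counts_1d(istart, iend, wstart, wend)
            brute = [
                sum(1 for s, e in zip(istart, iend) if s < we and e > ws)
                for ws, we in zip(wstart, wend)
            ]
            np.testing.assert_array_equal(fast, brute)

    def test_prox_dist_partition_disjoint(self):
        a = ann(g=("c", "+", 50_000), h=("c", "-", 120_000))
        prox = make_tss_windows(a, 500, 500)
        dist = _distal_windows(a)
        for g in a.index:
            p = prox.loc[g]
            for _, d in dist.loc[[g]].iterrows():
                assert d["end"] <= p["start"] or d["start"] >= p["end"]

    def test_interval_600bp_from_tss_is_distal_only(self):
        a = ann(g=("c", "+", 10_000))
        prox = make_tss_windows(a, 500, 500)
        dist = _distal_windows(a)
        trk = pd.DataFrame({"contig": ["c"], "start": [10_599], "end": [10_650],
                            "condition": ["x"]})  # 600 bp downstream of TSS
        assert count_track_overlaps(trk, prox, "count")["g"] == 0
        assert count_track_overlaps(trk, dist, "count")["g"] == 1


class TestDhsSummaries:
    @staticmethod
    def _track(conds, tss=10_000, offset=-100):
        return pd.DataFrame(
            {
                "contig": "c",
                "start": [tss - 1 + offset + 5 * i for i in range(len(conds))],
                "end": [tss - 1 + offset + 5 * i + 30 for i in range(len(conds))],
                "condition": conds,
            }
        )

    def test_profiles_we_only_both_times(self):
        a = ann(g=("c", "+", 10_000))
        out = varbuf.dhs_condition_summaries(
            self._track(["WE_2-4h", "WE_10-12h"]), a, DHS_CONDITIONS
        )
        assert out.loc["g", "dhs_time_profile.prox"] == "both"
        assert out.loc["g", "dhs_tissue_profile.prox"] == "WE_only"
        assert out.loc["g", "num_dhs_conditions.prox"] == 2

    def test_ubiquitous_needs_all_12_sorted_conditions(self):
        a = ann(g=("c", "+", 10_000))
        sorted12 = list(DHS_CONDITIONS.index[DHS_CONDITIONS["sorted12"]])
        assert len(sorted12) == 12
        full = varbuf.dhs_condition_summaries(self._track(sorted12), a, DHS_CONDITIONS)
        partial = varbuf.dhs_condition_summaries(
            self._track(sorted12[:-1]), a, DHS_CONDITIONS
        )
        assert full.loc["g", "dhs_ubiq.prox"] == 1
        assert partial.loc["g", "dhs_ubiq.prox"] == 0

    def test_unknown_condition_is_an_error(self):
        a = ann(g=("c", "+", 10_000))
        with pytest.raises(ValueError, match="vocabulary"):
            varbuf.dhs_condition_summaries(self._track(["nope"]), a, DHS_CONDITIONS)


class TestScalars:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 0.5), ("GGCC", 1.0), ("ANGC", 2 / 3)]
    )
    def test_gc_content(self, seq, expected):
        np.testing.assert_allclose(varbuf.gc_content(seq), expected)

    def test_gc_all_n_is_nan(self):
        assert np.isnan(varbuf.gc_content("NNNN"))

    def test_utr3_variant_index_values(self):
        assert varbuf.utr3_variant_index(0, [], 100) == 0.0
        np.testing.assert_allclose(
            varbuf.utr3_variant_index(4, [0.1, 0.2, 0.3, 0.4], 200), 0.005
        )
        afs7 = [0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35]  # mean 0.2
        np.testing.assert_allclose(
            varbuf.utr3_variant_index(7, afs7, 350), 7 * 0.2 / 350
        )

    def test_zero_width_is_an_error(self):
        with pytest.raises(ValueError, match="positive"):
            varbuf.utr3_variant_index(1, [0.5], 0)


class TestGenomicContext:
    def test_isolated_gene_and_tad_midpoint(self):
        a = pd.DataFrame(
            {"contig": ["c"], "strand": ["+"], "tss": [5_001]}, index=["g"]
        )
        tads = pd.DataFrame({"contig": ["c"], "start": [0], "end": [10_000]},
                            index=["t0"])
        out = varbuf.genomic_context_features(a, tads)
        assert out.loc["g", "num_genes.prox"] == 0
        assert out.loc["g", "dist_to_tad_border"] == 5_000
        assert out.loc["g", "tad_size"] == 10_000

    def test_five_gene_density_enumeration(self):
        tss = {"a": 1_000, "b": 1_800, "c": 2_100, "d": 15_000, "e": 40_000}
        a = pd.DataFrame(
            {"contig": "c", "strand": "+", "tss": list(tss.values())},
            index=list(tss),
        )
        out = varbuf.genomic_context_features(a, pd.DataFrame(
            columns=["contig", "start", "end"]))
        # +-1 kb: a~{b}, b~{a,c}, c~{b}, d~{}, e~{}
        assert out["num_genes.prox"].tolist() == [1, 2, 1, 0, 0]
        # +-20 kb: a,b,c,d mutually (d within 20kb of a/b/c), e isolated... e-d=25kb
        assert out["num_genes.dist"].tolist() == [3, 3, 3, 3, 0]
        assert out["dist_to_tad_border"].isna().all()

    def test_tss_outside_tads_missing_coded(self):
        a = pd.DataFrame({"contig": ["c"], "strand": ["+"], "tss": [50_000]},
                         index=["g"])
        tads = pd.DataFrame({"contig": ["c"], "start": [0], "end": [10_000]},
                            index=["t0"])
        out = varbuf.genomic_context_features(a, tads)
        assert np.isnan(out.loc["g", "dist_to_tad_border"])


class TestAggregationAndAssembly:
    def test_tissue_aggregates(self):
        per_tissue = pd.DataFrame(
            {"t1": [1.0, np.nan], "t2": [3.0, 4.0], "t3": [np.nan, np.nan]},
            index=["g1", "g2"],
        )
        mean = varbuf.aggregate_tissue_features(per_tissue, "mean")
        np.testing.assert_allclose(mean.tolist(), [2.0, 4.0])
        share = varbuf.aggregate_tissue_features(
            pd.DataFrame({"t1": [1, 1], "t2": [0, 0], "t3": [1, np.nan],
                          "t4": [1, np.nan], "t5": [1, np.nan]},
                         index=["g1", "g2"], dtype=float),
            "share_broad",
        )
        np.testing.assert_allclose(share.loc["g1"], 0.8)
        np.testing.assert_allclose(share.loc["g2"], 0.5)

    def test_imputable_zero_fill_and_drop_report(self):
        blocks = {
            "motifs": pd.DataFrame({"motif_x": [1.0, 0.0]}, index=["g1", "g2"]),
            "scalars": pd.DataFrame({"pausing_index": [2.0, 1.0, 5.0]},
                                    index=["g1", "g2", "g3"]),
        }
        table, meta, dropped = varbuf.assemble_feature_table(
            blocks, imputable=["motif_x"]
        )
        assert table.loc["g3", "motif_x"] == 0  # absent from motif block -> 0
        assert "g3" in table.index
        blocks2 = {
            "motifs": pd.DataFrame({"motif_x": [1.0]}, index=["g3"]),
            "scalars": pd.DataFrame({"pausing_index": [2.0, np.nan]},
                                    index=["g3", "g4"]),
        }
        table2, _, dropped2 = varbuf.assemble_feature_table(
            blocks2, imputable=["motif_x"]
        )
        assert "g4" not in table2.index
        assert dropped2["gene_id"].tolist() == ["g4"]
        assert "pausing_index" in dropped2["missing_features"].iloc[0]

    def test_duplicate_feature_names_rejected(self):
        blocks = {
            "a": pd.DataFrame({"x": [1]}, index=["g"]),
            "b": pd.DataFrame({"x": [2]}, index=["g"]),
        }
        with pytest.raises(ValueError, match="duplicate"):
            varbuf.assemble_feature_table(blocks)

    def test_strand_mirror_leaves_window_features_unchanged(self):
        # reverse strand and mirror coordinates around a pivot
        pivot = 100_000
        a_plus = pd.DataFrame({"contig": ["c"], "strand": ["+"], "tss": [20_000]},
                              index=["g"])
        a_minus = pd.DataFrame(
            {"contig": ["c"], "strand": ["-"], "tss": [pivot - 20_000 + 1]},
            index=["g"],
        )
        gen = np.random.default_rng(5)
        start = gen.integers(10_000, 31_000, 40)
        end = start + gen.integers(1, 400, 40)
        track = pd.DataFrame({"contig": "c", "start": start, "end": end,
                              "condition": "x"})
        mirrored = pd.DataFrame(
            {"contig": "c", "start": pivot - end, "end": pivot - start,
             "condition": "x"}
        )
        for up, down in [(500, 500), (300, 200)]:
            wp = make_tss_windows(a_plus, up, down)
            wm = make_tss_windows(a_minus, up, down)
            cp = count_track_overlaps(track, wp, "count")["g"]
            cm = count_track_overlaps(mirrored, wm, "count")["g"]
            assert cp == cm
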