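"""Normalization, summaries, the filtering ladder and LOESS-residual variation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import varbuf
from varbuf.pipeline import generate_fixture
from varbuf.variation import CountMatrix, residual_variation


def _cm(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestNormalize:
    def test_scalar_multiple_samples_recovered(self):
        base = np.array([3.0, 10.0, 40.0, 7.0])
        scalars = np.array([1.0, 2.0, 0.5])
        counts = np.outer(base, scalars)
        sf, norm = varbuf.normalize_counts(_cm(counts))
        ratio = sf.to_numpy() / sf.to_numpy()[0]
        np.testing.assert_allclose(ratio, scalars / scalars[0], rtol=1e-9)
        # normalized matrix is the base profile up to one global constant
        np.testing.assert_allclose(norm.to_numpy() / norm.to_numpy()[:, :1],
                                   1.0, rtol=1e-9)

    def test_identical_samples_give_unit_factors(self):
        counts = np.tile([[4], [9], [1]], (1, 5))
        sf, _ = varbuf.normalize_counts(_cm(counts))
        np.testing.assert_allclose(sf.to_numpy(), 1.0, rtol=1e-12)

    def test_median_of_ratios_hand_oracle(self):
        # counts [[2,4],[8,16],[2,8]]: ratios to gene geometric means are
        # (0.7071, 0.7071, 0.5) and (1.4142, 1.4142, 2.0); medians
        # 1/sqrt(2) and sqrt(2), already geometric-mean 1.
        sf, _ = varbuf.normalize_counts(_cm([[2, 4], [8, 16], [2, 8]]))
        np.testing.assert_allclose(
            sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_no_reference_gene_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            varbuf.normalize_counts(_cm([[0, 5], [5, 0]]))


class TestSummaries:
    def test_hand_cv_values(self):
        s = varbuf.summarize_expression(
            pd.DataFrame([[5, 5, 5], [1, 2, 3]], index=["const", "lin"],
                         columns=list("abc"))
        )
        assert s.loc["const", "cv"] == 0
        np.testing.assert_allclose(s.loc["lin", "cv"], 0.5)  # mean 2, sd 1

    def test_cv_matches_two_pass_oracle(self, small_bundle):
        norm = small_bundle.norms[small_bundle.cfg.focal_timepoint]
        s = varbuf.summarize_expression(norm)
        arr = norm.to_numpy()
        mean = arr.mean(axis=1)
        sd = np.sqrt(((arr - mean[:, None]) ** 2).sum(axis=1) / (arr.shape[1] - 1))
        ok = mean > 0
        np.testing.assert_allclose(s["cv"].to_numpy()[ok], (sd / mean)[ok],
                                   rtol=1e-12)

    def test_zero_mean_gene_flagged(self):
        s = varbuf.summarize_expression(
            pd.DataFrame([[0, 0, 0]], index=["dead"], columns=list("abc"))
        )
        assert bool(s.loc["dead", "cv_undefined"])
        assert np.isnan(s.loc["dead", "cv"])

    def test_too_few_samples_is_an_error(self):
        with pytest.raises(ValueError, match="3 samples"):
            varbuf.summarize_expression(pd.DataFrame([[1, 2]]))


class TestFilterLadder:
    def test_hand_built_fixture_exact(self):
        fx = generate_fixture("filter_ladder")
        summaries = {
            "late": varbuf.summarize_expression(fx["counts_late.tsv"].astype(float)),
            "early": varbuf.summarize_expression(fx["counts_early.tsv"].astype(float)),
        }
        flags = varbuf.filter_genes(summaries, "late", "early",
                                    pct=fx["params"]["pct"])
        retained = sorted(flags.index[flags["retained"]])
        assert retained == sorted(fx["expected_retained.tsv"].index)
        # each exclusion carries the right flag
        assert bool(flags.loc["g00", "zero_median"])
        assert bool(flags.loc["g01", "bottom5"])
        assert bool(flags.loc["g19", "top5"])
        assert bool(flags.loc["g05", "decreasing"])
        assert bool(flags.loc["g10", "decreasing"])
        per_gene_reasons = flags[list(varbuf.variation.FILTER_ORDER)].sum(axis=1)
        assert (per_gene_reasons[~flags["retained"]] == 1).all()

    def test_ladder_order_rules_are_sequential(self):
        # a zero-median gene must not consume a top/bottom-percentile slot
        genes = [f"g{i}" for i in range(21)]
        vals = np.array([0] + list(range(1, 21)), dtype=float)
        counts = pd.DataFrame(np.repeat(vals[:, None], 5, axis=1), index=genes)
        flags = varbuf.filter_genes(
            {"t": varbuf.summarize_expression(counts)}, "t", pct=0.05
        )
        assert bool(flags.loc["g0", "zero_median"]) and not flags.loc["g0", "bottom5"]
        assert flags["bottom5"].sum() == 1 and bool(flags.loc["g1", "bottom5"])

    def test_empty_result_is_an_error(self):
        counts = pd.DataFrame(np.zeros((3, 4)), index=list("abc"))
        with pytest.raises(ValueError, match="every gene"):
            varbuf.filter_genes(
                {"t": varbuf.summarize_expression(counts)}, "t"
            )


class TestResidualVariation:
    def test_smooth_monotone_statistic_fits_perfectly(self):
        x = pd.Series(np.linspace(2, 12, 400))
        stat = pd.Series(2.0 ** (3 - 0.4 * x))  # log2 stat linear in x
        res = residual_variation(x, stat)
        assert np.nanmax(np.abs(res)) < 0.02 * np.log2(stat).std()

    def test_constant_statistic_gives_zero_residuals(self):
        x = pd.Series(np.linspace(1, 10, 200))
        res = residual_variation(x, pd.Series(np.full(200, 3.0)))
        assert np.nanmax(np.abs(res)) < 1e-9

    def test_residuals_are_centered(self, default_bundle):
        r = default_bundle.resid
        assert abs(r.mean()) < 1e-6 * r.std()

    def test_span_and_degree_validation(self):
        x = pd.Series(np.linspace(1, 10, 100))
        y = pd.Series(np.ones(100))
        with pytest.raises(ValueError, match="span"):
            residual_variation(x, y, span=1.5)
        with pytest.raises(ValueError, match="degree"):
            residual_variation(x, y, degree=2)

    def test_alternative_metrics_agree(self, default_bundle):
        s = default_bundle.summary
        both = s[["resid_cv", "resid_sd"]].dropna()
        rho = spearmanr(both["resid_cv"], both["resid_sd"]).statistic
        assert rho >= 0.8

    def test_invariant_to_scaling_one_sample(self, small_bundle):
        cm = small_bundle.data.counts[small_bundle.cfg.focal_timepoint]
        scaled = cm.counts.copy().astype(float)
        scaled.iloc[:, 0] *= 7.0
        genes = small_bundle.retained
        _, n1 = varbuf.normalize_counts(cm.counts)
        _, n2 = varbuf.normalize_counts(scaled)
        r1 = varbuf.expression_summary(n1.loc[genes])["resid_cv"]
        r2 = varbuf.expression_summary(n2.loc[genes])["resid_cv"]
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-9)


class TestSubsampleStability:
    def test_full_size_subset_is_identity(self, small_bundle):
        cm = small_bundle.data.counts[small_bundle.cfg.focal_timepoint]
        out = varbuf.subsample_stability(
            cm, [cm.n_samples], reps=3, seed=0, genes=small_bundle.retained
        )
        np.testing.assert_allclose(out["pearson_r"], 1.0, atol=1e-12)

    def test_record_count_and_seeded_determinism(self, small_bundle):
        cm = small_bundle.data.counts[small_bundle.cfg.focal_timepoint]
        a = varbuf.subsample_stability(cm, [5, 10], reps=4, seed=9,
                                       genes=small_bundle.retained)
        b = varbuf.subsample_stability(cm, [5, 10], reps=4, seed=9,
                                       genes=small_bundle.retained)
        assert len(a) == 8
        pd.testing.assert_frame_equal(a, b)

    def test_size_below_three_is_an_error(self, small_bundle):
        cm = small_bundle.data.counts[small_bundle.cfg.focal_timepoint]
        with pytest.raises(ValueError, match="at least 3"):
            varbuf.subsample_stability(cm, [2], reps=1, seed=0)


class TestNeighborCorrelation:
    @staticmethod
    def _toy_annotation(n=600, seed=0):
        gen = np.random.default_rng(seed)
        tss = np.sort(gen.integers(1, 3_000_000, n))
        ann = pd.DataFrame(
            {"contig": "chr1", "strand": "+", "tss": tss},
            index=[f"g{i:04d}" for i in range(n)],
        )
        starts = np.arange(0, 3_000_000, 200_000)
        tads = pd.DataFrame(
            {"contig": "chr1", "start": starts, "end": starts + 200_000},
            index=[f"tad{i}" for i in range(len(starts))],
        )
        return ann, tads

    def test_iid_values_uncorrelated(self):
        ann, tads = self._toy_annotation(n=2500, seed=1)
        vals = pd.Series(np.random.default_rng(2).normal(size=len(ann)),
                         index=ann.index)
        out = varbuf.neighbor_pair_correlation(vals, ann, tads)
        big = out[out["n_pairs"] >= 200]
        assert (big["spearman_rho"].abs() < 0.1).all()

    def test_duplicated_neighbors_correlate_in_nearest_bin(self):
        # tight gene pairs (200 bp apart) with duplicated values, pair
        # centres 70 kb apart: the nearest-distance bin holds exactly the
        # within-pair pairs and must correlate perfectly
        n_pairs = 300
        centres = 50_000 + np.arange(n_pairs) * 150_000  # pairs out of range
        gaps = 100 + 37 * (np.arange(n_pairs) % 40)  # varied within-pair dist
        tss = np.sort(np.concatenate([centres, centres + gaps]))
        ann = pd.DataFrame(
            {"contig": "chr1", "strand": "+", "tss": tss},
            index=[f"g{i:04d}" for i in range(2 * n_pairs)],
        )
        starts = np.arange(0, tss.max() + 200_000, 200_000)
        tads = pd.DataFrame(
            {"contig": "chr1", "start": starts, "end": starts + 200_000},
            index=[f"tad{i}" for i in range(len(starts))],
        )
        gen = np.random.default_rng(4)
        pair_vals = gen.normal(size=n_pairs)
        vals = pd.Series(np.repeat(pair_vals, 2), index=ann.index)
        out = varbuf.neighbor_pair_correlation(vals, ann, tads)
        nearest = out[out["dist_bin"] == 0].dropna(subset=["spearman_rho"])
        assert nearest["spearman_rho"].max() > 0.99

    def test_tad_block_correlation_separates_same_vs_different(self):
        ann, tads = self._toy_annotation(n=2500, seed=5)
        gen = np.random.default_rng(6)
        # shared TAD component with block correlation 0.5
        from varbuf.variation import _assign_tads

        tad_of = _assign_tads(ann, tads)
        shared = pd.Series(gen.normal(size=len(tads)), index=tads.index)
        vals = np.sqrt(0.5) * tad_of.map(shared).astype(float) + np.sqrt(0.5) * gen.normal(
            size=len(ann)
        )
        out = varbuf.neighbor_pair_correlation(pd.Series(vals.to_numpy(),
                                                         index=ann.index), ann, tads)
        pivot = out.pivot(index="dist_bin", columns="same_tad",
                          values="spearman_rho").dropna()
        assert (pivot[True] > pivot[False]).all()

    def test_small_cells_reported_undefined(self):
        ann, tads = self._toy_annotation(n=40, seed=7)
        vals = pd.Series(np.random.default_rng(8).normal(size=len(ann)),
                         index=ann.index)
        out = varbuf.neighbor_pair_correlation(vals, ann, tads, min_pairs=10**6)
        assert out["spearman_rho"].isna().all()
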