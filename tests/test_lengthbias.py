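import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import make_matrix
from oracle_utils import polyA_runs_oracle, polyA_windows_oracle, quantile_oracle
from nucdist.genes import GeneModel, GeneModelSet
from nucdist.lengthbias import (
    bin_by_length,
    bin_summary,
    gene_lengths,
    gene_polyA_max,
    length_bias_analysis,
    log_length_correlation,
    polyA_nmer_count,
    total_gene_counts,
    trend_curve,
)
from nucdist.synthetic import (
    SimAnnotationConfig,
    simulate_annotation,
    simulate_length_bias_totals,
)


class TestGeneLengths:
    def test_two_exon_transcript(self, toy_models):
        out = gene_lengths(toy_models)
        assert out.loc["geneA", "preandmrna_length"] == 9
        assert out.loc["geneA", "transcript_length"] == 6

    def test_single_exon_lengths_equal(self):
        gene = GeneModel("chr1", "+")
        gene.transcripts["t"] = [(5, 25)]
        out = gene_lengths(GeneModelSet({"g": gene}))
        assert out.loc["g", "preandmrna_length"] == out.loc["g", "transcript_length"] == 20

    def test_max_over_isoforms(self):
        gene = GeneModel("chr1", "+")
        gene.transcripts["short"] = [(0, 3), (6, 9)]  # spliced 6
        gene.transcripts["long"] = [(0, 8)]  # spliced 8
        out = gene_lengths(GeneModelSet({"g": gene}))
        assert out.loc["g", "transcript_length"] == 8
        assert out.loc["g", "preandmrna_length"] == 9


class TestTotals:
    def test_row_sums(self):
        out = total_gene_counts(make_matrix([[1, 2], [0, 0]]))
        assert out.tolist() == [3, 0]

    def test_permuting_cells_invariant(self):
        m = make_matrix([[1, 2, 3], [4, 0, 1]])
        mp = m.select_cells([2, 0, 1])
        assert total_gene_counts(m).tolist() == total_gene_counts(mp).tolist()


class TestBinning:
    def test_one_gene_per_bin(self):
        lengths = pd.Series(np.arange(10, 0, -1), index=[f"g{i}" for i in range(10)])
        bins = bin_by_length(lengths, 10)
        # shortest gene (g9, length 1) lands in bin 1
        assert bins["g9"] == 1
        assert bins["g0"] == 10

    def test_sizes_differ_by_at_most_one(self):
        lengths = pd.Series(np.arange(11), index=[f"g{i:02d}" for i in range(11)])
        sizes = bin_by_length(lengths, 10).value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 11

    def test_ties_broken_by_gene_id(self):
        lengths = pd.Series([5, 5, 5, 5], index=["d", "b", "a", "c"])
        bins = bin_by_length(lengths, 2)
        assert bins.sort_index().tolist() == [1, 1, 2, 2]

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            bin_by_length(pd.Series([1.0, 2.0], index=["a", "b"]), 3)


class TestBinSummary:
    def test_linear_interpolation_quantiles(self):
        totals = pd.Series([1, 2, 3], index=list("abc"))
        bins = pd.Series([1, 1, 1], index=list("abc"))
        out = bin_summary(totals, bins)
        assert out.loc[0, "median"] == 2
        assert out.loc[0, "q25"] == 1.5
        assert out.loc[0, "q75"] == 2.5

    def test_constant_bin(self):
        totals = pd.Series([7, 7, 7], index=list("abc"))
        bins = pd.Series([1, 1, 1], index=list("abc"))
        out = bin_summary(totals, bins)
        assert out.loc[0, ["median", "q25", "q75"]].tolist() == [7, 7, 7]

    def test_outlier_moves_q75_not_median(self):
        # with type-7 quantiles on n=4, q75 interpolates into the top rank
        base = [10, 11, 12, 13]
        with_outlier = base[:-1] + [10_000]
        idx = list("abcd")
        out_a = bin_summary(pd.Series(base, index=idx), pd.Series(1, index=idx))
        out_b = bin_summary(
            pd.Series(with_outlier, index=idx), pd.Series(1, index=idx)
        )
        assert out_a.loc[0, "median"] == out_b.loc[0, "median"]
        assert out_b.loc[0, "q75"] > out_a.loc[0, "q75"]

    def test_matches_brute_force_order_statistics(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 1000, 37)
        idx = [f"g{i}" for i in range(37)]
        out = bin_summary(
            pd.Series(vals, index=idx), pd.Series(1, index=idx)
        )
        assert out.loc[0, "median"] == pytest.approx(quantile_oracle(vals, 0.5))
        assert out.loc[0, "q25"] == pytest.approx(quantile_oracle(vals, 0.25))
        assert out.loc[0, "q75"] == pytest.approx(quantile_oracle(vals, 0.75))

    def test_invariant_to_within_bin_ordering(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 100, 20)
        idx = [f"g{i}" for i in range(20)]
        bins = pd.Series(rng.integers(1, 4, 20), index=idx)
        totals = pd.Series(vals, index=idx)
        perm = rng.permutation(20)
        out_a = bin_summary(totals, bins)
        out_b = bin_summary(totals.iloc[perm], bins.iloc[perm])
        pd.testing.assert_frame_equal(out_a, out_b)


class TestPolyACounting:
    @pytest.mark.parametrize(
        "seq,n,runs,windows",
        [
            ("AAAA", 4, 1, 1),
            ("AAACAAAA", 4, 1, 1),
            ("AAAAAAAA", 4, 1, 5),  # one maximal run vs 5 sliding windows
            ("CGCGCG", 2, 0, 0),
            ("AAcAA", 2, 2, 2),  # case-insensitive
        ],
    )
    def test_conventions(self, seq, n, runs, windows):
        assert polyA_nmer_count(seq, n, "runs") == runs
        assert polyA_nmer_count(seq, n, "windows") == windows

    @given(st.text(alphabet="ACGT", min_size=0, max_size=120), st.sampled_from([2, 4, 6, 8]))
    def test_matches_character_scan_oracle(self, seq, n):
        assert polyA_nmer_count(seq, n, "runs") == polyA_runs_oracle(seq, n)
        assert polyA_nmer_count(seq, n, "windows") == polyA_windows_oracle(seq, n)

    def test_invalid(self):
        with pytest.raises(ValueError):
            polyA_nmer_count("AAAA", 0)
        with pytest.raises(ValueError):
            polyA_nmer_count("AAAA", 2, "zigzag")


class TestGenePolyAMax:
    def test_intronic_run_only_in_unspliced(self):
        gene = GeneModel("chr1", "+")
        gene.transcripts["t"] = [(0, 3), (11, 14)]
        genome = {"chr1": "CGTAAAAAAAAGTC"}  # run of 8 A inside the intron
        out = gene_polyA_max(GeneModelSet({"g": gene}), genome, 8)
        assert out["g"] == 1

    def test_no_runs_anywhere(self):
        gene = GeneModel("chr1", "+")
        gene.transcripts["t"] = [(0, 6)]
        out = gene_polyA_max(GeneModelSet({"g": gene}), {"chr1": "CGTCGT"}, 6)
        assert out["g"] == 0

    def test_splice_junction_creates_run_absent_from_unspliced(self):
        # exons AAA + AAA joined by splicing -> run of 6 in the spliced
        # transcript only; gene max takes the larger of the two
        gene = GeneModel("chr1", "+")
        gene.transcripts["t"] = [(0, 3), (6, 9)]
        genome = {"chr1": "AAACCCAAA"}
        models = GeneModelSet({"g": gene})
        assert gene_polyA_max(models, genome, 6)["g"] == 1
        # unspliced alone has no 6-run
        from nucdist.reference import unspliced_transcript_sequences

        uns = unspliced_transcript_sequences(models, genome).entries[0]
        assert polyA_nmer_count(uns.sequence, 6) == 0


class TestLogLengthCorrelation:
    def test_proportional_gives_r_one(self):
        lengths = np.array([10, 100, 1000, 10_000])
        assert log_length_correlation(lengths * 3, lengths).r == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(6)
        lengths = 10 ** rng.uniform(2, 6, 2000)
        totals = rng.permutation(np.round(lengths)).astype(int) + 1
        assert abs(log_length_correlation(totals, lengths).r) < 0.1

    def test_zero_total_genes_excluded_and_counted(self):
        out = log_length_correlation([10, 0, 20, 40], [100, 200, 300, 400])
        assert out.n_used == 3
        assert out.n_excluded == 1

    def test_too_few_usable_genes(self):
        with pytest.raises(ValueError, match="positive totals"):
            log_length_correlation([1, 0, 0], [10, 20, 30])


class TestTrendCurve:
    def test_reproduces_exact_line(self):
        x = np.linspace(0, 5, 60)
        y = 2.0 + 0.7 * x
        grid, fitted = trend_curve(x, y)
        np.testing.assert_allclose(fitted, 2.0 + 0.7 * grid, atol=1e-6)

    def test_constant_y(self):
        x = np.linspace(0, 5, 30)
        _, fitted = trend_curve(x, np.full(30, 3.0))
        np.testing.assert_allclose(fitted, 3.0, atol=1e-9)

    def test_tracks_true_mean_function(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 4, 1500)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.2, 1500)
        grid, fitted = trend_curve(x, y, span=0.4)
        interior = (grid > 0.5) & (grid < 3.5)
        np.testing.assert_allclose(
            fitted[interior], 1.0 + 0.5 * grid[interior], atol=0.05
        )

    def test_invalid_span_and_size(self):
        x = np.linspace(0, 1, 20)
        with pytest.raises(ValueError, match="span"):
            trend_curve(x, x, span=1.5)
        with pytest.raises(ValueError, match="10 points"):
            trend_curve(x[:5], x[:5])


class TestStratifiedTrends:
    @staticmethod
    def _grouped_trends(df, bonus_log10):
        totals = df["total"].to_numpy(dtype=float)
        rng = np.random.default_rng(0)
        has_polya = rng.random(len(df)) < 0.5
        totals = np.where(has_polya, totals * 10**bonus_log10, totals)
        keep = totals > 0
        x = np.log10(df["length"].to_numpy(dtype=float))[keep]
        y = np.log10(totals[keep])
        flag = has_polya[keep]
        lo = max(x[flag].min(), x[~flag].min()) + 0.2
        hi = min(x[flag].max(), x[~flag].max()) - 0.2
        grid = np.linspace(lo, hi, 25)
        _, f_yes = trend_curve(x[flag], y[flag], grid=grid)
        _, f_no = trend_curve(x[~flag], y[~flag], grid=grid)
        return f_yes, f_no

    def test_injected_polya_bonus_lifts_trend(self):
        df = simulate_length_bias_totals(2000, beta=0.5, sigma=0.3, seed=8)
        f_yes, f_no = self._grouped_trends(df, bonus_log10=0.5)
        assert np.all(f_yes > f_no)

    def test_no_effect_trends_coincide(self):
        df = simulate_length_bias_totals(2000, beta=0.5, sigma=0.3, seed=8)
        f_yes, f_no = self._grouped_trends(df, bonus_log10=0.0)
        assert np.max(np.abs(f_yes - f_no)) < 0.1

    def test_residual_bias_in_nonpolya_subgroup(self):
        """With the length effect applied to all genes, the subgroup
        without poly-A still shows a clearly positive correlation."""
        df = simulate_length_bias_totals(2000, beta=0.5, sigma=0.3, seed=9)
        rng = np.random.default_rng(1)
        non_polya = df[rng.random(len(df)) < 0.5]
        out = log_length_correlation(non_polya["total"], non_polya["length"])
        assert out.r > 0.5


def test_length_bias_analysis_end_to_end():
    models, genome = simulate_annotation(
        SimAnnotationConfig(
            n_genes=60, exons_per_gene=(1, 4), polyA_insert_prob=0.5,
            polyA_run_length=8, seed=10,
        )
    )
    rng = np.random.default_rng(2)
    gene_ids = sorted(models.genes)
    counts = rng.poisson(5.0, size=(len(gene_ids), 20))
    m = make_matrix(counts, gene_ids=gene_ids)
    result = length_bias_analysis(m, models, genome, nmer=8, n_bins=5)
    assert len(result.per_gene) == 60
    assert (
        result.per_gene["preandmrna_length"]
        >= result.per_gene["transcript_length"]
    ).all()
    assert result.per_bin["n_genes"].sum() == 60
    assert (result.per_bin["q25"] <= result.per_bin["median"]).all()
    assert (result.per_bin["median"] <= result.per_bin["q75"]).all()
    assert result.per_gene["has_polyA"].any()
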