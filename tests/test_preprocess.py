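"""Filtering, z-scoring, iTRAQ normalization and down-shifted imputation."""

import numpy as np
import pandas as pd
import pytest

from protstrat import io, preprocess
from protstrat.containers import ProteinMatrix
from protstrat.errors import ConfigError, FormatError
from protstrat.preprocess import (FilterParams, ImputationParams,
                                  average_replicates, default_plasma_proteins,
                                  filter_min_valid, filter_replicates,
                                  impute_downshifted, normalize_itraq,
                                  remove_flagged, remove_plasma_proteins,
                                  zscore)

from conftest import toy_matrix


def meta_frame(lines, replicates):
    rows = []
    for line in lines:
        for r in range(1, replicates + 1):
            rows.append({"sample": f"{line}_R{r}", "line": line,
                         "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


class TestIO:
    def test_zero_intensity_becomes_missing(self, tmp_path):
        path = tmp_path / "pg.tsv"
        path.write_text("Protein IDs\tLFQ intensity A\tLFQ intensity B\n"
                        "P1\t0\t1024\n")
        matrix = io.read_protein_groups(path)
        assert np.isnan(matrix.values.loc["P1", "A"])
        assert matrix.values.loc["P1", "B"] == pytest.approx(10.0)

    def test_flag_columns_parsed(self, tmp_path):
        path = tmp_path / "pg.tsv"
        path.write_text(
            "Protein IDs\tLFQ intensity A\tReverse\t"
            "Only identified by site\tPotential contaminant\n"
            "P1\t100\t+\t\t\nP2\t100\t\t+\t\nP3\t100\t\t\t+\nP4\t100\t\t\t\n")
        matrix = io.read_protein_groups(path)
        assert matrix.flags.loc["P1", "reverse"]
        assert matrix.flags.loc["P2", "only_by_site"]
        assert matrix.flags.loc["P3", "contaminant"]
        assert not matrix.flags.loc["P4"].any()

    def test_missing_required_column_named(self, tmp_path):
        path = tmp_path / "pg.tsv"
        path.write_text("ids\tLFQ intensity A\nP1\t1\n")
        with pytest.raises(FormatError, match="Protein IDs"):
            io.read_protein_groups(path)

    def test_round_trip_preserves_matrix_and_mask(self, tmp_path, small_panel):
        matrix = small_panel["matrix"]
        path = tmp_path / "pg.tsv"
        io.write_protein_groups(matrix, path)
        back = io.read_protein_groups(path)
        pd.testing.assert_frame_equal(back.mask, matrix.mask)
        np.testing.assert_allclose(back.values.to_numpy(),
                                   matrix.values.to_numpy(), rtol=1e-12)
        pd.testing.assert_frame_equal(back.flags, matrix.flags)

    def test_gmt_round_trip(self, tmp_path, small_panel):
        path = tmp_path / "ann.gmt"
        io.write_gmt(small_panel["annotations"], path)
        assert io.read_gmt(path) == small_panel["annotations"]


class TestRemoveFlagged:
    def test_drops_flagged_rows(self):
        matrix = toy_matrix(np.ones((4, 2)))
        matrix.flags.loc["P0", "reverse"] = True
        matrix.flags.loc["P1", "only_by_site"] = True
        out = remove_flagged(matrix)
        assert list(out.proteins) == ["P2", "P3"]

    def test_contaminants_separable(self):
        matrix = toy_matrix(np.ones((2, 2)))
        matrix.flags.loc["P0", "contaminant"] = True
        assert remove_flagged(matrix).n_proteins == 1
        assert remove_flagged(matrix, remove_contaminants=False).n_proteins == 2

    def test_identity_without_flags(self):
        matrix = toy_matrix(np.ones((3, 2)))
        assert remove_flagged(matrix).n_proteins == 3


class TestFilterReplicates:
    def test_single_replicate_rows_dropped(self):
        meta = meta_frame(["L1", "L2"], 3)
        values = np.full((2, 6), np.nan)
        values[0, 0] = 10.0   # P0 seen once in L1 only
        values[1, :] = 10.0   # P1 complete
        matrix = toy_matrix(values, samples=list(meta.index))
        out = filter_replicates(matrix, meta, min_quantified=2)
        assert list(out.proteins) == ["P1"]

    def test_fully_observed_unchanged(self):
        meta = meta_frame(["L1"], 3)
        matrix = toy_matrix([[1.0, 2.0, 3.0]], samples=list(meta.index))
        out = filter_replicates(matrix, meta)
        pd.testing.assert_frame_equal(out.values, matrix.values)

    def test_matches_bruteforce_per_line_rule(self):
        rng = np.random.default_rng(4)
        meta = meta_frame(["L1", "L2", "L3"], 3)
        values = rng.normal(20, 2, size=(40, 9))
        values[rng.random(values.shape) < 0.5] = np.nan
        matrix = toy_matrix(values, samples=list(meta.index))
        out = filter_replicates(matrix, meta, min_quantified=2)

        expected = values.copy()
        for j0 in (0, 3, 6):
            block = expected[:, j0:j0 + 3]
            fail = np.isfinite(block).sum(axis=1) < 2
            block[fail] = np.nan
        keep = np.isfinite(expected).any(axis=1)
        np.testing.assert_array_equal(
            out.values.to_numpy(), expected[keep])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        meta = meta_frame(["L1", "L2"], 3)
        values = rng.normal(20, 2, size=(30, 6))
        values[rng.random(values.shape) < 0.4] = np.nan
        matrix = toy_matrix(values, samples=list(meta.index))
        once = filter_replicates(matrix, meta)
        twice = filter_replicates(once, meta)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestAverageReplicates:
    def test_mean_over_observed(self):
        meta = meta_frame(["L1"], 3)
        matrix = toy_matrix([[10.0, 12.0, np.nan]], samples=list(meta.index))
        out, line_meta = average_replicates(matrix, meta)
        assert out.values.loc["P0", "L1"] == pytest.approx(11.0)
        assert list(line_meta.index) == ["L1"]

    def test_all_missing_stays_missing(self):
        meta = meta_frame(["L1", "L2"], 2)
        values = [[np.nan, np.nan, 4.0, 6.0]]
        out, _ = average_replicates(toy_matrix(values,
                                               samples=list(meta.index)), meta)
        assert np.isnan(out.values.loc["P0", "L1"])
        assert out.values.loc["P0", "L2"] == pytest.approx(5.0)

    def test_matches_bruteforce_masked_mean(self):
        rng = np.random.default_rng(6)
        meta = meta_frame(["L1", "L2", "L3"], 3)
        values = rng.normal(20, 2, size=(25, 9))
        values[rng.random(values.shape) < 0.3] = np.nan
        out, _ = average_replicates(toy_matrix(values,
                                               samples=list(meta.index)), meta)
        expected = np.column_stack([
            np.nanmean(values[:, j0:j0 + 3], axis=1) for j0 in (0, 3, 6)])
        np.testing.assert_allclose(out.values.to_numpy(), expected)


class TestFilterMinValid:
    def test_threshold_is_inclusive(self):
        values = np.full((2, 12), np.nan)
        values[0, :9] = 1.0   # 9 valid -> dropped at n=10
        values[1, :10] = 1.0  # 10 valid -> kept
        out = filter_min_valid(toy_matrix(values), 10)
        assert list(out.proteins) == ["P1"]

    def test_zero_threshold_is_identity(self):
        matrix = toy_matrix(np.ones((3, 4)))
        assert filter_min_valid(matrix, 0).n_proteins == 3

    def test_threshold_above_columns_rejected(self):
        with pytest.raises(ConfigError):
            filter_min_valid(toy_matrix(np.ones((2, 3))), 4)


class TestPlasmaRemoval:
    def test_empty_set_is_identity(self):
        matrix = toy_matrix(np.ones((3, 2)))
        assert remove_plasma_proteins(matrix, set()).n_proteins == 3

    def test_listed_ids_dropped_including_group_members(self):
        matrix = toy_matrix(np.ones((3, 2)),
                            proteins=["ALB", "KRT7;ALB", "KRT7"])
        out = remove_plasma_proteins(matrix, {"ALB"})
        assert list(out.proteins) == ["KRT7"]

    def test_packaged_list_has_about_200_entries(self):
        plasma = default_plasma_proteins()
        assert 180 <= len(plasma) <= 260
        assert "ALB" in plasma


class TestZscore:
    def test_row_closed_form(self):
        out = zscore(toy_matrix([[1.0, 2.0, 3.0]]), by="rows")
        np.testing.assert_allclose(out.values.to_numpy(),
                                   [[-1.0, 0.0, 1.0]])  # SD uses n-1

    def test_constant_row_becomes_zeros(self):
        out = zscore(toy_matrix([[5.0, 5.0, 5.0]]), by="rows")
        np.testing.assert_allclose(out.values.to_numpy(), [[0.0, 0.0, 0.0]])

    def test_columns_mode(self):
        out = zscore(toy_matrix([[1.0], [2.0], [3.0]]), by="columns")
        np.testing.assert_allclose(out.values.to_numpy().ravel(),
                                   [-1.0, 0.0, 1.0])

    def test_groupwise_cohorts_standardized_separately(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(20, 6))
        values[:, 3:] += 5.0  # cohort offset
        matrix = toy_matrix(values)
        cohorts = pd.Series(["LFQ"] * 3 + ["ITRAQ"] * 3,
                            index=matrix.samples)
        out = zscore(matrix, by="rows", groups=cohorts)
        np.testing.assert_allclose(
            out.values.iloc[:, :3].mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(
            out.values.iloc[:, 3:].mean(axis=1), 0.0, atol=1e-12)


class TestNormalizeItraq:
    def test_column_equal_to_control_gives_zeros(self):
        reporter = pd.DataFrame({"117": [100.0, 200.0],
                                 "S1": [100.0, 200.0]})
        out = normalize_itraq(reporter, "117")
        np.testing.assert_allclose(out.values["S1"].to_numpy(), 0.0,
                                   atol=1e-12)

    def test_output_columns_have_zero_median(self):
        rng = np.random.default_rng(8)
        reporter = pd.DataFrame(rng.uniform(10, 1000, size=(51, 4)),
                                columns=["117", "S1", "S2", "S3"])
        out = normalize_itraq(reporter, "117")
        np.testing.assert_allclose(out.values.median(axis=0), 0.0, atol=1e-12)

    def test_matches_bruteforce_subtraction(self):
        rng = np.random.default_rng(9)
        reporter = pd.DataFrame(rng.uniform(10, 1000, size=(20, 3)),
                                columns=["117", "S1", "S2"])
        out = normalize_itraq(reporter, "117")
        expected = np.log2(reporter[["S1", "S2"]].to_numpy()) \
            - np.log2(reporter[["117"]].to_numpy())
        expected -= np.median(expected, axis=0, keepdims=True)
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_absent_control_channel_rejected(self):
        with pytest.raises(FormatError):
            normalize_itraq(pd.DataFrame({"S1": [1.0]}), "117")


class TestImputation:
    def test_no_missing_is_identity(self):
        matrix = toy_matrix(np.ones((3, 4)) * 20)
        out = impute_downshifted(matrix, ImputationParams(seed=0))
        pd.testing.assert_frame_equal(out.values, matrix.values)

    def test_observed_entries_never_altered(self, small_panel):
        matrix = small_panel["matrix"]
        out = impute_downshifted(matrix, ImputationParams(seed=1))
        mask = matrix.mask.to_numpy()
        np.testing.assert_array_equal(out.values.to_numpy()[mask],
                                      matrix.values.to_numpy()[mask])
        assert not out.values.isna().any().any()

    def test_deterministic_under_seed(self, small_panel):
        matrix = small_panel["matrix"]
        a = impute_downshifted(matrix, ImputationParams(seed=3))
        b = impute_downshifted(matrix, ImputationParams(seed=3))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_downshift_and_width_match_stated_parameters(self):
        """Imputed draws follow Normal(mu - 1.8 sd, (0.15 sd)^2)."""
        rng = np.random.default_rng(10)
        n = 20000
        col = np.concatenate([rng.normal(20.0, 1.0, n), np.full(n, np.nan)])
        matrix = toy_matrix(col[:, None], samples=["A"])
        observed = matrix.values["A"].dropna()
        mu, sd = observed.mean(), observed.std(ddof=1)
        out = impute_downshifted(matrix, ImputationParams(seed=2))
        drawn = out.values["A"].to_numpy()[n:]
        se_mean = 0.15 * sd / np.sqrt(n)
        assert abs(drawn.mean() - (mu - 1.8 * sd)) < 3 * se_mean
        assert abs(drawn.std(ddof=1) - 0.15 * sd) / (0.15 * sd) < 0.05

    def test_degenerate_limit_returns_column_mean(self):
        col = np.array([10.0, 12.0, np.nan])
        matrix = toy_matrix(col[:, None], samples=["A"])
        out = impute_downshifted(matrix, ImputationParams(
            width=1e-9, down_shift=0.0, seed=0))
        assert out.values.loc["P2", "A"] == pytest.approx(11.0, abs=1e-6)

    def test_column_with_too_few_observed_skipped(self):
        col = np.array([10.0, np.nan, np.nan])
        matrix = toy_matrix(col[:, None], samples=["A"])
        out = impute_downshifted(matrix, ImputationParams(seed=0))
        assert out.values["A"].isna().sum() == 2
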