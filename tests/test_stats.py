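"""Tests for group summaries, comparisons, bootstrap and reporting."""

import numpy as np
import pandas as pd
import pytest

import pulsetrace as pt
from _oracles import rank_sum_permutation_p, rank_sum_u


def _profiles_frame(rows):
    defaults = {
        "cell_id": "c", "subset": "HEC", "side": "ventral", "n_frames": 20,
        "n_peaks": 0, "peaks_per_10_frames": 0.0, "mean_mfi_3_12": 40.0,
        "max_peak_mfi": np.nan, "max_fold_amplitude": np.nan,
        "high_amplitude": False, "periods_h": "",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestSummarizeByGroup:
    def test_single_cell_group(self):
        df = _profiles_frame([{"cell_id": "a", "mean_mfi_3_12": 42.0}])
        summary, _ = pt.summarize_by_group(df)
        row = summary.iloc[0]
        assert row["n_cells"] == 1
        assert row["mean_mfi_3_12_mean"] == 42.0
        assert np.isnan(row["mean_mfi_3_12_sd"])

    def test_two_identical_cells_zero_dispersion(self):
        df = _profiles_frame(
            [{"cell_id": "a", "mean_mfi_3_12": 42.0}, {"cell_id": "b", "mean_mfi_3_12": 42.0}]
        )
        summary, _ = pt.summarize_by_group(df)
        assert summary.iloc[0]["mean_mfi_3_12_sd"] == 0.0

    def test_row_order_invariance(self, default_cohort):
        kept, _ = pt.filter_tracks(default_cohort.traces)
        df = pt.profiles_to_frame([pt.profile_cell(t) for t in kept])
        shuffled = df.sample(frac=1.0, random_state=0)
        a, fa = pt.summarize_by_group(df, ["subset", "side"])
        b, fb = pt.summarize_by_group(shuffled, ["subset", "side"])
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(fa, fb)

    def test_period_fractions_sum_to_one(self):
        df = _profiles_frame(
            [
                {"cell_id": "a", "n_peaks": 3, "periods_h": "1.0;2.0"},
                {"cell_id": "b", "n_peaks": 2, "periods_h": "2.2"},
                {"cell_id": "c", "subset": "BC", "n_peaks": 2, "periods_h": "3.0"},
                {"cell_id": "d", "n_peaks": 1, "periods_h": ""},  # excluded
            ]
        )
        _, fractions = pt.summarize_by_group(df)
        frac_cols = [c for c in fractions.columns if c.startswith("frac_")]
        sums = fractions[frac_cols].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)
        hec = fractions[fractions.subset == "HEC"].iloc[0]
        assert hec["n_cells"] == 2  # only cells with >= 2 peaks contribute

    def test_simulated_bc_has_more_short_periods_than_hec(self, default_cohort):
        # detection-side analog of the prior ordering: BCs pulse faster
        kept, _ = pt.filter_tracks(default_cohort.traces)
        profiles = [pt.profile_cell(t) for t in kept]
        df = pt.profiles_to_frame(profiles)
        _, fractions = pt.summarize_by_group(df)
        fractions = fractions.set_index("subset")
        short = fractions.get("frac_1h", 0) + fractions.get("frac_2h", 0)
        assert short.loc["BC"] > short.loc["HEC"]

    def test_unknown_grouping_key_raises(self):
        with pytest.raises(KeyError):
            pt.summarize_by_group(_profiles_frame([{}]), ["genotype"])


class TestCompareGroups:
    def test_identical_groups_adjusted_p_is_one(self):
        rows = []
        for subset in ("HEC", "BC", "IAHC"):
            for i, v in enumerate([1.0, 1.0, 2.0, 2.0]):
                rows.append(
                    {"cell_id": f"{subset}{i}", "subset": subset, "peaks_per_10_frames": v}
                )
        res = pt.compare_groups(
            _profiles_frame(rows), "peaks_per_10_frames", method="rank_sum"
        )
        assert (res.pairwise["p_bonf"] == 1.0).all()

    def test_rank_sum_statistic_and_p_match_permutation_oracle(self):
        rows = [
            {"cell_id": f"a{i}", "subset": "HEC", "mean_mfi_3_12": v}
            for i, v in enumerate([1.0, 2.0, 3.0])
        ] + [
            {"cell_id": f"b{i}", "subset": "BC", "mean_mfi_3_12": v}
            for i, v in enumerate([4.0, 5.0, 6.0])
        ]
        res = pt.compare_groups(_profiles_frame(rows), "mean_mfi_3_12")
        pair = res.pairwise.iloc[0]
        a, b = [4.0, 5.0, 6.0], [1.0, 2.0, 3.0]  # groups sorted: BC before HEC
        assert pair["statistic"] == rank_sum_u(a, b)
        assert pair["p_raw"] == pytest.approx(rank_sum_permutation_p(a, b))

    @pytest.mark.parametrize("seed", range(5))
    def test_rank_sum_p_matches_oracle_on_random_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 8, 2)
        a = rng.normal(0, 1, n1)
        b = rng.normal(0.5, 1, n2)
        rows = [
            {"cell_id": f"a{i}", "subset": "BC", "mean_mfi_3_12": v}
            for i, v in enumerate(a)
        ] + [
            {"cell_id": f"b{i}", "subset": "HEC", "mean_mfi_3_12": v}
            for i, v in enumerate(b)
        ]
        res = pt.compare_groups(_profiles_frame(rows), "mean_mfi_3_12")
        pair = res.pairwise.iloc[0]
        assert pair["p_raw"] == pytest.approx(
            rank_sum_permutation_p(list(a), list(b)), abs=1e-9
        )

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(0)
        rows = []
        for subset in ("HEC", "BC", "IAHC"):
            for i in range(5):
                rows.append(
                    {
                        "cell_id": f"{subset}{i}", "subset": subset,
                        "mean_mfi_3_12": float(rng.normal(40, 5)),
                    }
                )
        res = pt.compare_groups(
            _profiles_frame(rows), "mean_mfi_3_12", method="anova_bonferroni"
        )
        assert len(res.pairwise) == 3
        for _, row in res.pairwise.iterrows():
            assert row["p_bonf"] == pytest.approx(min(row["p_raw"] * 3, 1.0))

    def test_insufficient_observations_is_explicit_error(self):
        rows = [
            {"cell_id": "a", "subset": "HEC", "mean_mfi_3_12": 1.0},
            {"cell_id": "b", "subset": "BC", "mean_mfi_3_12": 2.0},
            {"cell_id": "c", "subset": "BC", "mean_mfi_3_12": 3.0},
        ]
        with pytest.raises(ValueError, match="HEC"):
            pt.compare_groups(_profiles_frame(rows), "mean_mfi_3_12")


class TestBootstrapPeriodFrequencies:
    def test_identical_cells_zero_sd(self):
        periods = {f"c{i}": [2.0] for i in range(10)}
        table = pt.bootstrap_period_frequencies(periods, n_boot=200, seed=0)
        np.testing.assert_allclose(table["boot_sd"], 0.0)
        np.testing.assert_allclose(table["error_bar"], 0.0)

    def test_error_bar_is_twice_sd(self):
        periods = {f"c{i}": [2.0 if i % 3 else 3.0] for i in range(12)}
        table = pt.bootstrap_period_frequencies(periods, n_boot=300, seed=1)
        np.testing.assert_allclose(table["error_bar"], 2.0 * table["boot_sd"])

    def test_deterministic_under_seed(self):
        periods = {f"c{i}": [1.0 + (i % 4)] for i in range(20)}
        a = pt.bootstrap_period_frequencies(periods, n_boot=250, seed=5)
        b = pt.bootstrap_period_frequencies(periods, n_boot=250, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_binomial_closed_form_agreement(self):
        # 20 of 50 single-period cells in the 2-h bin: SD ~ sqrt(p(1-p)/n)
        periods = {f"c{i}": [2.0 if i < 20 else 3.0] for i in range(50)}
        table = pt.bootstrap_period_frequencies(periods, n_boot=2000, seed=3)
        p = 20 / 50
        expected = np.sqrt(p * (1 - p) / 50)
        observed = float(table.loc[table.period_h == 2, "boot_sd"].iloc[0])
        assert observed == pytest.approx(expected, rel=0.2)

    def test_residual_resampling_option_labelled(self):
        periods = {f"c{i}": [2.0 if i % 2 else 3.0] for i in range(10)}
        table = pt.bootstrap_period_frequencies(
            periods, n_boot=200, seed=0, method="residuals"
        )
        assert table.attrs["method"] == "residuals"
        assert (table["error_bar"] >= 0).all()

    def test_no_eligible_cells_raises(self):
        with pytest.raises(ValueError):
            pt.bootstrap_period_frequencies({"a": []}, n_boot=200)


class TestWriteReport:
    def test_empty_profiles_metadata_only(self, tmp_path):
        written = pt.write_report(tmp_path / "out")
        names = [p.name for p in written]
        assert names == ["run_metadata.json"]

    def test_rerun_is_byte_identical(self, tmp_path, small_cohort):
        kept, excluded = pt.filter_tracks(small_cohort.traces)
        df = pt.profiles_to_frame([pt.profile_cell(t) for t in kept])
        summary, fractions = pt.summarize_by_group(df)
        outs = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            pt.write_report(
                out, profiles=df, summary=summary, period_fractions=fractions,
                exclusions=excluded, metadata={"seed": 42},
            )
            outs.append(out)
        for name in ("profiles.csv", "group_summary.csv", "exclusions.csv"):
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()

    def test_report_includes_exclusion_ledger(self, tmp_path, small_cohort):
        kept, excluded = pt.filter_tracks(small_cohort.traces)
        df = pt.profiles_to_frame([pt.profile_cell(t) for t in kept])
        pt.write_report(tmp_path / "r", profiles=df, exclusions=excluded)
        ledger = pd.read_csv(tmp_path / "r" / "exclusions.csv")
        assert list(ledger.columns) == ["cell_id", "reason"]
        assert len(ledger) == len(excluded)
        assert set(ledger["reason"]).issubset({"too_short", "mitosis", "drift"})
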