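"""Match-up construction and the R2 / RMSE / OWT-accuracy measures."""

import numpy as np
import pandas as pd
import pytest

from lakeowt.retrieval import retrieve_table
from lakeowt.synthetic import generate_matchups
from lakeowt.validation import (GroupingScheme, build_matchups, owt_accuracy,
                                r_squared, rmse, summarize)


class TestBuildMatchups:
    @staticmethod
    def _tables():
        ins = pd.DataFrame({"station": ["A"], "date": ["2018-06-10"],
                            "chl": [5.0]})
        sat = pd.DataFrame({
            "station": ["A", "A", "A"],
            "date": ["2018-06-09", "2018-06-11", "2018-06-12"],
            "TOA_R705": [0.02, 0.021, 0.022],
        })
        return ins, sat

    def test_plus_minus_one_day_window(self):
        ins, sat = self._tables()
        mu = build_matchups(ins, sat, "MSI")
        assert len(mu) == 2  # D-1 and D+1 kept, D+2 excluded
        assert sorted(mu["time_delta_days"]) == [-1, 1]
        assert (mu["window"] == "3x3 mean").all()

    def test_olci_single_pixel_window(self):
        ins, sat = self._tables()
        mu = build_matchups(ins, sat, "OLCI")
        assert (mu["window"] == "single").all()

    def test_duplicate_satellite_rows_deduplicated(self):
        ins, sat = self._tables()
        sat2 = pd.concat([sat, sat.iloc[[0]]], ignore_index=True)
        with pytest.warns(UserWarning, match="duplicate"):
            mu = build_matchups(ins, sat2, "MSI")
        assert len(mu) == 2

    def test_no_common_stations_warns_empty(self):
        ins, sat = self._tables()
        sat["station"] = "B"
        with pytest.warns(UserWarning, match="common"):
            mu = build_matchups(ins, sat, "MSI")
        assert mu.empty


class TestR2AndRmse:
    def test_perfect_prediction(self, rng):
        y = rng.uniform(0, 10, 20)
        assert r_squared(y, y) == pytest.approx(1.0)
        assert rmse(y, y) == 0.0

    def test_mean_prediction_gives_zero(self, rng):
        y = rng.uniform(0, 10, 20)
        assert r_squared(y, np.full_like(y, y.mean())) == pytest.approx(0.0)

    def test_can_be_negative_hand_value(self):
        # 1 - 11 / (96/9) = -0.03125
        assert r_squared([0, 0, 4], [1, 1, 1]) == pytest.approx(-0.03125)

    def test_constant_observations_flagged_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(r_squared([2, 2, 2], [1, 2, 3]))

    def test_rmse_hand_values(self):
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))
        assert rmse([2], [5]) == 3.0

    def test_rmse_translation_and_scale(self, rng):
        y, yh = rng.uniform(0, 5, 30), rng.uniform(0, 5, 30)
        base = rmse(y, yh)
        assert rmse(y + 7.7, yh + 7.7) == pytest.approx(base)
        assert rmse(3 * y, 3 * yh) == pytest.approx(3 * base)

    def test_r2_affine_invariance(self, rng):
        y, yh = rng.uniform(0, 5, 30), rng.uniform(0, 5, 30)
        base = r_squared(y, yh)
        assert r_squared(2.5 * y - 1.0, 2.5 * yh - 1.0) == pytest.approx(base)


class TestOwtAccuracy:
    def test_identical_labels(self):
        labs = ["Clear", "Brown", "Turbid"]
        out = owt_accuracy(labs, labs)
        assert out["accuracy"] == 100.0
        assert out["distribution"]["correct"] == 100.0

    def test_all_clear_vs_brown_is_large(self):
        out = owt_accuracy(["Clear"] * 4, ["Brown"] * 4)
        assert out["accuracy"] == 0.0
        assert out["distribution"]["large"] == 100.0

    def test_half_correct_half_little(self):
        truth = ["Moderate", "Turbid", "Moderate", "Turbid"]
        derived = ["Moderate", "Turbid", "Turbid", "Moderate"]
        out = owt_accuracy(truth, derived)
        assert out["accuracy"] == 50.0
        assert out["distribution"]["little"] == 50.0

    def test_distribution_sums_to_100(self, rng):
        from lakeowt.owt import OWT_CLASSES, UNCLASSIFIED
        pool = OWT_CLASSES + (UNCLASSIFIED,)
        truth = list(rng.choice(OWT_CLASSES, 37))
        derived = list(rng.choice(pool, 37))
        out = owt_accuracy(truth, derived)
        assert sum(out["distribution"].values()) == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            owt_accuracy([], [])


class TestSummarize:
    def test_single_group_equals_pooled(self):
        mu = pd.DataFrame({"chl": [1.0, 2, 3, 4], "chl_derived": [1.1, 2, 3, 3.9],
                           "owt": ["Brown"] * 4})
        out = summarize(mu, "chl", GroupingScheme("by_owt"))
        grp = out[out["group"] == "Brown"].iloc[0]
        pooled = out[out["group"] == "pooled"].iloc[0]
        assert grp["r2"] == pytest.approx(pooled["r2"])
        assert grp["rmse"] == pytest.approx(pooled["rmse"])

    def test_small_group_flagged(self):
        mu = pd.DataFrame({"chl": [1.0, 2, 3], "chl_derived": [1.0, 2, 3],
                           "owt": ["Brown", "Brown", "Clear"]})
        out = summarize(mu, "chl", GroupingScheme("by_owt"))
        clear = out[out["group"] == "Clear"].iloc[0]
        assert clear["flag"] == "n < 2"

    def test_missing_pairs_dropped_and_counted(self):
        mu = pd.DataFrame({"chl": [1.0, 2, np.nan], "chl_derived": [1.0, np.nan, 3]})
        out = summarize(mu, "chl")
        pooled = out[out["group"] == "pooled"].iloc[0]
        assert pooled["n"] == 1
        assert pooled["n_dropped"] == 2

    def test_tercile_bins_cover_data(self, rng):
        n = 90
        mu = pd.DataFrame({"chl": rng.uniform(0, 30, n)})
        mu["chl_derived"] = mu["chl"] * 1.01
        out = summarize(mu, "chl", GroupingScheme("by_insitu_bins"))
        names = set(out["group"]) - {"pooled"}
        assert names == {"low", "medium", "high"}
        assert out[out["group"] != "pooled"]["n"].sum() == n


class TestRecovery:
    """Synthetic match-ups summarised end-to-end recover the noise level."""

    def test_noise_free_matchups_are_exact(self, registry):
        ins, sat, _ = generate_matchups(60, "MSI", registry, noise_sd=0.0, seed=5)
        mu = retrieve_table(build_matchups(ins, sat, "MSI"), "MSI", registry=registry)
        out = summarize(mu, "chl", GroupingScheme("by_owt"))
        assert (out["rmse"] < 1e-9).all()
        pooled = out[out["group"] == "pooled"].iloc[0]
        assert pooled["r2"] == pytest.approx(1.0)

    def test_error_monotone_in_noise(self, registry):
        rmses = []
        for sd in (0.0, 0.05, 0.2):
            ins, sat, _ = generate_matchups(150, "MSI", registry,
                                            noise_sd=sd, seed=17)
            mu = retrieve_table(build_matchups(ins, sat, "MSI"), "MSI",
                                registry=registry)
            pooled = summarize(mu, "tsm").iloc[-1]
            rmses.append(pooled["rmse"])
        assert rmses[0] < 1e-9
        assert rmses[0] < rmses[1] < rmses[2]

    def test_rmse_tracks_relative_noise_level(self, registry):
        sd = 0.1
        ins, sat, _ = generate_matchups(500, "MSI", registry, noise_sd=sd, seed=11)
        mu = retrieve_table(build_matchups(ins, sat, "MSI"), "MSI", registry=registry)
        for product in ("chl", "tsm", "cdom400", "sd"):
            y = mu[product].to_numpy()
            yh = mu[f"{product}_derived"].to_numpy()
            scale = np.sqrt(np.mean(yh ** 2))
            assert rmse(y, yh) / scale == pytest.approx(sd, rel=0.2)
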