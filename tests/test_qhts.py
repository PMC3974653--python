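"""qHTS analysis: normalization, 4PL fits, curve classes, triage, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import series_from_params
from pheoscreen import qhts
from pheoscreen.qhts import (
    DoseResponseCurve,
    ScreenConfig,
    TitrationSeries,
    four_param_logistic,
    normalize_plate,
    triage_activity,
)


def make_plate(reads_sample, dmso=(2000, 2000, 2000), pos=(200, 200, 200)):
    rows = [("P1", 1, 5 + i, r, "sample") for i, r in enumerate(reads_sample)]
    rows += [("P1", i + 1, 1, r, "dmso") for i, r in enumerate(dmso)]
    rows += [("P1", i + 1, 3, r, "pos_ctrl") for i, r in enumerate(pos)]
    return pd.DataFrame(rows, columns=["plate_id", "row", "col", "read", "role"])


class TestNormalizePlate:
    def test_control_medians_map_to_0_and_100(self):
        plate = make_plate([2000, 200])
        out = normalize_plate(plate)
        sample = out[out["role"] == "sample"]["normalized"]
        assert sample.tolist() == [0.0, 100.0]

    def test_midpoint_read_is_50_percent(self):
        out = normalize_plate(make_plate([1100]))
        assert out[out["role"] == "sample"]["normalized"].iloc[0] == pytest.approx(50.0)

    def test_too_few_controls_rejected(self):
        plate = make_plate([1000], dmso=(2000,), pos=(200, 200))
        with pytest.raises(ValueError, match="control wells"):
            normalize_plate(plate)

    def test_degenerate_window_rejected(self):
        plate = make_plate([1000], dmso=(500, 500), pos=(500, 500))
        with pytest.raises(ValueError, match="degenerate"):
            normalize_plate(plate)

    def test_affine_idempotence_on_ideal_controls(self):
        # normalizing already-normalized data with ideal (0/100) controls
        # changes nothing
        plate = make_plate([0.0, 37.5, 100.0], dmso=(0.0, 0.0),
                           pos=(100.0, 100.0))
        plate["read"] = -plate["read"]  # inhibition lowers the raw signal
        out = normalize_plate(plate)
        sample = out[out["role"] == "sample"]
        assert np.allclose(sample["normalized"], -sample["read"])


class TestFit4PL:
    def test_roundtrip_recovers_parameters(self):
        s = series_from_params(0.0, 90.0, 0.47, 1.5)
        res = DoseResponseCurve(s).fit()
        assert res.converged
        assert res.ic50 == pytest.approx(0.47, rel=1e-4)
        assert res.hill == pytest.approx(1.5, rel=1e-4)
        assert res.efficacy == pytest.approx(90.0, rel=1e-4)

    def test_flat_series_harmless(self):
        conc = np.logspace(-3, 1, 8)
        res = DoseResponseCurve(TitrationSeries("flat", conc, np.zeros(8))).fit()
        assert (not res.converged) or res.efficacy < 1e-6
        assert res.curve_class == "4"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">=4"):
            DoseResponseCurve(TitrationSeries("x", [0.1, 1, 10], [0, 50, 90]))

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            TitrationSeries("x", [0.0, 0.1, 1.0, 10.0], [0, 10, 50, 90])

    def test_matches_grid_search_oracle(self):
        """Fit SSE must not exceed a brute-force profile-grid minimum."""
        rng = np.random.default_rng(7)
        conc = np.logspace(-3, 1.66, 8)
        for _ in range(20):
            bottom = rng.uniform(-5, 5)
            top = rng.uniform(40, 110)
            ic50 = 10 ** rng.uniform(-2, 1)
            hill = rng.uniform(0.5, 4)
            y = four_param_logistic(conc, bottom, top, ic50, hill)
            y = y + rng.normal(0, 2.0, conc.size)
            res = DoseResponseCurve(TitrationSeries("r", conc, y)).fit()
            # independent dense grid, linear profile of (bottom, top)
            best = np.inf
            for lg in np.linspace(-4, 2.7, 80):
                for h in np.linspace(0.1, 6, 60):
                    f = 1 / (1 + (10.0 ** lg / conc) ** h)
                    A = np.c_[np.ones_like(f), f]
                    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                    sse = float(np.sum((y - A @ coef) ** 2))
                    best = min(best, sse)
            assert res.sse <= best + 1e-6 + 0.01 * best

    def test_summary_mentions_class_and_ic50(self):
        res = DoseResponseCurve(series_from_params(0, 90, 0.47, 1.5)).fit()
        text = res.summary()
        assert "IC50" in text and "curve class" in text


class TestClassifyCurve:
    def fit(self, series, config=None):
        return DoseResponseCurve(series).fit(config or ScreenConfig())

    def test_complete_high_efficacy_is_1_1(self):
        res = self.fit(series_from_params(0, 96, 0.2, 2.0))
        assert res.curve_class == "1.1"

    def test_complete_sub80_efficacy_is_1_2(self):
        res = self.fit(series_from_params(0, 74, 0.2, 2.0))
        assert res.curve_class == "1.2"

    def test_one_asymptote_is_2_x(self):
        # IC50 near the top of the tested range: lower asymptote only
        res = self.fit(series_from_params(0, 96, 15.0, 1.8))
        assert res.curve_class == "2.1"
        res = self.fit(series_from_params(0, 75, 15.0, 1.8))
        assert res.curve_class == "2.2"

    def test_spike_at_highest_dose_is_3(self):
        conc = np.logspace(-3, 1.66, 8)
        resp = np.zeros(8)
        resp[-1] = 55.0
        res = self.fit(TitrationSeries("spike", conc, resp))
        assert res.curve_class == "3"

    def test_flat_is_4(self):
        conc = np.logspace(-3, 1.66, 8)
        res = self.fit(TitrationSeries("flat", conc, np.full(8, 0.5)))
        assert res.curve_class == "4"

    def test_classification_total_over_random_inputs(self):
        rng = np.random.default_rng(0)
        conc = np.logspace(-3, 1.66, 8)
        for _ in range(25):
            resp = rng.normal(0, 30, 8)
            res = self.fit(TitrationSeries("r", conc, resp))
            assert res.curve_class in qhts.CURVE_CLASSES


class TestTriage:
    @pytest.mark.parametrize(
        "cls,eff,expected",
        [("1.1", 96, "active"), ("1.2", 74, "active"), ("2.1", 85, "active"),
         ("2.2", 75, "active"), ("2.2", 52, "inconclusive"),
         ("1.2", 60, "inconclusive"),     # strict >60
         ("3", 90, "inconclusive"), ("4", 0, "inactive"), ("4", 99, "inactive")])
    def test_rule(self, cls, eff, expected):
        assert triage_activity(cls, eff) == expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown curve class"):
            triage_activity("5", 50)

    @given(cls=st.sampled_from(qhts.CURVE_CLASSES),
           eff=st.floats(0, 150, allow_nan=False))
    @settings(max_examples=60, deadline=None)
    def test_partition_total_and_exclusive(self, cls, eff):
        assert triage_activity(cls, eff) in {"active", "inactive", "inconclusive"}

    def test_counts_partition_the_screen(self, noiseless_screen):
        counts = noiseless_screen["activity"].value_counts()
        assert counts.sum() == len(noiseless_screen)

    def test_noiseless_class_recovery(self, noiseless_screen):
        m = noiseless_screen
        assert (m["curve_class"] == m["true_class"]).mean() >= 0.99

    def test_observed_max_triage_switch(self):
        cfg = ScreenConfig(triage_on_observed_max=True)
        # fitted efficacy ~55 but the observed maximum response exceeds 60
        conc = np.logspace(-3, 1.66, 8)
        resp = four_param_logistic(conc, 0, 55, 0.2, 2.0)
        resp[-1] = 62.0
        res = DoseResponseCurve(TitrationSeries("x", conc, resp)).fit(cfg)
        default = DoseResponseCurve(TitrationSeries("x", conc, resp)).fit()
        if res.curve_class in qhts.CLASS_CONFIDENCE_ORDER:
            assert res.activity == "active"
            assert default.activity == "inconclusive"


class TestRankHits:
    def test_table1_class11_block_sorted_by_potency(self, top50):
        df = top50.rename(columns={"name": "compound_id", "ic50_um": "ic50",
                                   "efficacy_pct": "efficacy"})
        df["activity"] = "active"  # printed hits: rank them all
        ranked = qhts.rank_hits(df, top_n=None)
        block = ranked[ranked["curve_class"] == "1.1"]
        assert block["ic50"].is_monotonic_increasing
        assert ranked.iloc[0]["compound_id"].startswith("Colchicine")
        # class blocks keep their confidence order
        order = ranked["curve_class"].map(
            {c: i for i, c in enumerate(qhts.CLASS_CONFIDENCE_ORDER)})
        assert order.is_monotonic_increasing

    def test_empty_input_empty_output(self):
        empty = pd.DataFrame(columns=["compound_id", "ic50", "curve_class",
                                      "activity"])
        assert len(qhts.rank_hits(empty, 10)) == 0

    def test_only_actives_returned(self, noiseless_screen):
        ranked = qhts.rank_hits(noiseless_screen, top_n=None)
        assert (ranked["activity"] == "active").all()

    def test_overlarge_top_n_warns_and_returns_all(self, noiseless_screen):
        with pytest.warns(UserWarning, match="only"):
            ranked = qhts.rank_hits(noiseless_screen, top_n=10 ** 6)
        assert len(ranked) == (noiseless_screen["activity"] == "active").sum()


class TestCategoryEnrichment:
    def test_half_active_single_category(self):
        fits = pd.DataFrame({
            "compound_id": list("abcd"),
            "category": ["x"] * 4,
            "activity": ["active", "active", "inactive", "inactive"]})
        tab = qhts.category_enrichment(fits)
        assert len(tab) == 1
        assert tab.loc[0, "enrichment_ratio"] == pytest.approx(50.0)
        assert bool(tab.loc[0, "enriched"])

    def test_planted_enriched_category_flagged(self):
        rng = np.random.default_rng(5)
        n = 400
        cat = np.where(rng.random(n) < 0.1, "planted", "background")
        active_p = np.where(cat == "planted", 0.30, 0.01)
        activity = np.where(rng.random(n) < active_p, "active", "inactive")
        fits = pd.DataFrame({"compound_id": [f"c{i}" for i in range(n)],
                             "category": cat, "activity": activity})
        tab = qhts.category_enrichment(fits).set_index("category")
        assert bool(tab.loc["planted", "enriched"])
        assert not bool(tab.loc["background", "enriched"])
        assert tab.index[0] == "planted"  # sorted descending

    def test_top5_report_has_five_rows(self):
        fits = pd.DataFrame({
            "compound_id": [f"c{i}" for i in range(70)],
            "category": [f"cat{i % 7}" for i in range(70)],
            "activity": ["active" if i % 3 == 0 else "inactive"
                         for i in range(70)]})
        assert len(qhts.category_enrichment(fits).head(5)) == 5
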