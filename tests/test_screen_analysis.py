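import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from myoscreen.screen_analysis import (
    AnalysisParams,
    HitCall,
    LayoutEntry,
    PhenotypeCategory,
    PlateLayout,
    classify_phenotype,
    mann_whitney,
    normalize_to_mock,
    primary_select,
    secondary_confirm,
    significance_code,
    subtract_death_background,
    summarize_screen,
)
from myoscreen.synthetic_data import PlateSimParams, simulate_plate
from conftest import make_layout


def brute_force_mw_p(a, b, alternative):
    """Independent oracle: enumerate every assignment of pooled ranks."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(a)
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    n = len(pooled)
    mid = n1 * (n - n1) / 2
    hits = total = 0
    for combo in itertools.combinations(range(1, n + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        total += 1
        if alternative == "less":
            hits += u <= u_obs
        elif alternative == "greater":
            hits += u >= u_obs
        else:
            hits += abs(u - mid) >= abs(u_obs - mid) - 1e-9
    return hits / total


class TestMannWhitney:
    def test_separated_samples_one_sided(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6], "less") == pytest.approx(0.05)

    def test_separated_samples_two_sided(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6], "two_sided") == pytest.approx(0.10)

    def test_identical_constant_vectors(self):
        assert mann_whitney([5.0] * 4, [5.0] * 4, "two_sided") == 1.0

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 3), (2, 6)])
    @pytest.mark.parametrize("alternative", ["less", "greater", "two_sided"])
    def test_exact_matches_enumeration_oracle(self, n1, n2, alternative, rng):
        for _ in range(5):
            vals = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float))
            a, b = vals[:n1], vals[n1:]
            assert mann_whitney(a, b, alternative) == pytest.approx(
                brute_force_mw_p(a, b, alternative)
            )

    def test_large_sample_normal_approx_reasonable(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(1.5, 1, 30)
        p = mann_whitney(a, b, "less")
        assert 0 < p < 0.01

    def test_tie_correction_path(self):
        # ties force the approximate path even for small n
        p = mann_whitney([1, 1, 2], [2, 3, 3], "two_sided")
        assert 0 < p <= 1

    def test_significance_codes(self):
        assert significance_code(0.004) == "***"
        assert significance_code(0.009) == "**"
        assert significance_code(0.04) == "*"
        assert significance_code(0.06) == "ns"


class TestPlateAdjustments:
    def _plate(self, layout, values):
        rows = [
            {"well_id": w, "pct_myotubes": v, "cell_count": 1000.0}
            for w, v in values.items()
        ]
        return pd.DataFrame(rows)

    def test_zero_death_background_is_identity(self):
        layout = make_layout(n_samples=2, n_death=2)
        plate = self._plate(
            layout, {w: (0.0 if w.startswith("D") else 50.0) for w in layout.entries}
        )
        out = subtract_death_background(plate, layout)
        kept = out[~out["well_id"].str.startswith("D")]
        assert (kept["pct_myotubes"] == 50.0).all()

    def test_death_background_subtracted_and_floored(self):
        layout = make_layout(n_samples=2, n_death=1)
        values = {w: 10.0 if w.startswith("D") else 50.0 for w in layout.entries}
        values["S000r1"] = 5.0
        out = subtract_death_background(self._plate(layout, values), layout)
        by_well = out.set_index("well_id")["pct_myotubes"]
        assert by_well["S001r1"] == 40.0
        assert by_well["S000r1"] == 0.0  # floored

    def test_no_death_wells_errors(self):
        layout = make_layout(n_samples=1)
        with pytest.raises(ValueError, match="death"):
            subtract_death_background(self._plate(layout, {"S000r1": 1.0}), layout)

    def test_normalization_basics(self):
        layout = make_layout(n_samples=2, n_mock=2, n_neg=0)
        values = {"S000r1": 20.0, "S001r1": 40.0, "M00": 40.0, "M01": 40.0}
        out = normalize_to_mock(self._plate(layout, values), layout)
        rel = out.set_index("well_id")["rel_pct_myotubes"]
        assert rel["S000r1"] == 50.0
        assert rel["S001r1"] == 100.0
        assert rel["M00"] == 100.0

    def test_per_plate_normalization(self):
        layout = make_layout(n_samples=1, n_mock=1, n_neg=0)
        plate = pd.DataFrame(
            [
                {"plate_id": "p1", "well_id": "S000r1", "pct_myotubes": 20.0, "cell_count": 1.0},
                {"plate_id": "p1", "well_id": "M00", "pct_myotubes": 40.0, "cell_count": 1.0},
                {"plate_id": "p2", "well_id": "S000r1", "pct_myotubes": 20.0, "cell_count": 1.0},
                {"plate_id": "p2", "well_id": "M00", "pct_myotubes": 20.0, "cell_count": 1.0},
            ]
        )
        out = normalize_to_mock(plate, layout)
        rel = out.set_index(["plate_id", "well_id"])["rel_pct_myotubes"]
        assert rel[("p1", "S000r1")] == 50.0
        assert rel[("p2", "S000r1")] == 100.0

    def test_zero_mock_mean_errors(self):
        layout = make_layout(n_samples=1, n_mock=1, n_neg=0)
        with pytest.raises(ValueError, match="mock"):
            normalize_to_mock(
                self._plate(layout, {"S000r1": 10.0, "M00": 0.0}), layout
            )

    def test_normalization_idempotence(self):
        layout = make_layout(n_samples=3, n_mock=2, n_neg=0)
        values = {"S000r1": 50.0, "S001r1": 75.0, "S002r1": 125.0,
                  "M00": 100.0, "M01": 100.0}
        once = normalize_to_mock(self._plate(layout, values), layout)
        renamed = once.rename(
            columns={"pct_myotubes": "x"}
        ).rename(columns={"rel_pct_myotubes": "pct_myotubes"})
        twice = normalize_to_mock(
            renamed[["well_id", "pct_myotubes", "cell_count"]], layout
        )
        assert np.allclose(
            twice["rel_pct_myotubes"], once["rel_pct_myotubes"]
        )


def _normalized_table(layout, rel_values):
    rows = []
    for well, rel in rel_values.items():
        rows.append(
            {
                "well_id": well,
                "rel_pct_myotubes": rel,
                "rel_cell_count": 100.0,
            }
        )
    return pd.DataFrame(rows)


class TestPrimarySelect:
    def test_threshold_arithmetic(self):
        # mean 100, SD 30.5 -> threshold 39 (percent of control)
        layout = PlateLayout(
            entries={
                "S000r1": LayoutEntry("reagent000", "sample"),
                "N00": LayoutEntry("neg_lna", "neg_ctrl"),
                "N01": LayoutEntry("neg_lna", "neg_ctrl"),
                "N02": LayoutEntry("neg_lna", "neg_ctrl"),
                "M00": LayoutEntry("mock", "mock"),
            }
        )
        neg = {"N00": 100 - 30.5, "N01": 100.0, "N02": 100 + 30.5, "M00": 100.0}
        sd = pd.Series(list(neg.values())).std(ddof=1)
        table = _normalized_table(layout, {**neg, "S000r1": 50.0})
        _, threshold = primary_select(table, layout)
        assert threshold == pytest.approx(100 - 2 * sd)

    def test_boundary_value_selected(self):
        layout = make_layout(n_samples=2, n_mock=2, n_neg=2)
        neg = {"N00": 80.0, "N01": 120.0, "M00": 90.0, "M01": 110.0}
        sd = pd.Series(list(neg.values())).std(ddof=1)
        threshold = 100 - 2 * sd
        table = _normalized_table(
            layout, {**neg, "S000r1": threshold, "S001r1": threshold + 0.01}
        )
        candidates, got = primary_select(table, layout)
        assert got == pytest.approx(threshold)
        assert list(candidates["reagent_id"]) == ["reagent000"]

    def test_too_few_controls_errors(self):
        layout = PlateLayout(
            entries={
                "M00": LayoutEntry("mock", "mock"),
                "S000": LayoutEntry("r0", "sample"),
            }
        )
        table = _normalized_table(layout, {"M00": 100.0, "S000": 10.0})
        with pytest.raises(ValueError, match="negative-control"):
            primary_select(table, layout)

    def test_null_rate_near_gaussian_tail(self):
        # DERIVED: one-sided P(Z < -2) ~ 2.27% for Gaussian nulls
        layout = make_layout(n_samples=4000, n_mock=50, n_neg=50)
        plate = simulate_plate(
            PlateSimParams(layout=layout, well_noise_cv=0.1, seed=3)
        )
        normalized = normalize_to_mock(plate, layout)
        candidates, _ = primary_select(normalized, layout)
        frac = len(candidates) / 4000
        assert frac == pytest.approx(0.0227, abs=0.007)


class TestClassification:
    def _hit(self, rel_pct, rel_count, p_diff, p_count, direction="low"):
        return HitCall(
            reagent_id="x",
            rel_pct_myotubes=rel_pct,
            rel_cell_count=rel_count,
            p_diff=p_diff,
            p_count=p_count,
            direction=direction,
        )

    def test_inhibited(self):
        # curated-table row: 7.12% of control, cell count 91.11
        hit = self._hit(7.12, 91.11, 0.001, 0.03)
        assert classify_phenotype(hit) == PhenotypeCategory.INHIBITED

    def test_inhibited_low_count(self):
        hit = self._hit(4.75, 28.64, 0.001, 0.001)
        assert classify_phenotype(hit) == PhenotypeCategory.INHIBITED_LOW_COUNT

    def test_inhibited_high_count(self):
        hit = self._hit(38.04, 102.74, 0.001, 0.03)
        assert classify_phenotype(hit) == PhenotypeCategory.INHIBITED_HIGH_COUNT

    def test_enhanced(self):
        hit = self._hit(104.51, 87.82, 0.03, 0.001, direction="high")
        assert classify_phenotype(hit) == PhenotypeCategory.ENHANCED

    def test_high_count_only(self):
        hit = self._hit(98.0, 110.0, 0.5, 0.01, direction="high")
        assert classify_phenotype(hit) == PhenotypeCategory.HIGH_COUNT

    def test_not_hit(self):
        hit = self._hit(95.0, 99.0, 0.4, 0.6)
        assert classify_phenotype(hit) == PhenotypeCategory.NOT_HIT

    def test_totality_and_determinism(self, rng):
        params = AnalysisParams()
        for _ in range(200):
            hit = self._hit(
                float(rng.uniform(0, 150)),
                float(rng.uniform(0, 150)),
                float(rng.uniform(0, 1)),
                float(rng.uniform(0, 1)),
                direction=rng.choice(["low", "high"]),
            )
            c1 = classify_phenotype(hit, params)
            c2 = classify_phenotype(hit, params)
            assert isinstance(c1, PhenotypeCategory)
            assert c1 == c2


class TestSecondaryConfirm:
    def _screen(self, effect, n_reps=3, n_ctrl=24, cv=0.1, seed=0):
        layout = make_layout(
            n_samples=1, n_mock=n_ctrl // 2, n_neg=n_ctrl // 2, replicates=n_reps
        )
        plate = simulate_plate(
            PlateSimParams(
                layout=layout,
                effect_map={"reagent000": (effect, 1.0)},
                well_noise_cv=cv,
                seed=seed,
            )
        )
        normalized = normalize_to_mock(plate, layout)
        candidates = pd.DataFrame(
            [{"reagent_id": "reagent000", "direction": "low"}]
        )
        return layout, normalized, candidates

    def test_strong_inhibitor_confirmed(self):
        layout, normalized, candidates = self._screen(0.07)
        calls = secondary_confirm(candidates, normalized, layout)
        assert calls[0].confirmed
        assert calls[0].sig_diff == "***"
        assert calls[0].category == PhenotypeCategory.INHIBITED

    def test_null_reagent_not_confirmed(self):
        layout, normalized, candidates = self._screen(1.0, seed=5)
        calls = secondary_confirm(candidates, normalized, layout)
        assert not calls[0].confirmed

    def test_missing_replicates_flagged_not_dropped(self):
        layout, normalized, candidates = self._screen(0.1, n_reps=2)
        calls = secondary_confirm(candidates, normalized, layout)
        assert len(calls) == 1
        assert not calls[0].evaluable

    def test_planted_effect_power(self):
        # DERIVED: Monte-Carlo power of triplicates vs 24 pooled controls
        # at a 0.2x effect and cv=0.1 is ~1
        confirmed = 0
        for seed in range(20):
            layout, normalized, candidates = self._screen(0.2, seed=seed)
            calls = secondary_confirm(candidates, normalized, layout)
            confirmed += calls[0].confirmed
        assert confirmed >= 19

    def test_viability_exclusion(self):
        layout = make_layout(n_samples=1, n_mock=12, n_neg=12, replicates=3)
        plate = simulate_plate(
            PlateSimParams(
                layout=layout,
                effect_map={"reagent000": (0.1, 0.05)},  # nearly dead well
                well_noise_cv=0.05,
                seed=1,
            )
        )
        normalized = normalize_to_mock(plate, layout)
        candidates = pd.DataFrame([{"reagent_id": "reagent000", "direction": "low"}])
        params = AnalysisParams(viability_exclusion_pct=20.0)
        calls = secondary_confirm(candidates, normalized, layout, params)
        assert not calls[0].evaluable


class TestSummarize:
    def test_empty_hit_set(self):
        table, _ = summarize_screen([])
        assert len(table) == 0
        assert "category" in table.columns

    def test_category_ordering_and_permutation_invariance(self, rng):
        hits = [
            HitCall("r_enh", 120.0, 100.0, p_diff=0.01, direction="high",
                    category=PhenotypeCategory.ENHANCED, confirmed=True),
            HitCall("r_inh", 20.0, 90.0, p_diff=0.001, p_count=0.2,
                    category=PhenotypeCategory.INHIBITED, confirmed=True),
            HitCall("r_low", 10.0, 40.0, p_diff=0.001, p_count=0.001,
                    category=PhenotypeCategory.INHIBITED_LOW_COUNT, confirmed=True),
            HitCall("r_none", 100.0, 100.0, category=PhenotypeCategory.NOT_HIT),
        ]
        table1, _ = summarize_screen(hits)
        shuffled = [hits[i] for i in rng.permutation(len(hits))]
        table2, _ = summarize_screen(shuffled)
        assert list(table1["category"]) == [
            "inhibited", "inhibited_low_count", "enhanced"
        ]
        pd.testing.assert_frame_equal(table1, table2)

    def test_series_export(self):
        layout = make_layout(n_samples=3)
        plate = simulate_plate(PlateSimParams(layout=layout, seed=0))
        normalized = normalize_to_mock(plate, layout)
        _, series = summarize_screen([], normalized)
        assert len(series) == len(normalized)
        assert list(series["series_index"]) == list(range(len(series)))
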