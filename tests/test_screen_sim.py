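import math

import numpy as np
import pytest

from tmdscreen import (
    AffinityModel,
    HillParams,
    ScreenConfig,
    TMDPair,
    assign_true_ld50,
    enumerate_pairs,
    fit_hill,
    make_variant,
    simulate_control_discrimination,
    simulate_dose_response,
    simulate_selection,
    survival_probability,
)
from tmdscreen.library_design import WILD_TYPE
from tmdscreen.pattern_stats import classify_charge_pair, within_spacing
from tmdscreen.screen_sim import calibrate_survival

from .conftest import STANDARD_DOSES

WT_PAIR = TMDPair(n_variant=WILD_TYPE, c_variant=WILD_TYPE)
D6R7 = TMDPair(n_variant=make_variant(6, "D"), c_variant=make_variant(7, "R"))


class TestAffinityModel:
    def test_uncharged_pair_is_base(self):
        model = AffinityModel(noise_cv=0.0)
        rng = np.random.default_rng(0)
        assert assign_true_ld50(WT_PAIR, model, rng) == model.base_ld50

    def test_default_calibration_anchor(self):
        model = AffinityModel()
        assert model.base_ld50 / model.reference_ld50 == pytest.approx(0.37)

    def test_opposite_6_7_beats_every_like_pair(self):
        model = AffinityModel(noise_cv=0.0)
        rng = np.random.default_rng(0)
        best = assign_true_ld50(D6R7, model, rng)
        like = [
            p for p in enumerate_pairs()
            if classify_charge_pair(p).value == "like"
        ]
        assert all(assign_true_ld50(p, model, rng) < best for p in like)

    def test_noise_cv_zero_deterministic(self):
        model = AffinityModel(noise_cv=0.0)
        rng = np.random.default_rng(1)
        values = {assign_true_ld50(D6R7, model, rng) for _ in range(10)}
        assert len(values) == 1

    def test_lognormal_clone_factor_unbiased(self):
        model = AffinityModel(noise_cv=0.3)
        rng = np.random.default_rng(2)
        draws = [assign_true_ld50(WT_PAIR, model, rng) for _ in range(20000)]
        assert np.mean(draws) == pytest.approx(model.base_ld50, rel=0.02)
        cv = np.std(draws) / np.mean(draws)
        assert cv == pytest.approx(0.3, rel=0.1)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            AffinityModel(base_ld50=120.0, reference_ld50=100.0)
        with pytest.raises(ValueError):
            AffinityModel(penalty_like=0.0)


class TestSurvival:
    def test_zero_dose(self):
        assert survival_probability(0.0, 10.0, 4.0) == 1.0

    def test_infinite_ld50(self):
        assert survival_probability(100.0, math.inf, 4.0) == 1.0

    def test_half_survival_at_ld50(self):
        assert survival_probability(10.0, 10.0, 4.0) == pytest.approx(0.5)

    def test_monotone_in_dose_and_ld50(self):
        doses = np.linspace(0, 100, 50)
        s = [survival_probability(d, 30.0, 4.0) for d in doses]
        assert all(a >= b for a, b in zip(s, s[1:]))
        ld50s = np.linspace(1, 100, 50)
        s = [survival_probability(30.0, l, 4.0) for l in ld50s]
        assert all(a <= b for a, b in zip(s, s[1:]))


class TestSimulateDoseResponse:
    def test_noiseless_round_trip(self, true_params):
        rng = np.random.default_rng(0)
        series = simulate_dose_response(
            true_params, STANDARD_DOSES, 0.0, 1, rng
        )
        params, diag = fit_hill(series[0])
        assert diag.accepted
        assert abs(params.k - true_params.k) / true_params.k < 1e-6

    def test_same_seed_identical(self, true_params):
        a = simulate_dose_response(
            true_params, STANDARD_DOSES, 0.05, 3, np.random.default_rng(42)
        )
        b = simulate_dose_response(
            true_params, STANDARD_DOSES, 0.05, 3, np.random.default_rng(42)
        )
        assert a == b

    def test_requires_zero_dose(self, true_params):
        with pytest.raises(ValueError):
            simulate_dose_response(
                true_params, (1, 2, 3, 4, 5), 0.0, 1, np.random.default_rng(0)
            )

    def test_responses_truncated_at_zero(self):
        true = HillParams(c=0.05, k=5.0, g=3.0)
        rng = np.random.default_rng(3)
        series = simulate_dose_response(true, STANDARD_DOSES, 0.2, 5, rng)
        for s in series:
            assert all(y >= 0 for y in s.responses)

    def test_fit_unbiased_under_noise(self, true_params):
        # scaled-down version of the 200-curve acceptance check
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            series = simulate_dose_response(
                true_params, STANDARD_DOSES, 0.05, 1, rng
            )
            params, diag = fit_hill(series[0])
            if diag.accepted:
                errors.append((params.k - true_params.k) / true_params.k)
        assert np.median(np.abs(errors)) <= 0.10
        assert abs(np.mean(errors)) <= 0.05


@pytest.fixture(scope="module")
def tiny_library():
    return [WT_PAIR, D6R7, TMDPair(n_variant=make_variant(6, "D"),
                                   c_variant=make_variant(7, "E"))]


class TestSimulateSelection:
    def test_zero_doses_all_survive(self, tiny_library):
        config = ScreenConfig(seed=0, plate_amp=0.0, liquid_amp=0.0,
                              cells_plated=300)
        isolates = simulate_selection(tiny_library, AffinityModel(), config)
        assert sum(p.observed_count for p in isolates) == 300

    def test_same_seed_identical(self, tiny_library):
        config = ScreenConfig(seed=5, cells_plated=500)
        a = simulate_selection(tiny_library, AffinityModel(), config)
        b = simulate_selection(tiny_library, AffinityModel(), config)
        assert a == b

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            simulate_selection([], AffinityModel(), ScreenConfig(seed=0))

    def test_zero_survivors_valid(self, tiny_library):
        config = ScreenConfig(seed=0, plate_amp=1e6, liquid_amp=1e6,
                              cells_plated=50)
        assert simulate_selection(tiny_library, AffinityModel(), config) == []

    def test_expected_survivors_match_binomial_mean(self, tiny_library):
        # analytic per-pair mean: cells x frequency x S(plate) x S(liquid),
        # checked against the Monte-Carlo mean over seeded runs
        model = AffinityModel(noise_cv=0.0)
        config = ScreenConfig(seed=0, cells_plated=300)
        n_runs = 1000
        counts = np.zeros((n_runs, len(tiny_library)))
        index = {p.pair_id: j for j, p in enumerate(tiny_library)}
        for i in range(n_runs):
            isolates = simulate_selection(
                tiny_library, model, ScreenConfig(seed=i, cells_plated=300)
            )
            for p in isolates:
                counts[i, index[p.pair_id]] = p.observed_count
        for j, pair in enumerate(tiny_library):
            ld50 = model.mean_ld50(pair)
            p_survive = (
                survival_probability(config.plate_amp, ld50, config.survival_g)
                * survival_probability(config.liquid_amp, ld50, config.survival_g)
            )
            p_cell = p_survive / len(tiny_library)
            expected = 300 * p_cell
            se = math.sqrt(300 * p_cell * (1 - p_cell) / n_runs)
            assert abs(counts[:, j].mean() - expected) <= 3 * se + 1e-9

    def test_frequencies_respected(self, tiny_library):
        config = ScreenConfig(seed=0, plate_amp=0.0, liquid_amp=0.0,
                              cells_plated=3000)
        isolates = simulate_selection(
            tiny_library, AffinityModel(), config, frequencies=[1.0, 0.0, 0.0]
        )
        assert len(isolates) == 1
        assert isolates[0].pair_id == WT_PAIR.pair_id

    def test_isolates_carry_affinity_classes(self):
        config = ScreenConfig(seed=11)
        isolates = simulate_selection(
            enumerate_pairs(), AffinityModel(), config
        )
        assert isolates
        assert all(p.affinity_class in ("high", "medium", "low")
                   for p in isolates)
        assert all(p.observed_count >= 1 for p in isolates)


class TestGroundTruthSpacing:
    def test_monotone_class_ordering(self):
        # exhaustive, noiseless: classify all 1089 pairs by the model mean
        from dataclasses import replace

        from tmdscreen.dose_response import classify_affinity

        model = AffinityModel(noise_cv=0.0)
        classed = []
        for p in enumerate_pairs():
            pct = 100.0 * model.mean_ld50(p) / model.reference_ld50
            classed.append(
                replace(p, percent_of_reference=pct,
                        affinity_class=classify_affinity(pct))
            )
        fractions = within_spacing(classed, threshold=5)
        assert fractions["high"] >= fractions["medium"] >= fractions["low"]


class TestControlDiscrimination:
    def test_equal_ld50_gives_unit_ratios(self):
        config = ScreenConfig(seed=0)
        assert simulate_control_discrimination(50.0, 50.0, config) == (1.0, 1.0)

    def test_monotone_in_steepness(self):
        ratios = [
            simulate_control_discrimination(
                10.0, 2.9, ScreenConfig(seed=0, survival_g=g)
            )
            for g in (1.0, 2.0, 4.0, 6.0)
        ]
        plate = [r[0] for r in ratios]
        two_step = [r[1] for r in ratios]
        assert all(a < b for a, b in zip(plate, plate[1:]))
        assert all(a < b for a, b in zip(two_step, two_step[1:]))

    def test_zero_mutant_survival_flagged_infinite(self):
        config = ScreenConfig(seed=0, plate_amp=1e12, survival_g=8.0)
        plate, two_step = simulate_control_discrimination(1e-3, 1e-30, config)
        assert math.isinf(plate) and math.isinf(two_step)

    def test_calibration_reaches_discrimination_targets(self):
        # 100:29 relative LD50s admit a steepness/scale reproducing the
        # plate-step factor ~5 and two-step factor ~30
        g, wt, plate_ratio, two_step_ratio = calibrate_survival()
        assert plate_ratio == pytest.approx(5.0, rel=1e-3)
        assert two_step_ratio == pytest.approx(30.0, rel=0.05)
        assert 0.5 <= g <= 8.0
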