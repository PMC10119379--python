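import numpy as np
import pandas as pd
import pytest

from attnwarp.synthetic_observer import (
    CohortSpec,
    ObserverParams,
    cohort_child_seeds,
    p_choose_target,
    simulate_cohort,
    simulate_dataset,
)

PHI_1_25 = 0.8943502263331446  # Phi(10/8), frozen from scipy.stats.norm.cdf(1.25)


def mc_choice_probability(delta, foil_direction, bias, sigma, n_draws, rng,
                          circular=False):
    """Brute-force oracle: sample the representation, apply the nearest rule.

    Axis points away from the distractor; the representation is centered at
    +bias and the foil sits at +delta (away) or -delta (toward).
    """
    foil = delta if foil_direction == "away" else -delta
    x = bias + sigma * rng.standard_normal(n_draws)
    if circular:
        # wrap onto the circle and compare arc distances
        d_t = np.minimum(np.abs(x) % 360, 360 - np.abs(x) % 360)
        d_f = np.minimum(np.abs(x - foil) % 360, 360 - np.abs(x - foil) % 360)
        return np.mean(d_t < d_f)
    return np.mean(np.abs(x) < np.abs(x - foil))


class TestChoiceProbability:
    def test_chance_at_half_delta(self):
        for sigma in (3.0, 8.0, 25.0):
            params = ObserverParams(bias=5.0, sigma=sigma)
            assert p_choose_target(10.0, "away", params) == 0.5

    def test_symmetry_at_zero_bias(self):
        params = ObserverParams(bias=0.0, sigma=7.0)
        assert p_choose_target(20, "away", params) == p_choose_target(
            20, "toward", params
        )

    def test_closed_form_example(self):
        params = ObserverParams(bias=5.0, sigma=8.0)
        assert p_choose_target(10, "away", params) == 0.5
        assert p_choose_target(10, "toward", params) == pytest.approx(
            PHI_1_25, abs=1e-12
        )

    def test_matches_monte_carlo_linear(self):
        rng = np.random.default_rng(99)
        n = 1_000_000
        for delta in (10.0, 20.0, 60.0):
            for bias in (0.0, 5.0, 11.5):
                for sigma in (5.0, 15.0):
                    for direction in ("away", "toward"):
                        params = ObserverParams(bias=bias, sigma=sigma)
                        p = p_choose_target(delta, direction, params)
                        phat = mc_choice_probability(delta, direction, bias, sigma, n, rng)
                        se = np.sqrt(max(p * (1 - p), 1e-12) / n)
                        assert abs(p - phat) < 3 * se + 1e-6

    def test_matches_monte_carlo_circular(self):
        rng = np.random.default_rng(5)
        n = 1_000_000
        for delta, bias, sigma in [(10.0, 5.0, 8.0), (60.0, 11.5, 20.0),
                                   (20.0, 0.0, 30.0), (40.0, 10.0, 80.0)]:
            for direction in ("away", "toward"):
                params = ObserverParams(bias=bias, sigma=sigma)
                p = p_choose_target(delta, direction, params, model="circular")
                phat = mc_choice_probability(
                    delta, direction, bias, sigma, n, rng, circular=True
                )
                se = np.sqrt(max(p * (1 - p), 1e-12) / n)
                assert abs(p - phat) < 4 * se + 1e-6

    def test_circular_agrees_with_linear_in_small_angle_regime(self):
        for delta in (10.0, 20.0, 40.0, 60.0):
            for bias in (0.0, 5.0, 11.5, 20.0):
                for sigma in (5.0, 10.0, 20.0, 30.0):
                    for direction in ("away", "toward"):
                        params = ObserverParams(bias=bias, sigma=sigma)
                        lin = p_choose_target(delta, direction, params)
                        circ = p_choose_target(delta, direction, params, model="circular")
                        assert abs(lin - circ) <= 0.005

    def test_monotone_in_delta_away(self):
        params = ObserverParams(bias=4.0, sigma=9.0)
        ps = [p_choose_target(d, "away", params) for d in (10, 14, 20, 30, 60)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_monotone_in_bias(self):
        biases = (0.0, 3.0, 6.0, 12.0)
        away = [
            p_choose_target(10, "away", ObserverParams(bias=b, sigma=9.0))
            for b in biases
        ]
        toward = [
            p_choose_target(10, "toward", ObserverParams(bias=b, sigma=9.0))
            for b in biases
        ]
        assert all(a > b for a, b in zip(away, away[1:]))
        assert all(a < b for a, b in zip(toward, toward[1:]))

    def test_lapse_mixes_toward_chance(self):
        base = ObserverParams(bias=0.0, sigma=5.0)
        lapsed = ObserverParams(bias=0.0, sigma=5.0, lapse=0.4)
        p0 = p_choose_target(60, "away", base)
        p1 = p_choose_target(60, "away", lapsed)
        assert p1 == pytest.approx(0.6 * p0 + 0.2)

    def test_bias_by_distance_lookup(self):
        params = ObserverParams(bias_by_D={30.0: 11.5, 60.0: 5.3}, sigma=9.0)
        p30 = p_choose_target(10, "away", params, D=30.0)
        p60 = p_choose_target(10, "away", params, D=60.0)
        assert p30 < p60
        with pytest.raises(KeyError):
            p_choose_target(10, "away", params, D=90.0)

    def test_validation(self):
        params = ObserverParams()
        with pytest.raises(ValueError):
            p_choose_target(0.0, "away", params)
        with pytest.raises(ValueError):
            p_choose_target(-5.0, "away", params)
        with pytest.raises(ValueError):
            p_choose_target(10.0, "sideways", params)
        with pytest.raises(ValueError):
            p_choose_target(10.0, "away", params, model="cubic")
        with pytest.raises(ValueError):
            ObserverParams(sigma=0.0)
        with pytest.raises(ValueError):
            ObserverParams(lapse=0.7)


class TestSimulateDataset:
    def test_deterministic(self, designs):
        params = ObserverParams(bias=8.0, sigma=10.0, search_accuracy=0.9)
        a = simulate_dataset(designs["E1"], params, seed=5)
        b = simulate_dataset(designs["E1"], params, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            simulate_dataset(pd.DataFrame(), ObserverParams(), seed=0)

    def test_cell_rates_match_closed_form(self, designs):
        # pool many observers of one E1 design; rates land near the model's p
        params = ObserverParams(bias=0.0, sigma=10.0)
        frames = [
            simulate_dataset(designs["E1"], params, seed=s, subject_id=s)
            for s in range(40)
        ]
        tab = pd.concat(frames)
        for (delta, direction), cell in tab.groupby(["delta", "foil_direction"]):
            p = p_choose_target(delta, direction, params)
            phat = (cell["choice"] == "target").mean()
            se = np.sqrt(p * (1 - p) / len(cell))
            assert abs(phat - p) < 3 * se + 1e-9

    def test_full_lapse_dilutes_to_chance(self, designs):
        params = ObserverParams(bias=20.0, sigma=5.0, lapse=0.5)
        frames = [
            simulate_dataset(designs["E1"], params, seed=s) for s in range(30)
        ]
        tab = pd.concat(frames)
        for (_, direction), cell in tab.groupby(["delta", "foil_direction"]):
            phat = (cell["choice"] == "target").mean()
            p = p_choose_target(cell["delta"].iloc[0], direction, params)
            se = np.sqrt(0.25 / len(cell))
            assert abs(phat - p) < 4 * se
            assert abs(p - 0.5) <= 0.25  # half the probability mass is guessing

    def test_search_accuracy_map_missing_distance(self, designs):
        params = ObserverParams(search_accuracy={15.0: 0.9})
        with pytest.raises(KeyError, match="search_accuracy"):
            simulate_dataset(designs["E1"], params, seed=0)

    def test_search_rate_tracks_map(self, designs):
        acc = {15.0: 0.95, 30.0: 0.85, 45.0: 0.8, 60.0: 0.75, 90.0: 0.7, 180.0: 0.65}
        params = ObserverParams(search_accuracy=acc)
        frames = [simulate_dataset(designs["E1"], params, seed=s) for s in range(20)]
        tab = pd.concat(frames)
        rates = tab.groupby("D")["search_correct"].mean()
        for D, p in acc.items():
            assert abs(rates[D] - p) < 3 * np.sqrt(p * (1 - p) / 1000)

    def test_e3_response_masks(self, designs):
        params = ObserverParams(search_accuracy=0.9)
        tab = simulate_dataset(designs["E3"], params, seed=1)
        search = tab["trial_kind"] == "search_report"
        assert tab.loc[search, "choice"].isna().all()
        assert tab.loc[search, "search_correct"].notna().all()
        assert tab.loc[~search, "choice"].notna().all()
        assert tab.loc[~search, "search_correct"].isna().all()

    def test_zero_bias_equalizes_foil_directions(self, designs):
        # without a bias the foil side is statistically irrelevant: both
        # directions share p = Phi(delta/(2 sigma)) > 0.5, hence equal
        # positive d' (choices still favor the true target)
        from attnwarp.sdt_model import summarize

        params = ObserverParams(bias=0.0, sigma=10.0)
        frames = [
            simulate_dataset(designs["E1"], params, seed=s, subject_id=s)
            for s in range(50)
        ]
        cells = summarize(pd.concat(frames))
        piv = cells.pivot_table(index="D", columns="foil_direction", values="dprime")
        np.testing.assert_allclose(piv["away"], piv["toward"], atol=0.25)
        assert (piv["away"] > 0).all() and (piv["toward"] > 0).all()


class TestSimulateCohort:
    def test_single_subject_reduces_to_simulate_dataset(self, designs):
        spec = CohortSpec(bias=7.0, sigma=9.0, search_accuracy=0.9)
        cohort = simulate_cohort(1, designs["E2"], spec, seed=13)
        child = cohort_child_seeds(13, 1)[1]
        params = ObserverParams(bias=7.0, sigma=9.0, search_accuracy=0.9)
        solo = simulate_dataset(
            designs["E2"], params, rng=np.random.default_rng(child), subject_id=0
        )
        pd.testing.assert_frame_equal(cohort, solo)

    def test_zero_spread_shares_parameters(self, designs):
        spec = CohortSpec(bias=7.0, sigma=9.0, bias_sd=0.0, sigma_sd=0.0)
        cohort = simulate_cohort(3, designs["E2"], spec, seed=4)
        children = cohort_child_seeds(4, 3)
        params = ObserverParams(bias=7.0, sigma=9.0)
        for i in range(3):
            mine = cohort[cohort["subject_id"] == i].reset_index(drop=True)
            solo = simulate_dataset(
                designs["E2"], params, rng=np.random.default_rng(children[i + 1]),
                subject_id=i,
            )
            pd.testing.assert_frame_equal(mine, solo)

    def test_deterministic(self, designs):
        spec = CohortSpec(bias=5.0, bias_sd=3.0, sigma=9.0, sigma_sd=1.0)
        a = simulate_cohort(5, designs["E1"], spec, seed=21)
        b = simulate_cohort(5, designs["E1"], spec, seed=21)
        pd.testing.assert_frame_equal(a, b)

    def test_fig1b_sign_pattern(self, designs):
        # biased cohort: positive d' for toward foils, negative for away, D=30
        from attnwarp.sdt_model import summarize

        spec = CohortSpec(bias=10.0, sigma=10.0, bias_sd=0.0)
        tab = simulate_cohort(30, designs["E1"], spec, seed=77)
        cells = summarize(tab)
        d30 = cells[cells["D"] == 30.0].set_index("foil_direction")
        assert d30.loc["toward", "dprime"] > 0
        assert d30.loc["away", "dprime"] < 0

    def test_truncation_keeps_bias_nonnegative(self, designs):
        spec = CohortSpec(bias=1.0, bias_sd=5.0, sigma=9.0)
        tab = simulate_cohort(12, designs["E2"], spec, seed=3)
        # away foils at delta=180 should never be preferred on average if b >= 0
        cells = tab[tab["delta"] == 180.0]
        assert (cells["choice"] == "target").mean() > 0.9

    def test_invalid(self, designs):
        with pytest.raises(ValueError):
            simulate_cohort(0, designs["E1"], CohortSpec(), seed=0)
        with pytest.raises(ValueError):
            CohortSpec(bias_sd=-1.0)
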