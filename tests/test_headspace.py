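"""Headspace equilibration: mole balance, round trips, replicate handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pondn2o import (
    ConcentrationResult,
    DissolvedGasSample,
    WaterState,
    back_calculate,
    equilibrium_concentration,
    fleet_uncertainty,
    forward_equilibrate,
    solubility_coefficient,
)
from pondn2o.gases import water_vapor_pressure
from pondn2o.headspace import read_headspace_csv

import oracles


def sample_with(ppm, air=0.33, temp=20.0, bottle=1.2, headspace=0.060):
    return DissolvedGasSample(
        site_id="s1",
        gas="N2O",
        headspace_ppm_replicates=tuple(np.atleast_1d(ppm)),
        air_ppm=air,
        equilibration_state=WaterState(temperature=temp),
        bottle_volume_l=bottle,
        headspace_volume_l=headspace,
    )


class TestMassBalance:
    def test_fixed_point_at_equilibrium(self, state20):
        """Water at equilibrium with the added air leaves the headspace
        reading unchanged and back-calculates to exactly C_eq."""
        res = back_calculate(sample_with(0.33))
        assert res.concentration_nm == pytest.approx(
            equilibrium_concentration("N2O", state20, 0.33), rel=1e-14
        )

    @pytest.mark.parametrize("c0", [0.5, 6.55, 42.0, 110.0])
    def test_round_trip(self, c0):
        template = sample_with(0.0)
        x = forward_equilibrate(c0, template)
        res = back_calculate(sample_with(x))
        assert res.concentration_nm == pytest.approx(c0, rel=1e-9)

    def test_matches_brute_force_mole_balance(self, rng):
        for _ in range(50):
            t = rng.uniform(5.0, 30.0)
            x_hs = rng.uniform(0.1, 10.0)
            air = rng.uniform(0.1, 2.0)
            mine = back_calculate(sample_with(x_hs, air=air, temp=t)).concentration_nm
            ref = oracles.headspace_back_calc(x_hs, air, t)
            assert mine == pytest.approx(ref, rel=1e-6)

    def test_monotone_in_headspace_ppm(self):
        c = [back_calculate(sample_with(x)).concentration_nm for x in (0.2, 0.4, 0.8)]
        assert c[0] < c[1] < c[2]

    def test_vanishing_headspace_limit(self, state20):
        """As the headspace volume shrinks, the back-calculated value tends
        to the final water-phase concentration K0 * p_final."""
        k0 = solubility_coefficient("N2O", state20).value
        p_dry = 1.0 - water_vapor_pressure(20.0)
        target = k0 * 0.5e-6 * p_dry * 1e9
        approx = back_calculate(sample_with(0.5, headspace=1e-9)).concentration_nm
        assert approx == pytest.approx(target, rel=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        c0=st.floats(0.1, 500.0),
        temp=st.floats(5.0, 30.0),
        air=st.floats(0.0, 3.0),
        headspace=st.floats(0.01, 0.5),
    )
    def test_inverse_identity_property(self, c0, temp, air, headspace):
        template = DissolvedGasSample(
            "p", "N2O", (0.0,), air, WaterState(temperature=temp),
            headspace_volume_l=headspace,
        )
        x = forward_equilibrate(c0, template)
        got = back_calculate(
            DissolvedGasSample(
                "p", "N2O", (x,), air, WaterState(temperature=temp),
                headspace_volume_l=headspace,
            )
        ).concentration_nm
        assert got == pytest.approx(c0, rel=1e-9)


class TestReplicates:
    def test_mean_and_sd(self):
        res = back_calculate(sample_with([0.4, 0.5]))
        a = back_calculate(sample_with(0.4)).concentration_nm
        b = back_calculate(sample_with(0.5)).concentration_nm
        assert res.concentration_nm == pytest.approx((a + b) / 2)
        assert res.uncertainty_nm == pytest.approx(np.std([a, b], ddof=1))

    def test_single_replicate_zero_sigma(self):
        assert back_calculate(sample_with(0.4)).uncertainty_nm == 0.0

    def test_negative_concentration_flagged_not_clamped(self):
        # headspace far below ambient air: water must have started negative
        res = back_calculate(sample_with(0.01, air=2.0))
        assert res.quality == "negative_concentration"
        assert res.concentration_nm < 0

    def test_invariants_rejected(self, state20):
        with pytest.raises(ValueError):
            DissolvedGasSample("x", "N2O", (), 0.33, state20)
        with pytest.raises(ValueError):
            DissolvedGasSample("x", "N2O", (-0.1,), 0.33, state20)
        with pytest.raises(ValueError):
            DissolvedGasSample("x", "N2O", (0.3,), 0.33, state20, headspace_volume_l=1.5)


class TestFleetUncertainty:
    def test_identical_replicates_zero(self):
        res = [back_calculate(sample_with([0.4, 0.4])) for _ in range(3)]
        assert fleet_uncertainty(res) == 0.0

    def test_single_site_identity(self, state20):
        r = ConcentrationResult("a", "N2O", 6.0, 1.25, 8.8)
        assert fleet_uncertainty([r]) == 1.25

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fleet_uncertainty([])

    def test_mean_recovers_generator_sigma(self, rng):
        """Fleet of sites whose replicate spread is drawn around a known
        sigma: the fleet mean lands near the generator value."""
        true_sigma = 1.25
        results = []
        for _ in range(400):
            reps = rng.normal(20.0, true_sigma, size=2)
            results.append(ConcentrationResult("s", "N2O", 20.0, float(np.std(reps, ddof=1)), 8.8))
        # E[sample sd of n=2 normal pairs] = sigma * sqrt(2/pi)
        expected = true_sigma * np.sqrt(2 / np.pi)
        assert fleet_uncertainty(results) == pytest.approx(expected, abs=0.1)


def test_csv_reader_groups_replicates(tmp_path):
    df = pd.DataFrame(
        {
            "site_id": ["a", "a", "b"],
            "gas": ["N2O"] * 3,
            "headspace_ppm": [0.4, 0.5, 0.6],
            "air_ppm": [0.33] * 3,
            "water_temp_c": [20.0] * 3,
        }
    )
    path = tmp_path / "hs.csv"
    df.to_csv(path, index=False)
    samples = read_headspace_csv(path)
    assert [s.site_id for s in samples] == ["a", "b"]
    assert samples[0].headspace_ppm_replicates == (0.4, 0.5)
    assert samples[0].bottle_volume_l == 1.2  # geometry defaults applied
    bad = tmp_path / "hs_bad.csv"
    df.drop(columns=["air_ppm"]).to_csv(bad, index=False)
    with pytest.raises(ValueError, match="air_ppm"):
        read_headspace_csv(bad)
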