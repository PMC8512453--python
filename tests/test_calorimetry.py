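"""Criterion lab arm: epoching, MET derivation, classification, energy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wearval as wv
from wearval.calorimetry import (
    KCAL_PER_L_O2,
    aggregate_breaths,
    assign_segments,
    classify_epochs,
    classify_met_intensity,
    gross_active_aee,
)
from wearval.types import ProtocolSegment, RestingRate, SubjectProfile


def breaths_df(times, rates):
    rates = np.broadcast_to(rates, np.shape(times)).astype(float)
    return pd.DataFrame(
        {"time_s": times, "vo2_ml_min": rates, "vco2_ml_min": 0.85 * rates}
    )


class TestAggregateBreaths:
    def test_constant_signal(self):
        df = aggregate_breaths(breaths_df(np.arange(2.0, 62.0, 2.0), 300.0))
        assert df["vo2_ml_min"].iloc[0] == pytest.approx(300.0)

    def test_equal_weight_halves(self):
        df = aggregate_breaths(breaths_df([30.0, 60.0], [200.0, 400.0]))
        assert df["vo2_ml_min"].iloc[0] == pytest.approx(300.0)

    def test_agrees_with_quadrature_oracle(self, rng):
        times = np.cumsum(rng.uniform(0.5, 4.0, size=200))
        rates = rng.uniform(100.0, 900.0, size=200)
        df = aggregate_breaths(breaths_df(times, rates), epoch_s=60.0)
        # oracle: integrate the backward-interval step function per epoch
        starts = np.concatenate([[0.0], times[:-1]])
        for k, row in df.iterrows():
            e0, e1 = row["epoch_start_s"], row["epoch_start_s"] + 60.0
            num = den = 0.0
            for s, e, r in zip(starts, times, rates):
                ov = min(e, e1) - max(s, e0)
                if ov > 0:
                    num += r * ov
                    den += ov
            if den > 0:
                assert row["vo2_ml_min"] == pytest.approx(num / den, abs=1e-9)

    def test_uncovered_epoch_is_missing_not_zero(self):
        # a 190-s breath gap leaves the middle epoch uncovered -> NaN
        gap = aggregate_breaths(breaths_df([10.0, 200.0], [300.0, 300.0]), epoch_s=60.0)
        assert np.isnan(gap["vo2_ml_min"].iloc[1])
        assert not (gap["vo2_ml_min"].fillna(-1) == 0).any()

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="row"):
            aggregate_breaths(breaths_df([10.0, 5.0], 300.0))

    def test_nonpositive_epoch_rejected(self):
        with pytest.raises(ValueError):
            aggregate_breaths(breaths_df([10.0], 300.0), epoch_s=0.0)


class TestRestingMet:
    prot = [ProtocolSegment("rest", 0.0, 120.0, "rest", 1.0)]

    def epochs(self, rates):
        return pd.DataFrame(
            {"epoch_start_s": 60.0 * np.arange(len(rates)), "vo2_ml_min": rates}
        )

    def test_arithmetic_mean(self):
        r = wv.compute_resting_met(self.epochs([4.0, 4.4]), self.prot, weight_kg=1.0)
        assert r.vo2_per_kg_1met == pytest.approx(4.2)
        assert r.n_epochs_used == 2

    def test_single_epoch_identity(self):
        r = wv.compute_resting_met(self.epochs([5.0]), self.prot, weight_kg=1.0)
        assert r.vo2_per_kg_1met == pytest.approx(5.0)

    def test_simulator_round_trip(self, subject30, noiseless_params):
        noiseless_params.resting_vo2_per_kg = 5.2
        prot = wv.make_lab_protocol()
        breaths = wv.simulate_gas_exchange(subject30, prot, noiseless_params)
        epochs = aggregate_breaths(breaths)
        r = wv.compute_resting_met(epochs, prot, subject30.weight_kg)
        assert r.vo2_per_kg_1met == pytest.approx(5.2, abs=1e-9)

    def test_missing_rest_segment_rejected(self):
        with pytest.raises(ValueError):
            wv.compute_resting_met(
                self.epochs([5.0]),
                [ProtocolSegment("a", 0.0, 120.0, "activity", 3.0)],
                weight_kg=1.0,
            )


class TestMets:
    def test_formula(self):
        epochs = pd.DataFrame({"epoch_start_s": [0.0], "vo2_ml_min": [300.0]})
        out = wv.mets_from_vo2(epochs, RestingRate(5.0, 1), weight_kg=30.0)
        assert out["met"].iloc[0] == pytest.approx(2.0)

    def test_resting_rate_is_one_met(self):
        epochs = pd.DataFrame({"epoch_start_s": [0.0], "vo2_ml_min": [5.0 * 30.0]})
        out = wv.mets_from_vo2(epochs, RestingRate(5.0, 1), weight_kg=30.0)
        assert out["met"].iloc[0] == pytest.approx(1.0)

    def test_halves_when_weight_doubles(self):
        epochs = pd.DataFrame({"epoch_start_s": [0.0], "vo2_ml_min": [300.0]})
        m1 = wv.mets_from_vo2(epochs, RestingRate(5.0, 1), 30.0)["met"].iloc[0]
        m2 = wv.mets_from_vo2(epochs, RestingRate(5.0, 1), 60.0)["met"].iloc[0]
        assert m2 == pytest.approx(m1 / 2.0)

    def test_zero_weight_rejected(self):
        epochs = pd.DataFrame({"epoch_start_s": [0.0], "vo2_ml_min": [300.0]})
        with pytest.raises(ValueError):
            wv.mets_from_vo2(epochs, RestingRate(5.0, 1), 0.0)


class TestClassification:
    @pytest.mark.parametrize(
        "met,expected",
        [(4.0, "MPA"), (1.5, "SED"), (6.0, "VPA"), (2.95, "LPA"),
         (0.0, "SED"), (1.50001, "LPA"), (3.0, "MPA"), (5.999, "MPA"), (12.0, "VPA")],
    )
    def test_band_anchors(self, met, expected):
        assert classify_met_intensity(met) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_met_intensity(-0.1)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.0, max_value=20.0, allow_nan=False))
    def test_partition_is_exhaustive_and_exclusive(self, met):
        assert classify_met_intensity(met) in ("SED", "LPA", "MPA", "VPA")


class TestMvpaMinutes:
    def make_epochs(self, intensities, category="activity"):
        n = len(intensities)
        return pd.DataFrame(
            {
                "epoch_start_s": 60.0 * np.arange(n),
                "vo2_ml_min": np.full(n, 400.0),
                "segment_category": [category] * n,
                "intensity": intensities,
            }
        )

    def test_empty_case(self):
        assert wv.mvpa_minutes(self.make_epochs(["SED", "LPA"])) == 0.0

    def test_count_times_length(self):
        ep = self.make_epochs(["MPA"] * 20 + ["LPA"] * 3)
        assert wv.mvpa_minutes(ep) == 20.0

    def test_transition_epochs_excluded(self):
        ep = pd.concat(
            [self.make_epochs(["MPA"] * 5), self.make_epochs(["MPA"] * 2, "transition")]
        )
        assert wv.mvpa_minutes(ep) == 5.0

    def test_unclassified_rejected(self):
        ep = self.make_epochs(["MPA", None])
        with pytest.raises(ValueError):
            wv.mvpa_minutes(ep)


class TestEnergy:
    @pytest.mark.parametrize("liters,kcal", [(1.0, 4.867), (0.0, 0.0), (2.0, 9.734)])
    def test_caloric_equivalent(self, liters, kcal):
        assert wv.vo2_to_kcal(liters) == pytest.approx(kcal)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            wv.vo2_to_kcal(-1.0)

    def epochs(self, rates_ml_min, category="activity"):
        n = len(rates_ml_min)
        return pd.DataFrame(
            {
                "epoch_start_s": 60.0 * np.arange(n),
                "vo2_ml_min": np.asarray(rates_ml_min, dtype=float),
                "segment_category": [category] * n,
            }
        )

    def test_single_active_minute(self):
        gross, active = gross_active_aee(self.epochs([1000.0]))
        assert gross == pytest.approx(4.867)
        assert active == 1.0

    def test_no_active_epochs(self):
        gross, active = gross_active_aee(self.epochs([1000.0] * 5, category="rest"))
        assert gross == 0.0 and active == 0.0

    def test_constant_rate_forty_minutes(self):
        gross, active = gross_active_aee(self.epochs([500.0] * 40))
        assert gross == pytest.approx(0.5 * 40 * 4.867)
        assert active == 40.0

    def test_missing_unit_conversion_inflates_1000x(self):
        # guard: feeding L/min-scaled rates as if mL/min changes results 1000x
        gross_ml, _ = gross_active_aee(self.epochs([500.0] * 10))
        gross_wrong, _ = gross_active_aee(self.epochs([500.0 * 1000.0] * 10))
        assert gross_wrong == pytest.approx(1000.0 * gross_ml)


class TestSchofield:
    def test_boy_band_3_10(self):
        s = SubjectProfile("b", "male", 9.0, 135.0, 32.0)
        assert wv.schofield_bmr(s) == pytest.approx(22.7 * 32 + 495)

    def test_girl_band_3_10(self):
        s = SubjectProfile("g", "female", 9.0, 135.0, 32.0)
        assert wv.schofield_bmr(s) == pytest.approx(22.5 * 32 + 499)

    def test_adolescent_bands(self):
        boy = SubjectProfile("b", "male", 12.0, 150.0, 40.0)
        girl = SubjectProfile("g", "female", 12.0, 150.0, 40.0)
        assert wv.schofield_bmr(boy) == pytest.approx(17.5 * 40 + 651)
        assert wv.schofield_bmr(girl) == pytest.approx(12.2 * 40 + 746)

    def test_invalid_subjects_rejected(self):
        with pytest.raises(ValueError):
            SubjectProfile("x", "male", 9.0, 135.0, 0.0)
        with pytest.raises(ValueError):
            SubjectProfile("x", "male", 2.0, 95.0, 14.0)


class TestNetAee:
    def test_one_kcal_per_minute_basal(self):
        assert wv.net_aee(100.0, 1440.0, 40.0) == pytest.approx(60.0)

    def test_zero_active_minutes(self):
        assert wv.net_aee(100.0, 1440.0, 0.0) == pytest.approx(100.0)

    def test_negative_net_warns_not_clamps(self):
        with pytest.warns(UserWarning, match="negative"):
            net = wv.net_aee(10.0, 1440.0, 40.0)
        assert net == pytest.approx(-30.0)


class TestLabRoundTrip:
    def test_noiseless_session_recovers_truth(self, subject30, noiseless_params):
        prot = wv.make_lab_protocol()
        breaths = wv.simulate_gas_exchange(subject30, prot, noiseless_params)
        epochs, lab = wv.process_lab_session(subject30, breaths, prot)
        truth = wv.lab_truth(subject30, prot, noiseless_params)
        assert lab.mvpa_min == truth.true_mvpa_min
        assert abs(lab.net_aee_kcal - truth.true_net_aee_kcal) < 0.1
        # invariant: net = gross - (bmr/1440) * active minutes
        assert lab.net_aee_kcal == pytest.approx(
            lab.gross_aee_kcal - lab.bmr_kcal_day / 1440.0 * lab.active_minutes
        )

    def test_epoch_met_equals_target_in_activity_segments(
        self, subject30, noiseless_params
    ):
        prot = wv.make_lab_protocol()
        breaths = wv.simulate_gas_exchange(subject30, prot, noiseless_params)
        epochs, _ = wv.process_lab_session(subject30, breaths, prot)
        for seg in prot:
            if seg.category != "activity":
                continue
            inside = (epochs["epoch_start_s"] >= seg.start_s) & (
                epochs["epoch_start_s"] + 60.0 <= seg.end_s
            )
            assert np.allclose(epochs.loc[inside, "met"], seg.target_met, atol=1e-9)

    def test_halving_epoch_length_preserves_mvpa(self, subject30, noiseless_params):
        prot = wv.make_lab_protocol()
        breaths = wv.simulate_gas_exchange(subject30, prot, noiseless_params)
        _, lab60 = wv.process_lab_session(subject30, breaths, prot, epoch_s=60.0)
        _, lab30 = wv.process_lab_session(subject30, breaths, prot, epoch_s=30.0)
        assert lab30.mvpa_min == lab60.mvpa_min

    def test_epoch_assignment_majority_rule(self):
        prot = [
            ProtocolSegment("rest", 0.0, 90.0, "rest", 1.0),
            ProtocolSegment("act", 90.0, 240.0, "activity", 4.0),
        ]
        ep = pd.DataFrame({"epoch_start_s": [0.0, 60.0, 120.0], "vo2_ml_min": 300.0})
        out = assign_segments(ep, prot)
        # epoch [60, 120): 30 s rest vs 30 s activity -> tie goes to earlier
        assert list(out["segment_category"]) == ["rest", "rest", "activity"]
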