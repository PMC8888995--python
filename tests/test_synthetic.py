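"""Generator contracts: motion classes, fields, plates, dose-response."""

import numpy as np
import pandas as pd
import pytest

from spermscreen.dose_response import DoseSeries, dilution_series, four_pl
from spermscreen.kinematics import compute_vcl, compute_vsl, kinematics_table
from spermscreen.synthetic import (
    CompoundEffectModel,
    MotilityClassParams,
    PlateSimConfig,
    PopulationConfig,
    simulate_dose_response,
    simulate_field,
    simulate_plate,
    simulate_track,
    true_percent_of_control,
)


class TestSimulateTrack:
    def test_immotile_track_with_no_noise_is_a_single_point(self):
        p = MotilityClassParams("IM", 0.0, 0.0, 0.0, 0.0)
        t = simulate_track(p, 20, 25.0, seed=1)
        assert np.ptp(t.x) == 0 and np.ptp(t.y) == 0
        assert compute_vcl(t, 25.0) == 0.0

    def test_straight_line_limit_vcl_equals_vsl(self):
        p = MotilityClassParams("PM", 100.0, 0.0, 1.0, 0.0)
        t = simulate_track(p, 5, 1.0, seed=2)
        steps = np.hypot(np.diff(t.x), np.diff(t.y))
        assert np.allclose(steps, 100.0)
        assert compute_vcl(t, 1.0) == pytest.approx(100.0)
        assert compute_vsl(t, 1.0) == pytest.approx(100.0, rel=1e-12)

    def test_mean_step_speed_matches_configured_distribution(self):
        # 10,000 tracks at speed_mean 50 sd 10: Monte-Carlo mean within 1%
        p = MotilityClassParams("PM", 50.0, 10.0, 0.9, 0.0)
        pop = PopulationConfig(
            n_cells=10_000, class_fractions=(0.0, 0.0, 1.0), n_frames=10, seed=11
        )
        f = simulate_field(pop, class_params={"IM": p, "NPM": p, "PM": p})
        t = f.truth.sort_values(["track_id", "frame"])
        xy = t[["x_um", "y_um"]].to_numpy()
        step = np.hypot(*np.diff(xy, axis=0).T)
        seam = np.diff(t["track_id"].to_numpy()) != 0
        speeds = step[~seam] * pop.frame_rate
        assert abs(speeds.mean() - 50.0) / 50.0 < 0.01

    def test_determinism(self):
        p = MotilityClassParams("NPM", 30.0, 10.0, 0.3, 0.5)
        a = simulate_track(p, 30, 25.0, seed=7)
        b = simulate_track(p, 30, 25.0, seed=7)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(speed_mean=-1.0),
            dict(speed_sd=-0.1),
            dict(directional_persistence=1.5),
            dict(positional_noise_sd=float("nan")),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        base = dict(class_label="PM", speed_mean=50.0, speed_sd=5.0,
                    directional_persistence=0.9, positional_noise_sd=0.2)
        with pytest.raises(ValueError):
            MotilityClassParams(**{**base, **bad})

    def test_too_short_clip_rejected(self):
        p = MotilityClassParams("PM", 50.0, 5.0, 0.9, 0.0)
        with pytest.raises(ValueError):
            simulate_track(p, 1, 25.0, seed=0)


class TestSimulateField:
    def test_all_immotile_field(self):
        pop = PopulationConfig(
            n_cells=100, class_fractions=(1.0, 0.0, 0.0),
            detection_dropout_prob=0.0, seed=5,
        )
        f = simulate_field(pop)
        assert f.truth["track_id"].nunique() == 100
        assert (f.track_classes == "IM").all()
        assert len(f.detections) == 100 * pop.n_frames

    def test_dropout_fraction_matches_binomial(self):
        pop = PopulationConfig(n_cells=1000, n_frames=50,
                               detection_dropout_prob=0.1, seed=6)
        f = simulate_field(pop)
        n_total = 1000 * 50
        realized = 1.0 - len(f.detections) / n_total
        sd = np.sqrt(0.1 * 0.9 / n_total)
        assert abs(realized - 0.1) < 3 * sd

    def test_class_counts_match_multinomial(self):
        pop = PopulationConfig(n_cells=10_000, class_fractions=(0.3, 0.3, 0.4), seed=8)
        f = simulate_field(pop)
        counts = f.track_classes.value_counts()
        for label, p in zip(("IM", "NPM", "PM"), (0.3, 0.3, 0.4)):
            sd = np.sqrt(10_000 * p * (1 - p))
            assert abs(counts[label] - 10_000 * p) < 3 * sd

    def test_determinism_bit_identical(self):
        pop = PopulationConfig(n_cells=50, detection_dropout_prob=0.05, seed=9)
        a, b = simulate_field(pop), simulate_field(pop)
        assert a.detections.equals(b.detections)
        assert np.array_equal(a.truth_track_id, b.truth_track_id)

    def test_truth_sidecar_aligned(self):
        pop = PopulationConfig(n_cells=20, detection_dropout_prob=0.2, seed=10)
        f = simulate_field(pop)
        side = f.truth_sidecar()
        assert len(side) == len(f.detections)
        merged = f.detections.assign(track_id=side["track_id"].to_numpy()).merge(
            f.truth, on=["track_id", "frame"], suffixes=("", "_t")
        )
        assert np.allclose(merged["x_um"], merged["x_um_t"])


class TestSimulatePlate:
    def test_sixteen_control_wells_flagged(self):
        plate = simulate_plate(PlateSimConfig(seed=1))
        assert (plate.layout["role"] == "control").sum() == 16

    def test_over_capacity_rejected(self):
        with pytest.raises(ValueError):
            PlateSimConfig(n_control_wells=16, n_compound_wells=380)

    def test_control_wells_share_null_population(self, class_params):
        cfg = PlateSimConfig(
            n_compound_wells=4,
            effects={"CPD0001": CompoundEffectModel(max_speed_multiplier=2.0)},
            population=PopulationConfig(n_cells=50, seed=0),
            seed=3,
        )
        plate = simulate_plate(cfg)
        controls = plate.layout.loc[plate.layout.role == "control", "well"]
        from spermscreen.synthetic import NULL_EFFECT
        assert all(plate.effect_for(w) == NULL_EFFECT for w in controls)

    def test_saturating_enhancer_shifts_median_by_multiplier(self, class_params):
        # closed-form expectation: scaling motile speeds by 1.5 scales the
        # well's median VCL by 1.5 when the median lies in the motile bulk
        effect = CompoundEffectModel(ec50_true=1e-4, hill_true=1.0,
                                     max_speed_multiplier=1.5)
        noiseless = {
            k: MotilityClassParams(k, v.speed_mean, v.speed_sd,
                                   v.directional_persistence, 0.0)
            for k, v in class_params.items()
        }
        cfg = PlateSimConfig(
            n_compound_wells=1, effects={"CPD0001": effect},
            population=PopulationConfig(n_cells=4000, seed=2), seed=2,
        )
        plate = simulate_plate(cfg, class_params=noiseless)
        cpd_well = plate.layout.loc[plate.layout.role == "compound", "well"].iloc[0]
        ctrl_well = plate.layout.loc[plate.layout.role == "control", "well"].iloc[0]
        med = {}
        for w in (cpd_well, ctrl_well):
            kin = kinematics_table(plate.field(w, 0).truth, 25.0)
            med[w] = kin["VCL"].median()
        assert med[cpd_well] / med[ctrl_well] * 100 == pytest.approx(150.0, rel=0.05)

    def test_true_percent_of_control_closed_form(self):
        effect = CompoundEffectModel(ec50_true=0.5, hill_true=1.0,
                                     max_speed_multiplier=1.5)
        assert true_percent_of_control(effect, 0.0) == 100.0
        assert true_percent_of_control(effect, 0.5) == pytest.approx(125.0)
        assert true_percent_of_control(effect, 1e9) == pytest.approx(150.0, abs=1e-3)


class TestSimulateDoseResponse:
    def test_null_compound_scatters_around_100(self):
        null = CompoundEffectModel(max_speed_multiplier=1.0)
        df = simulate_dose_response(null, noise_sd=5.0, seed=3)
        assert (df["true_percent_of_control"] == 100.0).all()
        assert abs(df["percent_of_control"].mean() - 100.0) < 5.0

    def test_top_dose_response_near_model_plateau(self):
        effect = CompoundEffectModel(ec50_true=0.5, hill_true=1.0,
                                     max_speed_multiplier=1.5)
        df = simulate_dose_response(effect, noise_sd=2.0, seed=4,
                                    n_replicate_experiments=2)
        top = df[df["concentration_uM"] == 10.0]
        expected = float(four_pl(10.0, 100.0, 150.0, 0.5, 1.0))
        assert top["true_percent_of_control"].iloc[0] == pytest.approx(expected)
        assert abs(top["percent_of_control"].mean() - expected) < 4 * 2.0

    def test_experiments_have_independent_noise(self):
        effect = CompoundEffectModel()
        df = simulate_dose_response(effect, seed=5)
        e1 = df[df.experiment_id == 1]["percent_of_control"].to_numpy()
        e2 = df[df.experiment_id == 2]["percent_of_control"].to_numpy()
        assert not np.allclose(e1, e2)

    def test_rejects_zero_experiments(self):
        with pytest.raises(ValueError):
            simulate_dose_response(CompoundEffectModel(), n_replicate_experiments=0)
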