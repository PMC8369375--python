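"""Generator contracts: template geometry, truth identities, determinism."""

import numpy as np
import pytest

from pttbp.session import validate_session
from pttbp.simulate import (
    CohortGroupSpec,
    GroundTruthLaw,
    NoiseModel,
    TemplateConfig,
    compact_schedule,
    default_law,
    make_beat_templates,
    random_law,
    simulate_cohort,
    simulate_session,
)

SHORT = compact_schedule(15.0, tasks=("sit_baseline", "stand_baseline", "rest"))


class TestTemplates:
    def test_ppg_minimum_precedes_max_upstroke(self):
        tpl = make_beat_templates()
        assert np.argmin(tpl.ppg) < np.argmax(np.diff(tpl.ppg))

    def test_scg_first_prominent_peak_at_ao_offset(self):
        tpl = make_beat_templates(TemplateConfig(scg_ao_offset_s=0.04))
        peak_t = np.argmax(tpl.scg) / tpl.fs
        assert abs(peak_t - 0.04) <= 0.001

    def test_abp_mean_strictly_between_extrema(self):
        tpl = make_beat_templates(TemplateConfig(abp_min=80.0, abp_max=120.0))
        assert tpl.abp.min() == pytest.approx(80.0)
        assert tpl.abp.max() == pytest.approx(120.0)
        assert 80.0 < tpl.abp.mean() < 120.0

    def test_nonphysical_config_rejected(self):
        with pytest.raises(ValueError, match="R-R"):
            make_beat_templates(TemplateConfig(ppg_rise_s=0.4, ppg_fall_s=0.5))


class TestLaw:
    def test_bp_ordering_and_component_consistency(self):
        law = default_law()
        for task in law.tasks:
            sbp, dbp, map_ = law.task_bp(task)
            assert dbp <= map_ <= sbp
            # the single task PTT reproduces all three components exactly
            for comp, bp in (("SBP", sbp), ("DBP", dbp), ("MAP", map_)):
                assert law.k1[comp] / law.ptt(task) + law.k2[comp] == pytest.approx(bp)

    def test_higher_bp_means_lower_ptt(self):
        law = default_law()
        by_dbp = sorted(law.tasks, key=lambda t: law.bp("DBP", t))
        ptts = [law.ptt(t) for t in by_dbp]
        assert all(a > b for a, b in zip(ptts, ptts[1:]))

    def test_invalid_ptt_window_rejected(self):
        with pytest.raises(ValueError, match="PTT"):
            GroundTruthLaw(
                k1={"DBP": 2.0, "MAP": 2.8, "SBP": 3.6},
                k2={"DBP": 60.0, "MAP": 75.0, "SBP": 92.0},
                task_invptt={"rest": 30.0},  # PTT 33 ms: non-physiologic
            )

    def test_random_law_respects_ranges_and_map_span(self, rng):
        for _ in range(25):
            law = random_law(rng)
            assert 1.0 <= law.k1["DBP"] <= 3.0
            assert 50.0 <= law.k2["DBP"] <= 75.0
            maps = [law.bp("MAP", t) for t in law.tasks]
            assert max(maps) - min(maps) >= 25.0
            assert all(0.05 < law.ptt(t) < 0.5 for t in law.tasks)


class TestSimulateSession:
    def test_truth_identities_hold_exactly(self):
        law = default_law()
        for seed in (0, 3):
            _, rec = simulate_session(law, NoiseModel(), schedule=SHORT, seed=seed)
            b = rec.beats
            np.testing.assert_array_equal(b["ao_time_s"], b["r_time_s"] + law.pep_s)
            np.testing.assert_array_equal(b["foot_time_s"], b["ao_time_s"] + b["ptt_s"])
            np.testing.assert_array_equal(b["pat_s"], b["foot_time_s"] - b["r_time_s"])

    def test_seed_determinism(self):
        law = default_law()
        s1, _ = simulate_session(law, NoiseModel(), schedule=SHORT, seed=1)
        s1b, _ = simulate_session(law, NoiseModel(), schedule=SHORT, seed=1)
        s2, _ = simulate_session(law, NoiseModel(), schedule=SHORT, seed=2)
        for name in s1.channels:
            np.testing.assert_array_equal(s1.channels[name].samples, s1b.channels[name].samples)
        assert not np.array_equal(s1.channel("ppg_ir").samples, s2.channel("ppg_ir").samples)

    def test_output_passes_validation(self):
        for seed in (0, 7):
            session, _ = simulate_session(default_law(), NoiseModel(), schedule=SHORT, seed=seed)
            assert validate_session(session) == []

    def test_reference_channels_carry_the_lag(self):
        session, rec = simulate_session(
            default_law(), NoiseModel.zero(), schedule=SHORT, seed=1, lag_samples=250
        )
        ecg_w = session.channel("ecg_wearable").samples
        ecg_r = session.channel("ecg_ref").samples
        np.testing.assert_allclose(ecg_r[250:], ecg_w[:-250], atol=1e-12)

    def test_too_short_task_rejected(self):
        with pytest.raises(ValueError, match="12 beats"):
            simulate_session(
                default_law(), NoiseModel(), schedule=compact_schedule(5.0), seed=0
            )

    def test_unknown_task_rejected(self):
        law = default_law(task_invptt={"rest": 5.0})
        with pytest.raises(ValueError, match="no PTT"):
            simulate_session(law, NoiseModel(), schedule=SHORT, seed=0)


class TestNoiseModel:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(channel_noise_sd={"ppg": -1.0})
        with pytest.raises(ValueError):
            NoiseModel(ppg_amplitude_scale={"ppg_ir": 1.5})

    def test_wavelength_snr_ordering(self):
        """With a common noise floor the amplitude scales order the SNR
        as IR > red > green."""
        nm = NoiseModel()
        assert (
            nm.ppg_amplitude_scale["ppg_ir"]
            > nm.ppg_amplitude_scale["ppg_red"]
            > nm.ppg_amplitude_scale["ppg_green"]
        )


class TestSimulateCohort:
    def test_obesity_class_matches_bmi_rule(self):
        specs = [CohortGroupSpec(name="mix", bmi_mean=30.0, bmi_sd=4.0)]
        _, table, _ = simulate_cohort(specs, 40, seed=3, signals=False)
        for _, row in table.iterrows():
            assert (row["obesity_class"] != "nonobese") == (row["bmi"] >= 30.0)

    def test_rejects_empty_inputs(self):
        with pytest.raises(ValueError):
            simulate_cohort([], 5)
        with pytest.raises(ValueError):
            simulate_cohort([CohortGroupSpec(name="a")], 0)

    def test_truth_table_has_coefficients_per_component(self):
        _, table, _ = simulate_cohort([CohortGroupSpec(name="a")], 3, seed=0, signals=False)
        assert {"K1_DBP", "K2_DBP", "K1_MAP", "K1_SBP"} <= set(table.columns)
        assert len(table) == 3
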