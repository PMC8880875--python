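"""Parameter types, validation, defaults and configuration round-trips."""

import numpy as np
import pytest
import yaml

import mdma_cea as m
from mdma_cea.params import DEFAULT_CLINICIAN_BREAKDOWN, _BASE_CONFIG


class TestDefaults:
    def test_default_params_match_published_inputs(self, base):
        """The bundled base case carries every published model input exactly."""
        assert base.intake.counts.tolist() == [0, 0, 0, 714, 286]
        assert base.followup.counts.tolist() == [333, 262, 262, 119, 24]
        assert base.intake.total == base.followup.total == base.cohort_size == 1000
        assert base.intervention.total == 11_537
        assert base.costs.mean.tolist() == [5_032, 10_118, 15_177, 20_236, 24_283]
        assert base.costs.sd.tolist() == [712, 1_431, 2_146, 2_862, 3_434]
        assert base.rr.mean.tolist() == [1.00, 1.74, 2.05, 2.51, 2.76]
        assert base.rr.sd.tolist() == [0.0, 0.70, 0.80, 1.10, 1.25]
        assert base.utilities.values.tolist() == [0.90, 0.83, 0.74, 0.61, 0.37]
        assert base.utilities.relative_range == 0.10
        assert (base.mean_age, base.age_sd) == (41.0, 11.9)
        assert (base.discount_rate, base.discount_rate_sd) == (0.03, 0.0034)
        assert base.horizon == 30
        assert base.ramp == (0.0, 0.25, 0.50, 0.75, 1.00)
        assert base.progression_rate_range == (0.05, 0.15)
        assert base.progression_start == 5
        assert base.life_table.qx_at(41.0) == pytest.approx(0.0020, abs=1e-15)

    def test_bundled_config_file_equals_in_code_defaults(self, base, tmp_path):
        from importlib.resources import files

        cfg = files("mdma_cea").joinpath("data/base_case.yaml")
        path = tmp_path / "base.yaml"
        path.write_text(cfg.read_text())
        loaded = m.load_params(path)
        np.testing.assert_array_equal(loaded.costs.mean, base.costs.mean)
        np.testing.assert_array_equal(loaded.intake.counts, base.intake.counts)
        assert loaded.ramp == base.ramp


class TestConfigIO:
    def test_round_trip_is_bit_equal(self, tmp_path):
        params = m.random_config(17)
        cfg = tmp_path / "cfg.yaml"
        m.write_params(params, cfg, life_table_path=tmp_path / "lt.csv")
        again = m.load_params(cfg)
        for arr in ("mean", "sd"):
            np.testing.assert_array_equal(getattr(again.costs, arr), getattr(params.costs, arr))
            np.testing.assert_array_equal(getattr(again.rr, arr), getattr(params.rr, arr))
        np.testing.assert_array_equal(again.utilities.values, params.utilities.values)
        np.testing.assert_array_equal(again.intake.counts, params.intake.counts)
        np.testing.assert_array_equal(again.followup.counts, params.followup.counts)
        assert again.intervention == params.intervention
        assert again.ramp == params.ramp
        assert (again.cohort_size, again.horizon) == (params.cohort_size, params.horizon)
        assert (again.discount_rate, again.mean_age) == (params.discount_rate, params.mean_age)
        np.testing.assert_array_equal(again.life_table.qx, params.life_table.qx)

    def test_missing_optional_keys_fill_with_defaults(self, tmp_path):
        cfg = tmp_path / "partial.yaml"
        cfg.write_text("cohort_size: 1000\n")  # everything else defaulted
        params = m.load_params(cfg)
        assert params.ramp == (0.0, 0.25, 0.50, 0.75, 1.00)
        assert params.intervention.total == 11_537

    def test_unknown_key_is_named_in_the_error(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("cohort_sise: 1000\n")
        with pytest.raises(m.ValidationError, match="cohort_sise"):
            m.load_params(cfg)

    def test_malformed_yaml_raises_parse_error(self, tmp_path):
        cfg = tmp_path / "broken.yaml"
        cfg.write_text("a: [unclosed\n")
        with pytest.raises(m.ValidationError):
            m.load_params(cfg)

    def test_validation_reports_every_failure_at_once(self, tmp_path):
        bad = dict(_BASE_CONFIG)
        bad = yaml.safe_load(yaml.safe_dump(bad))
        bad["severity_at_intake"] = {
            "asymptomatic": 0, "mild": 0, "moderate": 0, "severe": -1, "extreme": 286,
        }
        bad["discount_rate"] = 1.5
        cfg = tmp_path / "multi.yaml"
        cfg.write_text(yaml.safe_dump(bad))
        with pytest.raises(m.ValidationError) as err:
            m.load_params(cfg)
        assert len(err.value.problems) >= 3  # negativity, sum-mismatch, discount

    def test_count_sum_must_equal_cohort_size(self, base):
        off = base.replace(intake=m.SeverityDistribution([0, 0, 0, 714, 285]))
        with pytest.raises(m.ValidationError, match="cohort size"):
            off.validate()


class TestInterventionCost:
    @pytest.mark.parametrize(
        "components, expected",
        [
            ((9_828, 909, 800), 11_537.0),
            ((0, 0, 0), 0.0),
            ((9_828 * 1.3, 909 * 1.3, 800 * 1.3), 14_998.1),  # +30% bound
        ],
    )
    def test_total_is_exact_component_sum(self, components, expected):
        c = m.InterventionCost(*components)
        assert m.total_intervention_cost(c) == pytest.approx(expected, abs=1e-9)

    def test_negative_component_rejected(self):
        with pytest.raises(m.ValidationError, match="therapists"):
            m.total_intervention_cost(m.InterventionCost(therapists=-1))

    def test_component_shares(self):
        c = m.InterventionCost()
        shares = m.cost_component_shares(c)
        assert shares["therapists"] == pytest.approx(9_828 / 11_537)
        assert shares["non_therapist"] == pytest.approx(1_709 / 11_537)
        assert shares["therapists"] + shares["non_therapist"] == pytest.approx(1.0)

    def test_clinician_breakdown_decomposes_the_therapist_share(self):
        c = m.InterventionCost()
        shares = m.cost_component_shares(c, DEFAULT_CLINICIAN_BREAKDOWN)
        sub = [shares[k] for k in DEFAULT_CLINICIAN_BREAKDOWN]
        assert sum(sub) == pytest.approx(shares["therapists"])
        # adding back the published clinician screening-time slice of the
        # screening-lab component reproduces the ~90.7% clinician total
        assert shares["therapists"] + 0.056 == pytest.approx(0.907, abs=0.002)

    def test_zero_total_share_is_an_error(self):
        with pytest.raises(m.ValidationError, match="zero"):
            m.cost_component_shares(m.InterventionCost(0, 0, 0))

    def test_zero_therapist_share(self):
        shares = m.cost_component_shares(m.InterventionCost(0, 909, 800))
        assert shares["therapists"] == 0.0


class TestLifeTable:
    def test_csv_round_trip(self, tmp_path, base):
        p = tmp_path / "lt.csv"
        base.life_table.to_csv(p)
        again = m.LifeTable.from_csv(p)
        np.testing.assert_allclose(again.qx, base.life_table.qx)

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "lt.csv"
        p.write_text("age,rate\n41,0.002\n")
        with pytest.raises(m.ValidationError, match="age,qx"):
            m.LifeTable.from_csv(p)

    def test_anchor_outside_ten_percent_fails_validation(self):
        lt = m.make_life_table(m.GompertzParams.from_anchor(qx_at_ref=0.0030))
        assert any("age 41" in p for p in lt.problems())

    def test_lookup_clamps_to_table_ends(self, base):
        lt = base.life_table
        assert lt.qx_at(200.0) == lt.qx[-1]
        assert lt.qx_at(-5.0) == lt.qx[0]
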