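"""Input derivation arithmetic and configuration loading."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lusucea.params import (
    ProcedureMixEntry,
    dump_parameters,
    get_param,
    load_parameters,
    median_survival_to_annual_mortality,
    odds_ratio_to_probability,
    per_day_ae_risk,
    probability_to_odds_ratio,
    pt_cost_per_day,
    set_param,
    weighted_procedure_cost,
)

probs = st.floats(min_value=1e-6, max_value=1 - 1e-6)
odds_ratios = st.floats(min_value=1e-4, max_value=1e4)


class TestOddsRatioToProbability:
    @pytest.mark.parametrize(
        "reference, orr, expected, places",
        [
            (0.8571, 0.04, 0.1935, 4),  # pre-procedure transfusion, LUSU arm
            (0.3333, 0.44, 0.1803, 4),  # bleeding, LUSU arm
            (0.5, 1.0, 0.5, 12),
        ],
    )
    def test_published_derivations(self, reference, orr, expected, places):
        assert odds_ratio_to_probability(reference, orr) == pytest.approx(
            expected, abs=0.5 * 10**-places
        )

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_reference_rejected(self, bad):
        with pytest.raises(ValueError):
            odds_ratio_to_probability(bad, 0.5)

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_to_probability(0.5, 0.0)

    @given(p=probs)
    def test_unit_or_is_identity(self, p):
        assert odds_ratio_to_probability(p, 1.0) == pytest.approx(p, rel=1e-12)

    @given(p=probs, orr=odds_ratios)
    def test_inverts_odds_ratio_definition(self, p, orr):
        out = odds_ratio_to_probability(p, orr)
        assert 0.0 < out < 1.0
        assert probability_to_odds_ratio(p, out) == pytest.approx(orr, rel=1e-9)

    @given(p=probs, lo=odds_ratios, hi=odds_ratios)
    def test_strictly_increasing_in_or(self, p, lo, hi):
        if lo == hi:
            return
        lo, hi = min(lo, hi), max(lo, hi)
        assert odds_ratio_to_probability(p, lo) < odds_ratio_to_probability(p, hi)


class TestMedianSurvivalToAnnualMortality:
    def test_child_pugh_c_roundtrip(self):
        # the printed Child-Pugh C mortality 0.462 corresponds to a median
        # survival of ~18 months under the ln(2)/median x 12 rule
        assert median_survival_to_annual_mortality(18.0) == pytest.approx(0.4621, abs=5e-5)
        median = math.log(2.0) / 0.462 * 12.0
        assert median_survival_to_annual_mortality(median) == pytest.approx(0.462, rel=1e-12)

    def test_twelve_months_gives_ln2(self):
        assert median_survival_to_annual_mortality(12.0) == pytest.approx(math.log(2.0))

    def test_vanishes_for_long_survival(self):
        assert median_survival_to_annual_mortality(1e12) == pytest.approx(0.0, abs=1e-11)

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError):
            median_survival_to_annual_mortality(0.0)

    @given(m1=st.floats(min_value=0.1, max_value=1e3), m2=st.floats(min_value=0.1, max_value=1e3))
    def test_strictly_decreasing(self, m1, m2):
        if m1 == m2:
            return
        m1, m2 = min(m1, m2), max(m1, m2)
        assert median_survival_to_annual_mortality(m1) > median_survival_to_annual_mortality(m2)


class TestPerDayAeRisk:
    def test_published_product(self):
        risk = per_day_ae_risk(0.0004, 1.17)
        assert risk == pytest.approx(0.000468, rel=1e-12)
        assert round(risk * 100, 2) == 0.05  # displays as 0.05% per day

    @pytest.mark.parametrize(
        "per_pack, packs, expected", [(0.0, 5.0, 0.0), (0.0004, 2.0, 0.0008)]
    )
    def test_direct_products(self, per_pack, packs, expected):
        assert per_day_ae_risk(per_pack, packs) == pytest.approx(expected)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            per_day_ae_risk(0.5, 3.0)


class TestPtCostPerDay:
    @pytest.mark.parametrize(
        "unit, units, fee, expected",
        [
            (8169, 12.8, 15380, 119943.2),
            (0, 0, 0, 0.0),
            (8169, 7.8, 15380, 79098.2),
        ],
    )
    def test_composition(self, unit, units, fee, expected):
        assert pt_cost_per_day(unit, units, fee) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pt_cost_per_day(-1, 1, 1)


class TestWeightedProcedureCost:
    def test_published_mix(self, base_params):
        mix = base_params.costs.procedure_mix
        brute = sum(e.share * e.cost for e in mix) / sum(e.share for e in mix)
        value = weighted_procedure_cost(mix)
        assert value == pytest.approx(brute, rel=1e-12)
        assert value == pytest.approx(2.19e6, rel=0.01)
        assert sum(e.share for e in mix) == pytest.approx(1.001, abs=1e-9)

    def test_single_and_two_entries(self):
        one = [ProcedureMixEntry(name="x", share=1.0, cost=1234.0)]
        assert weighted_procedure_cost(one) == 1234.0
        two = [
            ProcedureMixEntry(name="a", share=0.5, cost=100.0),
            ProcedureMixEntry(name="b", share=0.5, cost=300.0),
        ]
        assert weighted_procedure_cost(two) == pytest.approx(200.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1.0))
    def test_share_rescaling_invariance(self, scale):
        mix = [
            ProcedureMixEntry(name="a", share=0.2, cost=100.0),
            ProcedureMixEntry(name="b", share=0.5, cost=900.0),
        ]
        scaled = [
            ProcedureMixEntry(name=e.name, share=e.share * scale, cost=e.cost) for e in mix
        ]
        assert weighted_procedure_cost(scaled) == pytest.approx(
            weighted_procedure_cost(mix), rel=1e-9
        )

    def test_zero_shares_rejected(self):
        with pytest.raises(ValueError):
            weighted_procedure_cost([ProcedureMixEntry(name="x", share=0.0, cost=1.0)])


class TestLoadParameters:
    def test_shipped_base_case(self, base_params):
        tr = base_params.transitions
        assert tr.p_bleed_PT == pytest.approx(0.3333)
        assert tr.p_prePT_PT == 1.0
        assert tr.or_prePT.odds_ratio == 0.04
        assert base_params.costs.pt_day_cost == pytest.approx(120206.0, abs=0.5)
        assert base_params.utilities.u_base == 0.808
        assert base_params.settings.wtp_threshold == 5_000_000

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(Exception) as err:
            load_parameters(overrides={"transitions": {"p_bleed_PT": 1.2}})
        assert "p_bleed_PT" in str(err.value)

    def test_scenario_b_override(self):
        p = load_parameters(overrides={"transitions": {"p_prePT_PT": 0.8571}})
        assert p.transitions.p_prePT("PT") == 0.8571
        # the LUSU arm stays anchored to the pooled reference rate
        assert p.transitions.p_prePT("LUSU") == pytest.approx(0.1935, abs=5e-5)

    def test_bad_simplex_rejected(self):
        with pytest.raises(Exception):
            load_parameters(
                overrides={"transitions": {"cp_weights": {"A": 0.6, "B": 0.6, "C": 0.0}}}
            )

    def test_round_trip_stability(self, base_params):
        doc = dump_parameters(base_params)
        reloaded = load_parameters(__import__("yaml").safe_load(doc))
        assert dump_parameters(reloaded) == doc
        assert reloaded == base_params

    def test_owsa_range_must_bracket_base(self):
        with pytest.raises(Exception) as err:
            load_parameters(overrides={"owsa_ranges": {"u_base": [0.9, 0.99]}})
        assert "u_base" in str(err.value)


class TestParamAddressing:
    @pytest.mark.parametrize(
        "pid, expected",
        [
            ("or_bleed", 0.44),
            ("p_noproc.PT.received", 0.1032),
            ("p_rescue.LUSU.none", 0.4286),
            ("pt_days.LUSU", 1.23),
            ("procedure_cost.1", 3769899.0),
            ("du_bleed", 0.397),
            ("p_allergic_per_day", 0.000468),
        ],
    )
    def test_get(self, base_params, pid, expected):
        assert get_param(base_params, pid) == pytest.approx(expected)

    def test_set_round_trip(self, params):
        for pid, value in [
            ("or_bleed", 0.9),
            ("p_noproc.LUSU.none", 0.01),
            ("pt_days.PT", 2.0),
            ("procedure_cost.0", 1.0),
            ("p_allergic_per_day", 0.0007),
        ]:
            set_param(params, pid, value)
            assert get_param(params, pid) == pytest.approx(value)

    def test_unknown_id_rejected(self, base_params):
        with pytest.raises(KeyError):
            get_param(base_params, "no_such_parameter")
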