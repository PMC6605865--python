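import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from immunoninf.response_rules import (
    DTT_RESPONSE_FLOOR,
    DTT_SEROPROTECTION,
    Tier,
    call_booster_dtt,
    call_booster_pertussis,
    call_seroresponse,
    classify,
    summarize_responses,
)
from immunoninf.trial_data import AntigenSpec, RuleKind
from conftest import make_subject


def booster_oracle(pre, post, rule_kind, cutoff=None):
    """Case-enumeration reference for the tiered booster rules.

    Enumerates the tier intervals explicitly and checks that exactly one
    applies, independently of the dispatch logic under test.
    """
    if rule_kind is RuleKind.BOOSTER_PERTUSSIS:
        c = cutoff
        tiers = [
            (0.0, c, lambda pre: 4.0 * c),
            (c, 4.0 * c, lambda pre: 4.0 * pre),
            (4.0 * c, np.inf, lambda pre: 2.0 * pre),
        ]
    else:
        tiers = [
            (0.0, DTT_SEROPROTECTION, lambda pre: DTT_RESPONSE_FLOOR),
            (DTT_SEROPROTECTION, np.inf, lambda pre: 4.0 * pre),
        ]
    matches = [(lo, hi, f) for lo, hi, f in tiers if lo <= pre < hi]
    assert len(matches) == 1, f"tier partition violated at pre={pre}"
    return post >= matches[0][2](pre)


class TestSeroresponse:
    @pytest.mark.parametrize(
        "post,expected",
        [(200.0, True), (199.99, False), (5000.0, True), (None, None)],
    )
    def test_measles_threshold_inclusive(self, spec_by_name, post, expected):
        assert call_seroresponse(post, spec_by_name["measles"]).responder is expected

    def test_vzv_ignores_missing_baseline(self, spec_by_name):
        # seroresponse disregards the pre-vaccination concentration entirely
        call = classify(None, 75.0, spec_by_name["VZV"])
        assert call.responder is True

    def test_wrong_rule_kind_rejected(self, spec_by_name):
        with pytest.raises(ValueError):
            call_seroresponse(10.0, spec_by_name["PT"])


class TestBoosterPertussis:
    @pytest.mark.parametrize(
        "antigen,pre,post,expected,tier",
        [
            # PT cut-off 2.693: seronegative tier needs post >= 4c = 10.772
            ("PT", 1.0, 10.772, True, Tier.BELOW_CUTOFF),
            ("PT", 1.0, 10.771, False, Tier.BELOW_CUTOFF),
            # FHA cut-off 2.046: low-positive tier needs post >= 4*pre
            ("FHA", 3.0, 11.9, False, Tier.LOW_POSITIVE),
            ("FHA", 3.0, 12.0, True, Tier.LOW_POSITIVE),
            # PRN cut-off 2.187: high-positive tier needs post >= 2*pre
            ("PRN", 10.0, 20.0, True, Tier.HIGH_POSITIVE),
            ("PRN", 10.0, 19.99, False, Tier.HIGH_POSITIVE),
        ],
    )
    def test_tier_boundaries(self, spec_by_name, antigen, pre, post, expected, tier):
        call = call_booster_pertussis(pre, post, spec_by_name[antigen])
        assert call.responder is expected
        assert call.tier is tier

    def test_pre_exactly_4c_is_high_positive(self, spec_by_name):
        spec = spec_by_name["PT"]
        call = call_booster_pertussis(4.0 * spec.assay_cutoff, 1.0, spec)
        assert call.tier is Tier.HIGH_POSITIVE

    def test_missing_input_gives_null(self, spec_by_name):
        assert call_booster_pertussis(None, 50.0, spec_by_name["PT"]).responder is None
        assert call_booster_pertussis(5.0, None, spec_by_name["PT"]).responder is None


class TestBoosterDtt:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (0.05, 0.40, True),   # seronegative: absolute 0.4 floor, inclusive
            (0.05, 0.39, False),
            (0.2, 0.80, True),    # seropositive: 4-fold rise, inclusive
            (0.2, 0.79, False),
            (0.0999, 0.39, False),
            (0.1, 0.4, True),     # pre exactly at seroprotection -> 4-fold branch
        ],
    )
    def test_branch_boundaries(self, spec_by_name, pre, post, expected):
        assert call_booster_dtt(pre, post, spec_by_name["DT"]).responder is expected


class TestOracleAgreement:
    def test_matches_enumeration_on_random_pairs(self, spec_by_name):
        rng = np.random.default_rng(42)
        for name in ("PT", "FHA", "PRN", "DT", "TT"):
            spec = spec_by_name[name]
            c = spec.assay_cutoff or DTT_SEROPROTECTION
            # log-uniform spanning all tier boundaries, plus exact boundaries
            pres = np.concatenate(
                [10 ** rng.uniform(np.log10(c) - 2, np.log10(c) + 2, 2000),
                 [c, 4 * c, c / 2, 8 * c]]
            )
            posts = 10 ** rng.uniform(np.log10(c) - 2, np.log10(c) + 3, pres.size)
            for pre, post in zip(pres, posts):
                got = classify(float(pre), float(post), spec).responder
                want = booster_oracle(float(pre), float(post), spec.rule_kind, spec.assay_cutoff)
                assert got == want, f"{name}: pre={pre} post={post}"

    @given(
        pre=st.floats(0.0, 100.0, allow_nan=False),
        post1=st.floats(0.0, 1000.0, allow_nan=False),
        bump=st.floats(0.0, 100.0, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_responder_monotone_in_post(self, spec_by_name, pre, post1, bump):
        for name in ("PT", "DT", "measles"):
            spec = spec_by_name[name]
            lo = classify(pre, post1, spec).responder
            hi = classify(pre, post1 + bump, spec).responder
            assert hi >= lo  # True >= False


class TestSummaries:
    def test_rate_to_one_decimal_matches_table_convention(self, spec_by_name):
        subs = [
            make_subject(subject_id=f"s{i}", measurements={"rubella": (50.0, 100.0)})
            for i in range(696)
        ] + [make_subject(subject_id="nr", measurements={"rubella": (50.0, 5.0)})]
        s = summarize_responses(subs, spec_by_name["rubella"])
        assert (s.x, s.n) == (696, 697)
        assert round(s.rate_pct, 1) == 99.9

    def test_null_calls_excluded_from_denominator(self, spec_by_name):
        meas = [(1.0, 50.0)] * 5 + [(1.0, 0.5)] + [(None, 50.0), (1.0, None)]
        subs = [
            make_subject(subject_id=f"s{i}", measurements={"PT": m}) for i, m in enumerate(meas)
        ]
        s = summarize_responses(subs, spec_by_name["PT"])
        assert (s.x, s.n) == (5, 6)

    def test_zero_responders(self, spec_by_name):
        subs = [
            make_subject(subject_id=f"s{i}", measurements={"measles": (None, 10.0)})
            for i in range(10)
        ]
        s = summarize_responses(subs, spec_by_name["measles"])
        assert s.rate_pct == 0.0

    def test_no_evaluable_subjects_is_an_error(self, spec_by_name):
        with pytest.raises(ValueError):
            summarize_responses([make_subject()], spec_by_name["measles"])
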