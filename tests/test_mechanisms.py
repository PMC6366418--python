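"""Rate-law algebra: nesting, reductions, apparent constants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from enzkin.errors import DomainError, ParameterMismatchError
from enzkin.mechanisms import (
    Condition,
    KineticParameters,
    Mechanism,
    apparent_constants,
    evaluate_rate,
)


class TestParameterCounts:
    @pytest.mark.parametrize(
        "mech, k",
        [
            (Mechanism.NONE, 2),
            (Mechanism.COMPETITIVE, 3),
            (Mechanism.UNCOMPETITIVE, 3),
            (Mechanism.NONCOMPETITIVE, 3),
            (Mechanism.MIXED, 4),
        ],
    )
    def test_free_parameter_counts(self, mech, k):
        assert mech.n_parameters == k

    def test_nesting_graph(self):
        three = {Mechanism.COMPETITIVE, Mechanism.UNCOMPETITIVE, Mechanism.NONCOMPETITIVE}
        assert Mechanism.NONE.nested_within == three | {Mechanism.MIXED}
        for m in three:
            assert m.nested_within == {Mechanism.MIXED}
            # the three one-constant mechanisms are mutually non-nested
            assert not any(m.is_nested_in(o) for o in three - {m})
        assert Mechanism.MIXED.nested_within == frozenset()


class TestEvaluateRate:
    def test_half_saturation_at_km(self):
        p = KineticParameters(vmax=12.0, km=1.2)
        assert evaluate_rate(p, Mechanism.NONE, Condition(S=1.2)) == pytest.approx(6.0)

    def test_competitive_hand_value(self):
        # v = 12*0.5 / (1.2*(1 + 132/132) + 0.5) = 6/2.9
        p = KineticParameters(vmax=12.0, km=1.2, kic=132.0)
        v = evaluate_rate(p, Mechanism.COMPETITIVE, Condition(S=0.5, I=132.0))
        assert v == pytest.approx(6.0 / 2.9, rel=1e-12)

    @pytest.mark.parametrize("S", [0.25, 0.5, 1.0, 3.0])
    def test_all_mechanisms_agree_at_zero_inhibitor(self, S):
        base = KineticParameters(vmax=12.0, km=1.2)
        variants = {
            Mechanism.NONE: base,
            Mechanism.COMPETITIVE: KineticParameters(12.0, 1.2, kic=30.0),
            Mechanism.UNCOMPETITIVE: KineticParameters(12.0, 1.2, kiu=7.0),
            Mechanism.NONCOMPETITIVE: KineticParameters(12.0, 1.2, kic=5.0, kiu=5.0),
            Mechanism.MIXED: KineticParameters(12.0, 1.2, kic=30.0, kiu=7.0),
        }
        expected = evaluate_rate(base, Mechanism.NONE, Condition(S=S))
        for mech, p in variants.items():
            assert evaluate_rate(p, mech, Condition(S=S, I=0.0)) == expected

    def test_mixed_with_equal_constants_is_noncompetitive(self):
        mixed = KineticParameters(12.0, 1.2, kic=9.0, kiu=9.0)
        nonc = KineticParameters(12.0, 1.2, kic=9.0, kiu=9.0)
        for S in (0.1, 0.5, 2.0):
            for I in (0.0, 3.0, 40.0):
                cond = Condition(S=S, I=I)
                assert evaluate_rate(mixed, Mechanism.MIXED, cond) == evaluate_rate(
                    nonc, Mechanism.NONCOMPETITIVE, cond
                )

    def test_mixed_with_huge_kiu_approaches_competitive(self):
        mixed = KineticParameters(12.0, 1.2, kic=132.0, kiu=1e9)
        comp = KineticParameters(12.0, 1.2, kic=132.0)
        for S in (0.05, 0.5, 5.0):
            for I in (0.0, 10.0, 1e3):
                cond = Condition(S=S, I=I)
                a = evaluate_rate(mixed, Mechanism.MIXED, cond)
                b = evaluate_rate(comp, Mechanism.COMPETITIVE, cond)
                assert a == pytest.approx(b, rel=1e-6)

    def test_missing_constant_raises(self):
        p = KineticParameters(vmax=12.0, km=1.2)
        with pytest.raises(ParameterMismatchError):
            evaluate_rate(p, Mechanism.COMPETITIVE, Condition(S=0.5, I=10.0))

    def test_extra_constant_raises(self):
        p = KineticParameters(vmax=12.0, km=1.2, kic=50.0)
        with pytest.raises(ParameterMismatchError):
            evaluate_rate(p, Mechanism.NONE, Condition(S=0.5))

    def test_noncompetitive_requires_equal_constants(self):
        p = KineticParameters(vmax=12.0, km=1.2, kic=5.0, kiu=6.0)
        with pytest.raises(ParameterMismatchError):
            evaluate_rate(p, Mechanism.NONCOMPETITIVE, Condition(S=0.5))

    def test_nonpositive_substrate_rejected(self):
        with pytest.raises(DomainError):
            Condition(S=0.0, I=0.0)
        with pytest.raises(DomainError):
            Condition(S=0.5, I=-1.0)

    @given(
        vmax=st.floats(0.1, 100.0),
        km=st.floats(0.05, 10.0),
        kic=st.floats(0.5, 1e4),
        kiu=st.floats(0.5, 1e4),
        s1=st.floats(0.05, 5.0),
        ds=st.floats(0.01, 5.0),
        i1=st.floats(0.0, 500.0),
        di=st.floats(0.1, 500.0),
    )
    def test_monotone_in_substrate_and_inhibitor(self, vmax, km, kic, kiu, s1, ds, i1, di):
        p = KineticParameters(vmax=vmax, km=km, kic=kic, kiu=kiu)
        v = evaluate_rate(p, Mechanism.MIXED, Condition(S=s1, I=i1))
        assert 0 < v <= vmax
        # strictly increasing in S, strictly decreasing in I (constants present)
        assert evaluate_rate(p, Mechanism.MIXED, Condition(S=s1 + ds, I=i1)) > v
        assert evaluate_rate(p, Mechanism.MIXED, Condition(S=s1, I=i1 + di)) < v


class TestApparentConstants:
    def test_competitive_doubles_km_at_i_equal_kic(self):
        p = KineticParameters(12.0, 1.2, kic=50.0)
        vmax_app, km_app = apparent_constants(p, Mechanism.COMPETITIVE, I=50.0)
        assert vmax_app == pytest.approx(12.0)
        assert km_app == pytest.approx(2.4)

    def test_uncompetitive_halves_both_at_i_equal_kiu(self):
        p = KineticParameters(12.0, 1.2, kiu=8.0)
        vmax_app, km_app = apparent_constants(p, Mechanism.UNCOMPETITIVE, I=8.0)
        assert vmax_app == pytest.approx(6.0)
        assert km_app == pytest.approx(0.6)

    def test_noncompetitive_halves_vmax_only(self):
        p = KineticParameters(12.0, 1.2, kic=8.0, kiu=8.0)
        vmax_app, km_app = apparent_constants(p, Mechanism.NONCOMPETITIVE, I=8.0)
        assert vmax_app == pytest.approx(6.0)
        assert km_app == pytest.approx(1.2)

    @pytest.mark.parametrize(
        "mech, params",
        [
            (Mechanism.COMPETITIVE, KineticParameters(12.0, 1.2, kic=132.0)),
            (Mechanism.UNCOMPETITIVE, KineticParameters(12.0, 1.2, kiu=0.71)),
            (Mechanism.NONCOMPETITIVE, KineticParameters(12.0, 1.2, kic=6.0, kiu=6.0)),
            (Mechanism.MIXED, KineticParameters(12.0, 0.9, kic=6.0, kiu=0.71)),
        ],
    )
    def test_reconstruction_identity_on_grid(self, mech, params):
        # Vmax_app * S / (Km_app + S) must reproduce the full rate law
        for I in np.linspace(0.0, 500.0, 11):
            vmax_app, km_app = apparent_constants(params, mech, I)
            for S in np.geomspace(0.05, 5.0, 9):
                direct = evaluate_rate(params, mech, Condition(S=S, I=I))
                rebuilt = vmax_app * S / (km_app + S)
                assert rebuilt == pytest.approx(direct, rel=1e-12)
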