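"""Rate-law evaluation against independent term-by-term oracles."""

import numpy as np
import pytest

from ssadhkin import (InhibitoryRegimeParams, MMParams, OrderedBiBiParams,
                      PartialSubstrateInhibitionParams, RateObservation,
                      SubstrateInhibitionParams, eval_inhibitory_regime,
                      eval_mm, eval_mm_substrate_inhibition,
                      eval_ordered_bibi, eval_partial_substrate_inhibition,
                      kcat_from_vmax, nadh_from_a340)


# Independent oracles: each rate law rebuilt term by term, no shared code.

def oracle_mm(s, vmax, km):
    return (vmax * s) / (km + s)


def oracle_si(s, vmax, km, ki):
    return (vmax * s) / (km + s * (1 + s / ki))


def oracle_bibi(a, b, vmax, ka, kb, kia):
    den = (kia * kb) + (kb * a) + (ka * b) + (a * b)
    return (vmax * a * b) / den


def oracle_regime(a, b, vmax, ka, kis, kix, kii):
    num = vmax * a * (1 + b / kix)
    den = ka * (1 + b / kis) + a * (1 + b / kii)
    return num / den


def oracle_partial(a, b, vmax, ka, kb, kia, kis, bb):
    num = vmax * a * b * (1 + bb * b / kis)
    den = (kia * kb) + (kb * a) + (ka * b) + a * b * (1 + b / kis)
    return num / den


class TestPointExamples:
    def test_mm(self):
        p = MMParams(vmax=100, km=10)
        assert eval_mm(0, p) == 0
        assert eval_mm(10, p) == pytest.approx(50)
        assert eval_mm(40, p) == pytest.approx(80)

    def test_substrate_inhibition(self):
        p = SubstrateInhibitionParams(vmax=100, km=10, ki=10)
        assert eval_mm_substrate_inhibition(0, p) == 0
        assert eval_mm_substrate_inhibition(10, p) == pytest.approx(1000 / 30)
        # ki -> infinity reduces to plain MM
        p_inf = SubstrateInhibitionParams(vmax=100, km=10, ki=1e12 * 10)
        for s in (1.0, 10.0, 200.0):
            assert eval_mm_substrate_inhibition(s, p_inf) == pytest.approx(
                eval_mm(s, MMParams(vmax=100, km=10)), rel=1e-9)

    def test_ordered_bibi(self, bibi_params):
        assert eval_ordered_bibi(0, 1, bibi_params) == 0
        assert eval_ordered_bibi(10, 0, bibi_params) == 0
        assert eval_ordered_bibi(10, 1, bibi_params) == pytest.approx(1000 / 35)
        # saturating-A limit -> MM in B
        assert eval_ordered_bibi(1e12, 3.0, bibi_params) == pytest.approx(
            100 * 3 / (1 + 3), rel=1e-9)

    def test_inhibitory_regime(self):
        p = InhibitoryRegimeParams(vmax=100, k_a=10, k_is=5, k_ix=84, k_ii=7)
        # B=0 reduces to MM in A
        assert eval_inhibitory_regime(10, 0, p) == pytest.approx(100 * 10 / 20)
        got = eval_inhibitory_regime(10, 7, p)
        assert got == pytest.approx(oracle_regime(10, 7, 100, 10, 5, 84, 7))
        # saturating-A limit
        assert eval_inhibitory_regime(1e14, 7, p) == pytest.approx(
            100 * (1 + 7 / 84) / (1 + 7 / 7), rel=1e-9)

    def test_partial_inhibition(self, partial_params):
        got = eval_partial_substrate_inhibition(10, 1, partial_params)
        assert got == pytest.approx(1050 / 36)
        # k_is -> infinity reduces to ordered bi-bi
        p_inf = PartialSubstrateInhibitionParams(
            vmax=100, k_a=10, k_b=1, k_ia=5, k_is=1e13, b=0.5)
        bibi = OrderedBiBiParams(vmax=100, k_a=10, k_b=1, k_ia=5)
        for a, b in [(1, 1), (10, 5), (500, 200)]:
            assert eval_partial_substrate_inhibition(a, b, p_inf) == \
                pytest.approx(eval_ordered_bibi(a, b, bibi), rel=1e-9)

    def test_complete_inhibition_limit(self):
        # b=0: rate vanishes at saturating inhibitory substrate
        p = PartialSubstrateInhibitionParams(
            vmax=100, k_a=10, k_b=1, k_ia=5, k_is=10, b=0.0)
        assert eval_partial_substrate_inhibition(10, 1e9 * 10, p) < 1e-5


def test_oracle_agreement_random_inputs():
    """All five laws match the term-by-term oracle to 1e-12 on 1000 draws."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        vmax, ka, kb, kia, kis, kix, kii = 10.0 ** rng.uniform(-1, 3, 7)
        bb = rng.uniform(0, 1)
        a, b = 10.0 ** rng.uniform(-2, 3, 2)
        assert eval_mm(b, MMParams(vmax, kb)) == pytest.approx(
            oracle_mm(b, vmax, kb), rel=1e-12)
        assert eval_mm_substrate_inhibition(
            b, SubstrateInhibitionParams(vmax, kb, kis)) == pytest.approx(
            oracle_si(b, vmax, kb, kis), rel=1e-12)
        assert eval_ordered_bibi(a, b, OrderedBiBiParams(vmax, ka, kb, kia)) \
            == pytest.approx(oracle_bibi(a, b, vmax, ka, kb, kia), rel=1e-12)
        assert eval_inhibitory_regime(
            a, b, InhibitoryRegimeParams(vmax, ka, kis, kix, kii)) == \
            pytest.approx(oracle_regime(a, b, vmax, ka, kis, kix, kii),
                          rel=1e-12)
        assert eval_partial_substrate_inhibition(
            a, b, PartialSubstrateInhibitionParams(vmax, ka, kb, kia, kis, bb)
        ) == pytest.approx(oracle_partial(a, b, vmax, ka, kb, kia, kis, bb),
                           rel=1e-12)


def test_substrate_inhibition_maximum_location():
    """Eq.(2) peaks at sqrt(Km*Ki): checked against dense grid search."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        vmax = 10.0 ** rng.uniform(0, 2)
        km = 10.0 ** rng.uniform(-1, 2)
        ki = 10.0 ** rng.uniform(-1, 2)
        p = SubstrateInhibitionParams(vmax, km, ki)
        s_star = np.sqrt(km * ki)
        grid = np.geomspace(s_star / 50, s_star * 50, 4001)
        s_grid = grid[np.argmax(eval_mm_substrate_inhibition(grid, p))]
        assert s_grid == pytest.approx(s_star, rel=5e-3)
        assert p.optimum == pytest.approx(s_star)


def test_high_ssa_limit_is_b_vmax():
    rng = np.random.default_rng(1)
    for _ in range(20):
        p = PartialSubstrateInhibitionParams(
            vmax=10.0 ** rng.uniform(0, 2), k_a=10.0 ** rng.uniform(0, 2),
            k_b=10.0 ** rng.uniform(-1, 1), k_ia=10.0 ** rng.uniform(0, 2),
            k_is=10.0 ** rng.uniform(0, 2), b=rng.uniform(0.05, 1.0))
        a = 10.0 ** rng.uniform(0, 2)
        got = eval_partial_substrate_inhibition(a, 1e9 * p.k_is, p)
        assert got == pytest.approx(p.b * p.vmax, rel=1e-3)


def test_nonnegative_and_zero_at_zero(bibi_params, partial_params):
    rng = np.random.default_rng(2)
    a = 10.0 ** rng.uniform(-2, 3, 50)
    b = 10.0 ** rng.uniform(-2, 3, 50)
    assert np.all(eval_ordered_bibi(a, b, bibi_params) >= 0)
    assert np.all(eval_partial_substrate_inhibition(a, b, partial_params) >= 0)
    assert eval_ordered_bibi(0.0, 0.0, bibi_params) == 0


@pytest.mark.parametrize("fn,args", [
    (eval_mm, (MMParams(1, 1),)),
    (eval_mm_substrate_inhibition, (SubstrateInhibitionParams(1, 1, 1),)),
])
def test_negative_concentration_rejected(fn, args):
    with pytest.raises(ValueError):
        fn(-1.0, *args)


def test_negative_concentration_rejected_two_substrate(bibi_params):
    with pytest.raises(ValueError):
        eval_ordered_bibi(-1.0, 1.0, bibi_params)
    with pytest.raises(ValueError):
        eval_ordered_bibi(1.0, -1.0, bibi_params)


class TestConversions:
    def test_nadh_from_a340(self):
        assert nadh_from_a340(0.0) == 0
        assert nadh_from_a340(0.622, 1.0) == pytest.approx(100.0)
        assert nadh_from_a340(6.22, 10.0) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            nadh_from_a340(0.1, 0.0)

    def test_kcat_from_vmax(self):
        assert kcat_from_vmax(0.0, 0.008) == 0
        assert kcat_from_vmax(1.328, 0.008) == pytest.approx(166.0)
        assert kcat_from_vmax(2 * 1.328, 2 * 0.008) == pytest.approx(166.0)
        with pytest.raises(ValueError):
            kcat_from_vmax(1.0, 0.0)


class TestRateObservation:
    def test_invariants(self):
        with pytest.raises(ValueError):
            RateObservation(ssa_um=-1, nad_um=1, rate=1)
        with pytest.raises(ValueError):
            RateObservation(ssa_um=1, nad_um=1, rate=1, enzyme_um=0)
        with pytest.raises(ValueError):
            RateObservation(ssa_um=1, nad_um=1, rate=-0.1)
        # negative rate allowed with blank subtraction
        o = RateObservation(ssa_um=1, nad_um=1, rate=-0.1,
                            blank_subtracted=True)
        assert o.rate == -0.1

    def test_unit_conversion(self):
        o = RateObservation(ssa_um=1, nad_um=1, rate=1.328,
                            rate_units="um_per_s", enzyme_um=0.008)
        assert o.rate_per_s == pytest.approx(166.0)
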