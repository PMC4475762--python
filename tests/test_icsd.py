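import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoplan import (
    ICSD,
    DoseConstants,
    average_depths,
    conditionalize,
    descriptor_set,
    dose_from_m1,
    icsd_from_samples,
    m1,
    m1_bio,
    m1_star,
    mix_absolute,
    y_lc,
    y_sc,
)
from nanoplan.icsd import WATER_SV_MASS_KG

from .conftest import make_absolute_probs


def absolute(probs):
    probs = np.asarray(probs, dtype=float)
    return ICSD(np.pad(probs, (0, max(0, 11 - len(probs)))), "absolute")


def conditional(probs):
    probs = np.asarray(probs, dtype=float)
    return ICSD(np.pad(probs, (0, max(0, 11 - len(probs)))), "conditional")


def delta(nu, width=31):
    p = np.zeros(width)
    p[nu] = 1.0
    return ICSD(p, "absolute")


@st.composite
def absolute_icsds(draw):
    seed = draw(st.integers(0, 2**31 - 1))
    return ICSD(make_absolute_probs(np.random.default_rng(seed)), "absolute")


class TestConstruction:
    def test_counting_normalization(self):
        samples = [2] * 5 + [1] * 10
        p = icsd_from_samples(np.array(samples), 100)
        assert p.probs[:3] == pytest.approx([0.85, 0.10, 0.05])

    def test_no_samples_is_all_zero_cluster(self):
        p = icsd_from_samples(np.array([], dtype=int), 50)
        assert p.probs[0] == 1.0

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            icsd_from_samples(np.array([1, 2]), 0)

    def test_overflow_pooled_into_top_bin(self):
        p = icsd_from_samples(np.array([40, 40]), 10, nu_max=30)
        assert p.probs[30] == pytest.approx(0.2)

    def test_unnormalized_vector_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            ICSD(np.r_[0.5, np.zeros(10)], "absolute")


class TestConditionalization:
    def test_renormalizes_tail(self):
        p = conditionalize(absolute([0.9, 0.05, 0.03, 0.02]))
        assert p.probs[:4] == pytest.approx([0.0, 0.5, 0.3, 0.2])

    def test_no_zero_mass_is_identity_on_tail(self):
        p = absolute([0.0, 0.5, 0.3, 0.2])
        assert conditionalize(p).probs == pytest.approx(p.probs)

    def test_idempotent(self):
        c = conditionalize(absolute([0.9, 0.1]))
        assert conditionalize(c) is c

    def test_all_zero_cluster_rejected(self):
        with pytest.raises(ValueError, match="no ionizing"):
            conditionalize(absolute([1.0]))


class TestDescriptors:
    def test_m1_hand_example(self):
        assert m1(absolute([0.9, 0.05, 0.03, 0.02])) == pytest.approx(0.17)

    def test_m1_of_delta(self):
        assert m1(delta(3)) == pytest.approx(3.0)

    def test_y_sc_windows(self):
        assert y_sc(absolute([0.9, 0.05, 0.03, 0.02])) == pytest.approx(0.05)
        assert y_sc(delta(1)) == 0.0
        assert y_sc(absolute([0, 0, 0.6, 0.4])) == pytest.approx(1.0)

    def test_y_lc_windows_and_exclusion(self):
        assert y_lc(delta(7)) == pytest.approx(1.0)
        assert y_lc(delta(11)) == 0.0  # clusters above ten are excluded
        assert y_lc(absolute([0.9, 0.05, 0.03, 0.02])) == 0.0

    def test_descriptors_require_absolute_kind(self):
        with pytest.raises(ValueError, match="absolute"):
            m1(conditional([0, 1.0]))


class TestMixing:
    def test_equal_weight_mixture(self):
        mixed = mix_absolute([absolute([0.9, 0.1]), absolute([0.8, 0.2])], [1, 1])
        assert mixed.probs[:2] == pytest.approx([0.85, 0.15])

    def test_single_nonzero_weight_is_identity(self):
        a, b = absolute([0.9, 0.1]), absolute([0.5, 0.5])
        mixed = mix_absolute([a, b], [3.0, 0.0])
        assert mixed.probs == pytest.approx(np.pad(a.probs, (0, 0)))

    @given(absolute_icsds(), absolute_icsds(), st.floats(0.01, 10), st.floats(0.01, 10))
    @settings(max_examples=30, deadline=None)
    def test_m1_linear_in_mixture(self, a, b, w1, w2):
        mixed = mix_absolute([a, b], [w1, w2])
        expected = (w1 * m1(a) + w2 * m1(b)) / (w1 + w2)
        assert m1(mixed) == pytest.approx(expected, abs=1e-12)


class TestCompositeConditionalMeans:
    def test_single_beam_conditional_mean(self):
        assert m1_star([conditional([0, 0.5, 0.3, 0.2])]) == pytest.approx(1.7)

    def test_identical_beams_any_mode(self):
        c = conditional([0, 0.5, 0.3, 0.2])
        lit = m1_star([c, c], mode="paper_literal")
        phys = m1_star([c, c], mode="physical", zero_fractions=[0.4, 0.4])
        assert lit == pytest.approx(phys) == pytest.approx(1.7)

    def test_modes_agree_when_zero_fractions_equal(self):
        # with equal P_i(0) the literal sum of conditionals equals the
        # conditional of the mixed absolute distribution
        rng = np.random.default_rng(8)
        conds = []
        for _ in range(4):
            p = make_absolute_probs(rng)
            p[0] = 0.0
            conds.append(ICSD(p / p.sum(), "conditional"))
        lit = m1_star(conds, mode="paper_literal")
        phys = m1_star(conds, mode="physical", zero_fractions=[0.7] * 4)
        assert lit == pytest.approx(phys, rel=1e-12)

    def test_all_zero_effective_weights_rejected(self):
        c = conditional([0, 1.0])
        with pytest.raises(ValueError, match="zero"):
            m1_star([c], mode="physical", zero_fractions=[1.0])

    def test_m1_bio_hand_example(self):
        assert m1_bio(conditional([0, 0.5, 0.3, 0.2])) == pytest.approx(2.4)

    def test_m1_bio_of_delta(self):
        p = np.zeros(31)
        p[6] = 1.0
        assert m1_bio(ICSD(p, "conditional")) == pytest.approx(6.0)

    def test_m1_bio_empty_window_rejected(self):
        p = np.zeros(31)
        p[1], p[12] = 0.6, 0.4
        with pytest.raises(ValueError, match="window"):
            m1_bio(ICSD(p, "conditional"))


class TestDose:
    def test_zero_cluster_size_gives_zero_dose(self):
        assert dose_from_m1(0.0) == 0.0

    def test_water_nanocylinder_reference_value(self):
        # independent arithmetic: D = M1 * W / m with m the mass of a
        # 2 nm x 16 nm water cylinder
        mass = np.pi * (1e-9) ** 2 * 16e-9 * 1000.0
        expected = 1e-3 * 30.0 * 1.602176634e-19 / mass
        got = dose_from_m1(1e-3, DoseConstants(W_eV=30.0, sv_mass_kg=WATER_SV_MASS_KG))
        assert got == pytest.approx(expected)
        assert got == pytest.approx(95.62, rel=1e-3)

    def test_linear_in_m1(self):
        assert dose_from_m1(2e-3) == pytest.approx(2 * dose_from_m1(1e-3))


class TestDepthAveraging:
    def test_identical_inputs_fixed_point(self):
        p = absolute([0.9, 0.1])
        assert average_depths([p, p, p]).probs == pytest.approx(p.probs)

    def test_scalar_mean(self):
        assert average_depths([1.0, 2.0, 3.0]) == pytest.approx(2.0)

    def test_commutes_with_m1(self):
        rng = np.random.default_rng(12)
        icsds = [ICSD(make_absolute_probs(rng), "absolute") for _ in range(3)]
        assert m1(average_depths(icsds)) == pytest.approx(
            np.mean([m1(p) for p in icsds]), abs=1e-12
        )


class TestInvariants:
    @given(absolute_icsds())
    @settings(max_examples=50, deadline=None)
    def test_normalization_preserved_and_yields_bounded(self, p):
        assert abs(p.probs.sum() - 1.0) < 1e-12
        assert y_sc(p) + y_lc(p) <= 1.0 - p.probs[0] - p.probs[1] + 1e-12
        if p.probs[0] < 1.0:
            cond = conditionalize(p)
            assert abs(cond.probs.sum() - 1.0) < 1e-12
            d = descriptor_set(p)
            assert d.m1_star >= 1.0
            if d.m1_bio is not None:
                assert 2.0 <= d.m1_bio <= 10.0
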