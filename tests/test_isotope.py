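"""Natural-abundance correction, flux ratios and internal-standard rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidkit.isotope import (
    GCMS_STANDARD_RULES,
    SOLVENT_STANDARD_RULES,
    IsotopologueVector,
    build_correction_matrix,
    correct_natural_abundance,
    labeling_ratio,
    normalize_to_internal_standard,
)


def _binomial_oracle(n, p, size):
    """Independent construction from the binomial mass function written out."""
    from math import comb

    m = np.zeros((size, size))
    for j in range(size):
        for i in range(j, size):
            k = i - j
            m[i, j] = comb(n - j, k) * p**k * (1 - p) ** (n - j - k)
    return m


class TestCorrectionMatrix:
    def test_zero_abundance_is_identity(self):
        m = build_correction_matrix(16, 0.0)
        assert np.array_equal(m, np.eye(17))

    def test_two_carbon_column_matches_binomial_oracle(self):
        m = build_correction_matrix(2, 0.0107)
        # (1-p)^2, 2 p (1-p), p^2 for p = 0.0107
        assert m[:, 0] == pytest.approx([0.97871, 0.02117, 0.00011], abs=5e-6)

    @given(
        n=st.integers(min_value=1, max_value=30),
        p=st.one_of(st.just(0.0), st.floats(min_value=1e-6, max_value=0.2)),
    )
    def test_column_sums_at_most_one(self, n, p):
        m = build_correction_matrix(n, p)
        assert np.all(m.sum(axis=0) <= 1 + 1e-12)
        assert np.all(np.diag(m) > 0)

    def test_matches_oracle_for_palmitate(self):
        mine = build_correction_matrix(16, 0.0107)
        oracle = _binomial_oracle(16, 0.0107, 17)
        np.testing.assert_allclose(mine, oracle, atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_correction_matrix(0)
        with pytest.raises(ValueError):
            build_correction_matrix(5, 1.0)
        with pytest.raises(ValueError):
            build_correction_matrix(5, 0.01, size=7)


class TestCorrectNaturalAbundance:
    def test_pure_unlabeled_round_trip(self):
        m = build_correction_matrix(16, 0.0107)
        planted = np.zeros(17)
        planted[0] = 1.0
        v = IsotopologueVector("FA 16:0", 16, m @ planted * 1e5)
        f = correct_natural_abundance(v, m)
        assert f[0] == pytest.approx(1.0, abs=1e-9)
        assert f[1:] == pytest.approx(np.zeros(16), abs=1e-9)

    def test_forward_simulate_then_invert(self):
        m = build_correction_matrix(16, 0.0107, size=3)
        planted = np.array([0.8, 0.0, 0.2])
        v = IsotopologueVector("FA 16:0", 16, m @ planted)
        f = correct_natural_abundance(v, m)
        assert f == pytest.approx(planted, abs=1e-6)

    @given(
        n=st.integers(min_value=2, max_value=30),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_round_trip_any_fraction_vector(self, n, seed):
        rng = np.random.default_rng(seed)
        size = min(n + 1, 7)
        planted = rng.dirichlet(np.ones(size))
        m = build_correction_matrix(n, 0.0107, size=size)
        v = IsotopologueVector(f"FA {n}:0", n, m @ planted)
        f = correct_natural_abundance(v, m)
        assert f == pytest.approx(planted, abs=1e-6)

    def test_noisy_monte_carlo_recovery(self):
        """Mean recovered M+2 fraction within 0.01 of planted at 5% noise."""
        rng = np.random.default_rng(42)
        planted = np.array([0.75, 0.0, 0.2, 0.0, 0.05])
        m = build_correction_matrix(16, 0.0107, size=5)
        envelope = m @ planted
        sigma = np.sqrt(np.log1p(0.05**2))
        recovered = []
        for _ in range(200):
            noisy = envelope * np.exp(rng.normal(0, sigma, size=5))
            f = correct_natural_abundance(IsotopologueVector("FA 16:0", 16, noisy), m)
            recovered.append(f[2])
        assert abs(np.mean(recovered) - planted[2]) < 0.01

    def test_fractions_nonnegative_and_sum_one_under_noise(self):
        rng = np.random.default_rng(3)
        m = build_correction_matrix(18, 0.0107, size=5)
        for _ in range(50):
            raw = np.abs(rng.normal(1.0, 0.5, size=5))
            f = correct_natural_abundance(IsotopologueVector("FA 18:0", 18, raw), m)
            assert np.all(f >= 0)
            assert f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_vector_rejected(self):
        m = build_correction_matrix(4, 0.0107)
        with pytest.raises(ValueError, match="all-zero"):
            correct_natural_abundance(IsotopologueVector("FA 4:0", 4, np.zeros(5)), m)


class TestLabelingRatio:
    def test_basic_arithmetic(self):
        r = labeling_ratio([0.8, 0.0, 0.2])
        assert r.m2_over_m0 == pytest.approx(0.25)
        assert r.m4_over_m0 is None

    def test_unlabeled_is_zero(self):
        assert labeling_ratio([1.0, 0.0, 0.0]).m2_over_m0 == 0.0

    def test_m4_reported_missing_for_short_vectors(self):
        r = labeling_ratio([0.5, 0.1, 0.2, 0.2])  # K = 3
        assert r.m4_over_m0 is None and "M+4" in r.reason

    def test_zero_m0_reported_missing_never_infinite(self):
        r = labeling_ratio([0.0, 0.0, 1.0])
        assert r.m2_over_m0 is None and r.m4_over_m0 is None
        assert "M+0" in r.reason

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e6),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_scale_invariance_through_correction(self, scale, seed):
        rng = np.random.default_rng(seed)
        raw = rng.dirichlet(np.ones(5)) + 0.01
        m = build_correction_matrix(16, 0.0107, size=5)
        f1 = correct_natural_abundance(IsotopologueVector("FA 16:0", 16, raw), m)
        f2 = correct_natural_abundance(IsotopologueVector("FA 16:0", 16, raw * scale), m)
        r1, r2 = labeling_ratio(f1), labeling_ratio(f2)
        assert r1.m2_over_m0 == pytest.approx(r2.m2_over_m0, rel=1e-9)


class TestInternalStandards:
    def test_division_by_matched_standard(self):
        rows = [("FA 18:1", 18, 2000.0)]
        out = normalize_to_internal_standard(rows, {"FA(16:0 d31)": 1000.0})
        assert out == [("FA 18:1", 2.0, True)]

    def test_c20_analyte_uses_c20_standard(self):
        rows = [("FA 20:4", 20, 500.0)]
        out = normalize_to_internal_standard(
            rows, {"FA(16:0 d31)": 1000.0, "FA(20:4 d8)": 250.0}
        )
        assert out == [("FA 20:4", 2.0, True)]

    def test_standard_normalized_to_itself_is_one(self):
        rows = [("FA(16:0 d31)", 16, 777.0)]
        out = normalize_to_internal_standard(rows, {"FA(16:0 d31)": 777.0})
        assert out == [("FA(16:0 d31)", 1.0, True)]

    def test_unmatched_analyte_flagged_unnormalized(self):
        rows = [("FA 24:0", 24, 100.0)]
        with pytest.warns(UserWarning, match="no internal-standard rule"):
            out = normalize_to_internal_standard(rows, {"FA(16:0 d31)": 1.0})
        assert out == [("FA 24:0", 100.0, False)]

    def test_zero_standard_rejects_sample(self):
        with pytest.raises(ValueError, match="rejected"):
            normalize_to_internal_standard(
                [("FA 16:0", 16, 1.0)], {"FA(16:0 d31)": 0.0}
            )

    def test_rule_sets_are_disjoint(self):
        for rules in (GCMS_STANDARD_RULES, SOLVENT_STANDARD_RULES):
            for c in range(0, 25):
                assert sum(r.matches(c) for r in rules) <= 1

    def test_solvent_rule_set_selectable(self):
        rows = [("FA 18:1", 18, 100.0)]
        out = normalize_to_internal_standard(
            rows, {"FA(18:1 d5)": 50.0}, rules=SOLVENT_STANDARD_RULES
        )
        assert out == [("FA 18:1", 2.0, True)]
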