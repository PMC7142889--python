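"""Probability scores: normal-tail calibration, monotonicity, ranking, filtering."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from lipannot.chem import IsotopePattern
from lipannot.scoring import (
    ErrorModel,
    ScoreTriple,
    Thresholds,
    combined_score,
    filter_annotations,
    isotope_fidelity_probability,
    mass_match_probability,
    msms_match_probability,
    rank_cross_class_candidates,
    two_sided_tail,
)

MODEL = ErrorModel()


class TestTailCalibration:
    """The z -> p mapping matches the normal-CDF closed form 2(1 - Phi(|z|))."""

    @pytest.mark.parametrize(
        "z,expected", [(0.0, 1.0), (1.0, 0.3173), (1.96, 0.0500), (-1.0, 0.3173)]
    )
    def test_reference_points(self, z, expected):
        assert two_sided_tail(z) == pytest.approx(expected, abs=1e-3)

    def test_matches_scipy_cdf(self):
        for z in np.linspace(-4, 4, 33):
            assert two_sided_tail(z) == pytest.approx(
                2 * (1 - scipy.stats.norm.cdf(abs(z))), abs=1e-12
            )


class TestMassMatch:
    def test_zero_error_is_one(self):
        assert mass_match_probability(760.0, 760.0, MODEL) == 1.0

    def test_one_sigma(self):
        theo = 760.0
        obs = theo * (1 + MODEL.sigma_ppm * 1e-6)
        assert mass_match_probability(obs, theo, MODEL) == pytest.approx(0.3173, abs=1e-3)

    def test_196_sigma(self):
        theo = 760.0
        obs = theo * (1 + 1.96 * MODEL.sigma_ppm * 1e-6)
        assert mass_match_probability(obs, theo, MODEL) == pytest.approx(0.0500, abs=1e-3)

    def test_monotone_in_error(self):
        theo = 500.0
        ps = [
            mass_match_probability(theo * (1 + d * 1e-6), theo, MODEL)
            for d in np.linspace(0, 30, 40)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_mz(self):
        with pytest.raises(ValueError):
            mass_match_probability(-1.0, 760.0, MODEL)


class TestIsotopeFidelity:
    def test_perfect_match(self):
        theo = IsotopePattern(np.array([1.0, 0.45, 0.11]))
        assert isotope_fidelity_probability(theo, theo, MODEL, k_peaks=2) == 1.0

    def test_one_sigma_everywhere(self):
        theo = IsotopePattern(np.array([1.0, 0.45, 0.11]))
        obs = IsotopePattern(
            np.array([
                1.0,
                0.45 * (1 + MODEL.sigma_isotope_rel),
                0.11 * (1 + MODEL.sigma_isotope_rel),
            ])
        )
        p = isotope_fidelity_probability(obs, theo, MODEL, k_peaks=2)
        assert p == pytest.approx(0.3173, abs=1e-3)

    def test_missing_envelope_of_large_lipid(self):
        """A lipid with theoretical A+1 ~ 0.45 observed with no isotopes at
        all scores below 0.05 (z = 1/sigma)."""
        theo = IsotopePattern(np.array([1.0, 0.45, 0.11]))
        obs = IsotopePattern(np.array([1.0]))
        p = isotope_fidelity_probability(obs, theo, MODEL, k_peaks=2)
        oracle = math.sqrt(
            two_sided_tail(1 / MODEL.sigma_isotope_rel) ** 2
        )
        assert p < 0.05
        assert p == pytest.approx(oracle, rel=1e-6)

    def test_requires_base_normalized(self):
        with pytest.raises(ValueError):
            isotope_fidelity_probability(
                IsotopePattern(np.array([0.9, 0.1])),
                IsotopePattern(np.array([1.0, 0.1])),
                MODEL,
            )

    def test_monotone_in_deviation(self):
        theo = IsotopePattern(np.array([1.0, 0.45]))
        ps = [
            isotope_fidelity_probability(
                IsotopePattern(np.array([1.0, 0.45 + d])), theo, MODEL, k_peaks=1
            )
            for d in np.linspace(0, 0.4, 30)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestMsmsMatch:
    def test_exact_fit(self):
        obs = np.array([100.0, 30.0, 10.0])
        assert msms_match_probability(obs, obs, MODEL) == 1.0

    def test_half_unexplained(self):
        obs = np.array([100.0, 100.0])
        fit = np.array([100.0, 0.0])
        # r = 0.5, sigma 0.5 -> z = 1
        assert msms_match_probability(obs, fit, MODEL) == pytest.approx(0.3173, abs=1e-3)

    def test_zero_overlap_is_minimal(self):
        obs = np.array([100.0, 50.0])
        fit = np.zeros(2)
        p = msms_match_probability(obs, fit, MODEL)
        assert p == pytest.approx(two_sided_tail(1.0 / MODEL.sigma_fragment_rel), rel=1e-9)

    def test_empty_composite_sentinel(self):
        assert math.isnan(msms_match_probability(np.array([]), np.array([]), MODEL))

    def test_monotone_in_residual(self):
        obs = np.array([100.0])
        ps = [
            msms_match_probability(obs, np.array([100.0 - d]), MODEL)
            for d in np.linspace(0, 100, 25)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestCombined:
    @pytest.mark.parametrize(
        "triple,expected",
        [((1.0, 1.0, 1.0), 100.0), ((0.5, 0.5, 0.5), 12.5), ((1.0, 0.0, 1.0), 0.0)],
    )
    def test_product(self, triple, expected):
        assert combined_score(*triple).combined == pytest.approx(expected)

    @settings(max_examples=60, derandomize=True)
    @given(
        p1=st.floats(0, 1), p2=st.floats(0, 1), p3=st.floats(0, 1)
    )
    def test_range_and_perfection(self, p1, p2, p3):
        s = combined_score(p1, p2, p3)
        assert 0.0 <= s.combined <= 100.0
        assert (s.combined == 100.0) == (p1 == p2 == p3 == 1.0)


class TestRanking:
    def test_diagnostic_fragment_wins(self):
        pc = ("PC(35:1) [M+H]+", ScoreTriple(0.9, 0.9, 0.95))
        pe = ("PE(36:1) [M+H]+", ScoreTriple(0.9, 0.9, 0.10))
        winner, margin, ranked = rank_cross_class_candidates([pe, pc])
        assert winner.name.startswith("PC")
        assert margin == pytest.approx(0.95 / 0.10, rel=1e-9)

    def test_single_candidate_posterior_one(self):
        winner, margin, ranked = rank_cross_class_candidates(
            [("PC(34:1) [M+H]+", ScoreTriple(0.5, 0.5, 0.5))]
        )
        assert winner.posterior == 1.0
        assert margin == math.inf

    def test_tie_breaks_lexicographic(self):
        s = ScoreTriple(0.8, 0.8, 0.8)
        winner, margin, _ = rank_cross_class_candidates([("B", s), ("A", s)])
        assert winner.name == "A"
        assert margin == pytest.approx(1.0)

    def test_order_invariant(self):
        cands = [
            ("PC", ScoreTriple(0.9, 0.8, 0.7)),
            ("PE", ScoreTriple(0.5, 0.9, 0.6)),
            ("SM", ScoreTriple(0.7, 0.7, 0.9)),
        ]
        w1, m1, _ = rank_cross_class_candidates(cands)
        w2, m2, _ = rank_cross_class_candidates(cands[::-1])
        assert w1.name == w2.name
        assert m1 == pytest.approx(m2)

    def test_no_candidates_raises(self):
        with pytest.raises(ValueError):
            rank_cross_class_candidates([])


class _R:
    def __init__(self, p1, p2, p3):
        self.scores = ScoreTriple(p1, p2, p3)


class TestFilter:
    def test_zero_thresholds_identity(self):
        results = [_R(0.01, 0.01, 0.01), _R(1, 1, 1)]
        kept, removed = filter_annotations(results, Thresholds(0, 0, 0, 0))
        assert kept == results
        assert sum(removed.values()) == 0

    def test_perfect_only(self):
        results = [_R(1, 1, 1), _R(1, 1, 0.999)]
        kept, _ = filter_annotations(results, Thresholds(0, 0, 0, 100.0))
        assert kept == [results[0]]

    def test_removal_counts_match_hand_count(self):
        th = Thresholds(mass=0.5, isotope=0.5, msms=0.5, combined=20.0)
        results = [
            _R(0.9, 0.9, 0.9),   # keep: combined 72.9
            _R(0.4, 0.9, 0.9),   # fails mass + combined (32.4 ok, mass 0.4 < 0.5 -> combined 32.4 >= 20)
            _R(0.9, 0.4, 0.9),   # fails isotope
            _R(0.9, 0.9, 0.1),   # fails msms + combined (8.1)
            _R(0.6, 0.6, 0.6),   # keep: combined 21.6
        ]
        kept, removed = filter_annotations(results, th)
        assert len(kept) == 2
        assert removed["mass"] == 1
        assert removed["isotope"] == 1
        assert removed["msms"] == 1
        assert removed["combined"] == 1

    def test_msms_sentinel_always_removed(self):
        kept, removed = filter_annotations(
            [_R(1.0, 1.0, float("nan"))], Thresholds(0, 0, 0, 0)
        )
        assert kept == []
        assert removed["msms"] == 1
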