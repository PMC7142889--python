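"""NNLS deconvolution: design matrix, percent abundances, level rule,
per-feature annotation."""

import numpy as np
import pytest

from lipannot.deconvolution import (
    DesignMatrix,
    MixtureFit,
    annotate_feature,
    build_design_matrix,
    decide_annotation_level,
    nnls_percent_abundance,
)
from lipannot.feature_finding import ChromatographicFeature, CompositeMS2
from lipannot.library import in_silico_spectrum
from lipannot.nomenclature import parse_lipid_name
from lipannot.scoring import ErrorModel, Thresholds


def _feature(mz, rt=5.0, isotopes=None):
    f = ChromatographicFeature(
        mz=mz, rt_apex=rt, rt_start=rt - 0.2, rt_end=rt + 0.2,
        height=1e6, area=1e4, quality=1.0,
    )
    if isotopes is not None:
        from lipannot.chem import IsotopePattern

        f.observed_isotopes = IsotopePattern(np.asarray(isotopes))
    return f


def _composite(feature, mzs, ints):
    return CompositeMS2(
        feature=feature, mz=np.asarray(mzs, float), intensity=np.asarray(ints, float),
        n_scans_averaged=1, precursor_mz=feature.mz,
    )


def _spectrum_pair(class_defs):
    a = in_silico_spectrum(parse_lipid_name("PC(16:0_18:1)"), "[M+H]+", class_defs["PC"])
    b = in_silico_spectrum(parse_lipid_name("PC(14:0_20:1)"), "[M+H]+", class_defs["PC"])
    return a, b


class TestDesignMatrix:
    def test_shared_fragment_bin(self, class_defs):
        a, b = _spectrum_pair(class_defs)
        feature = _feature(a.precursor_mz)
        comp = _composite(feature, [184.0733], [100.0])
        design = build_design_matrix([a, b], comp)
        # the phosphocholine bin is shared: two nonzero candidate entries
        i = int(np.argmin(np.abs(design.bins - 184.0733)))
        assert (design.matrix[i] > 0).sum() == 2
        assert design.observed[i] == 100.0

    def test_close_fragments_merge(self, class_defs):
        a, _ = _spectrum_pair(class_defs)
        feature = _feature(a.precursor_mz)
        # observed peak 10 ppm from the candidate fragment: same bin at 20 ppm
        comp = _composite(feature, [184.0733 * (1 + 10e-6)], [50.0])
        design = build_design_matrix([a], comp, frag_tol_ppm=20.0)
        i = int(np.argmin(np.abs(design.bins - 184.0733)))
        assert design.observed[i] == 50.0
        assert design.matrix[i, 0] > 0

    def test_empty_composite_flagged(self, class_defs):
        a, _ = _spectrum_pair(class_defs)
        feature = _feature(a.precursor_mz)
        comp = _composite(feature, [], [])
        design = build_design_matrix([a], comp)
        assert design.degenerate
        assert np.all(design.observed == 0)

    def test_requires_candidates(self, class_defs):
        a, _ = _spectrum_pair(class_defs)
        with pytest.raises(ValueError):
            build_design_matrix([], _composite(_feature(a.precursor_mz), [], []))


class TestNnls:
    def test_single_source_exact(self, class_defs):
        a, b = _spectrum_pair(class_defs)
        feature = _feature(a.precursor_mz)
        comp = _composite(feature, [mz for mz, _, _ in a.fragments],
                          [inten * 1e4 for _, inten, _ in a.fragments])
        fit = nnls_percent_abundance(build_design_matrix([a, b], comp))
        order = np.argsort(fit.percent_abundances)[::-1]
        assert fit.candidates[order[0]].name_constituent == "PC(16:0_18:1)"
        assert fit.percent_abundances[order[0]] == pytest.approx(100.0, abs=1e-6)

    def test_70_30_mixture(self, class_defs):
        """Noise-free 0.7A + 0.3B recovers the interior solution of the
        unconstrained closed form (signal-share percents 70/30 when columns
        are L1-normalised mixtures)."""
        a, b = _spectrum_pair(class_defs)
        feature = _feature(a.precursor_mz)
        bins_a = {round(mz, 3): i for mz, i, _ in a.fragments}
        l1a = sum(i for _, i, _ in a.fragments)
        l1b = sum(i for _, i, _ in b.fragments)
        merged = {}
        for mz, i, _ in a.fragments:
            merged[round(mz, 3)] = merged.get(round(mz, 3), 0) + 0.7 * i / l1a
        for mz, i, _ in b.fragments:
            merged[round(mz, 3)] = merged.get(round(mz, 3), 0) + 0.3 * i / l1b
        mzs = sorted(merged)
        comp = _composite(feature, mzs, [merged[m] * 1e5 for m in mzs])
        fit = nnls_percent_abundance(build_design_matrix([a, b], comp))
        by_name = dict(zip((c.name_constituent for c in fit.candidates),
                           fit.percent_abundances))
        assert by_name["PC(16:0_18:1)"] == pytest.approx(70.0, abs=0.1)
        assert by_name["PC(14:0_20:1)"] == pytest.approx(30.0, abs=0.1)

    def test_orthogonal_observed_all_zero(self, class_defs):
        a, b = _spectrum_pair(class_defs)
        feature = _feature(a.precursor_mz)
        comp = _composite(feature, [350.123, 400.456], [80.0, 60.0])
        fit = nnls_percent_abundance(build_design_matrix([a, b], comp))
        np.testing.assert_allclose(fit.weights, 0.0)
        assert fit.residual_norm == pytest.approx(np.hypot(80.0, 60.0))

    def test_interior_solution_matches_closed_form(self):
        """Independent oracle: for interior optima the NNLS weights equal the
        unconstrained least-squares solution (normal equations)."""
        rng = np.random.default_rng(11)
        for _ in range(60):
            n_bins = int(rng.integers(5, 12))
            n_cand = int(rng.integers(2, 4))
            A = rng.uniform(0.05, 1.0, size=(n_bins, n_cand))
            w_true = rng.uniform(0.3, 2.0, size=n_cand)
            y = A @ w_true
            design = DesignMatrix(np.arange(n_bins, dtype=float), A, y, [None] * n_cand, False)
            fit = nnls_percent_abundance(design)
            closed = np.linalg.solve(A.T @ A, A.T @ y)
            if np.all(closed > 0):
                np.testing.assert_allclose(fit.weights, closed, rtol=1e-6)

    def test_percents_sum_to_100_and_permute(self, class_defs):
        a, b = _spectrum_pair(class_defs)
        feature = _feature(a.precursor_mz)
        comp = _composite(feature, [mz for mz, _, _ in a.fragments],
                          [inten for _, inten, _ in a.fragments])
        fit_ab = nnls_percent_abundance(build_design_matrix([a, b], comp))
        fit_ba = nnls_percent_abundance(build_design_matrix([b, a], comp))
        assert fit_ab.percent_abundances.sum() == pytest.approx(100.0, abs=1e-6)
        np.testing.assert_allclose(
            fit_ab.percent_abundances, fit_ba.percent_abundances[::-1], atol=1e-9
        )

    def test_collinear_candidates_flagged(self, class_defs):
        a, _ = _spectrum_pair(class_defs)
        feature = _feature(a.precursor_mz)
        comp = _composite(feature, [mz for mz, _, _ in a.fragments],
                          [inten for _, inten, _ in a.fragments])
        fit = nnls_percent_abundance(build_design_matrix([a, a], comp))
        assert fit.collinear


def _fit(percents, names=None):
    n = len(percents)
    names = names or [f"PC(16:0_{14 + 2 * i}:{i})" for i in range(n)]
    return MixtureFit(
        candidates=[parse_lipid_name(nm) for nm in names],
        weights=np.asarray(percents, float),
        percent_abundances=np.asarray(percents, float),
        residual_norm=0.0,
        design_bins=np.array([]),
    )


class TestAnnotationLevel:
    def test_dominant_gives_fatty_acyl(self):
        level, sp = decide_annotation_level(_fit([80.0, 15.0, 5.0]), 2.0)
        assert level == "fatty_acyl"
        assert sp.chains

    def test_mixed_gives_sum_composition(self):
        level, sp = decide_annotation_level(_fit([50.0, 30.0, 20.0]), 2.0)
        assert level == "sum_composition"
        assert sp.chains == ()
        assert sp.name_sum == sp.name_constituent

    def test_single_candidate_dominant(self):
        level, _ = decide_annotation_level(_fit([100.0]), 2.0)
        assert level == "fatty_acyl"

    def test_scale_invariant(self):
        a = decide_annotation_level(_fit([80.0, 15.0, 5.0]), 2.0)
        b = decide_annotation_level(_fit([8.0, 1.5, 0.5]), 2.0)
        assert a[0] == b[0] and a[1].name_constituent == b[1].name_constituent

    def test_ratio_validation(self):
        with pytest.raises(ValueError):
            decide_annotation_level(_fit([100.0]), 1.0)


class TestAnnotateFeature:
    def _observed_iso(self, spec, class_defs):
        from lipannot.chem import formula_add, get_adduct, theoretical_isotope_pattern
        from lipannot.library import species_formula

        f = species_formula(spec.species, class_defs[spec.species.class_abbrev])
        add = get_adduct(spec.adduct)
        ion = formula_add(f, {e: n for e, n in add.delta_formula.items() if n > 0})
        return theoretical_isotope_pattern(ion, 3).ratios

    def test_pure_species_end_to_end(self, class_defs, positive_library):
        spec = in_silico_spectrum(
            parse_lipid_name("PC(16:0_18:1)"), "[M+H]+", class_defs["PC"]
        )
        feature = _feature(spec.precursor_mz,
                           isotopes=self._observed_iso(spec, class_defs))
        comp = _composite(feature, [mz for mz, _, _ in spec.fragments],
                          [i * 1e4 for _, i, _ in spec.fragments])
        result = annotate_feature(feature, comp, positive_library, class_defs)
        assert result is not None
        assert result.name == "PC(16:0_18:1)"
        assert result.structure_level == "fatty_acyl"
        assert result.scores.combined > 90

    def test_even_mixture_gives_sum_composition(self, class_defs, positive_library):
        a, b = _spectrum_pair(class_defs)
        feature = _feature(a.precursor_mz, isotopes=self._observed_iso(a, class_defs))
        l1a = sum(i for _, i, _ in a.fragments)
        l1b = sum(i for _, i, _ in b.fragments)
        merged = {}
        for mz, i, _ in a.fragments:
            merged[round(mz, 4)] = merged.get(round(mz, 4), 0) + 0.5 * i / l1a
        for mz, i, _ in b.fragments:
            merged[round(mz, 4)] = merged.get(round(mz, 4), 0) + 0.5 * i / l1b
        mzs = sorted(merged)
        comp = _composite(feature, mzs, [merged[m] * 1e5 for m in mzs])
        result = annotate_feature(feature, comp, positive_library, class_defs)
        assert result is not None
        assert result.structure_level == "sum_composition"
        assert result.name == "PC(34:1)"

    def test_no_candidates_returns_none(self, class_defs, positive_library):
        feature = _feature(123.456)
        comp = _composite(feature, [100.0], [10.0])
        assert annotate_feature(feature, comp, positive_library, class_defs) is None

    def test_ms1_only_returns_none(self, class_defs, positive_library):
        feature = _feature(760.5851)
        assert annotate_feature(feature, None, positive_library, class_defs) is None

    def test_lpc_sn_assignment(self, class_defs, positive_library):
        spec = in_silico_spectrum(
            parse_lipid_name("LPC(18:1)"), "[M+H]+", class_defs["LPC"]
        )
        feature = _feature(spec.precursor_mz,
                           isotopes=self._observed_iso(spec, class_defs))
        comp = _composite(feature, [mz for mz, _, _ in spec.fragments],
                          [i * 1e4 for _, i, _ in spec.fragments])
        result = annotate_feature(feature, comp, positive_library, class_defs)
        assert result is not None
        assert result.name == "LPC(0:0/18:1)"
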