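"""NNLS deconvolution of composite MS/MS spectra and feature annotation.

Co-eluting lipid isomers of one sum composition are co-isolated in DDA and
produce a mixed MS/MS spectrum.  Candidate in silico spectra are laid out on
a shared fragment-bin grid (the design matrix); non-negative least squares
finds the candidate weights whose cumulative predicted signal best matches
the observed composite.  Percent abundance of each constituent is its share
of the explained signal (weight times column L1 norm).  The feature is then
annotated at fatty-acyl level only when the top constituent dominates the
runner-up by a configurable ratio; otherwise the sum-composition name is
used — the annotation reflects only what the spectral evidence supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .chem import formula_add, get_adduct, theoretical_isotope_pattern
from .feature_finding import ChromatographicFeature, CompositeMS2
from .library import InSilicoSpectrum, LipidClassDef, SpectralLibrary
from .nomenclature import LipidSpecies
from .scoring import (
    ErrorModel,
    ScoreTriple,
    Thresholds,
    combined_score,
    isotope_fidelity_probability,
    mass_match_probability,
    msms_match_probability,
    rank_cross_class_candidates,
)


@dataclass
class DesignMatrix:
    bins: np.ndarray  # fragment m/z bin centers
    matrix: np.ndarray  # (n_bins, n_candidates) predicted relative intensities
    observed: np.ndarray  # observed intensity per bin
    candidates: list[InSilicoSpectrum]
    degenerate: bool  # no candidate fragment overlaps any observed signal


@dataclass
class MixtureFit:
    candidates: list[LipidSpecies]
    weights: np.ndarray
    percent_abundances: np.ndarray
    residual_norm: float
    design_bins: np.ndarray
    fitted: np.ndarray = field(default_factory=lambda: np.array([]))
    collinear: bool = False
    degenerate: bool = False


@dataclass
class AnnotationResult:
    feature: ChromatographicFeature
    species_or_sum: LipidSpecies
    structure_level: str  # "sum_composition" | "fatty_acyl"
    adduct: str
    scores: ScoreTriple
    mixture: MixtureFit | None
    name: str
    margin: float = float("inf")
    flags: tuple[str, ...] = ()


def build_design_matrix(
    candidate_spectra: list[InSilicoSpectrum],
    composite: CompositeMS2,
    frag_tol_ppm: float = 20.0,
) -> DesignMatrix:
    """Align candidate fragments and observed peaks on a merged bin grid.

    Bin edges come from a greedy ascending-m/z merge: consecutive entries
    (candidate fragments and observed peaks pooled) closer than the tolerance
    collapse into one bin.  The observed vector holds zeros where only
    candidates predict signal; observed peaks no candidate explains get their
    own bins so they count against the fit.
    """
    if not candidate_spectra:
        raise ValueError("candidates must be non-empty")
    if frag_tol_ppm <= 0:
        raise ValueError("frag_tol_ppm must be > 0")
    events: list[tuple[float, int, float]] = []  # (mz, source, intensity)
    for j, spec in enumerate(candidate_spectra):
        for mz, inten, _label in spec.fragments:
            events.append((mz, j, inten))
    for mz, inten in zip(composite.mz, composite.intensity):
        events.append((float(mz), -1, float(inten)))
    events.sort()

    bins: list[list[tuple[float, int, float]]] = []
    for ev in events:
        if bins and ev[0] - bins[-1][-1][0] <= max(ev[0] * frag_tol_ppm * 1e-6, 1e-6):
            bins[-1].append(ev)
        else:
            bins.append([ev])

    n_bins, n_cand = len(bins), len(candidate_spectra)
    matrix = np.zeros((n_bins, n_cand))
    observed = np.zeros(n_bins)
    centers = np.zeros(n_bins)
    for i, group in enumerate(bins):
        centers[i] = np.mean([g[0] for g in group])
        for _mz, src, inten in group:
            if src < 0:
                observed[i] += inten
            else:
                matrix[i, src] += inten
    degenerate = bool(matrix.sum() == 0 or matrix[observed > 0].sum() == 0)
    return DesignMatrix(centers, matrix, observed, list(candidate_spectra), degenerate)


def nnls_percent_abundance(design: DesignMatrix) -> MixtureFit:
    """Fit candidate weights by NNLS and convert to percent abundances.

    percent_i = 100 * w_i * ||col_i||_1 / sum_j w_j * ||col_j||_1 — each
    candidate's share of the explained signal, so candidates predicting few
    fragments are not inflated relative to fragment-rich ones.  A
    rank-deficient design (collinear candidate spectra) still returns a fit
    but sets the collinearity flag.
    """
    if design.matrix.shape[1] < 1:
        raise ValueError("design must have at least one candidate column")
    weights, residual = scipy.optimize.nnls(design.matrix, design.observed)
    l1 = np.abs(design.matrix).sum(axis=0)
    signal = weights * l1
    total = signal.sum()
    percents = 100.0 * signal / total if total > 0 else np.zeros_like(signal)
    collinear = (
        design.matrix.shape[1] > 1
        and np.linalg.matrix_rank(design.matrix, tol=1e-10) < design.matrix.shape[1]
    )
    return MixtureFit(
        candidates=[getattr(s, "species", s) for s in design.candidates],
        weights=weights,
        percent_abundances=percents,
        residual_norm=float(residual),
        design_bins=design.bins,
        fitted=design.matrix @ weights,
        collinear=collinear,
        degenerate=design.degenerate,
    )


def decide_annotation_level(
    fit: MixtureFit, dominance_ratio: float = 2.0
) -> tuple[str, LipidSpecies]:
    """Fatty-acyl name only when a constituent dominates the mixture.

    The top constituent wins fatty-acyl annotation iff its percent abundance
    is at least ``dominance_ratio`` times the runner-up's (a zero runner-up
    always counts as dominated).  Otherwise the sum-composition name stands.
    Depends only on percent ratios, hence scale-invariant.
    """
    if dominance_ratio <= 1:
        raise ValueError("dominance_ratio must be > 1")
    order = np.argsort(fit.percent_abundances)[::-1]
    top = int(order[0])
    top_pct = float(fit.percent_abundances[top])
    second_pct = float(fit.percent_abundances[order[1]]) if len(order) > 1 else 0.0
    winner = fit.candidates[top]
    if top_pct > 0 and (second_pct == 0 or top_pct >= dominance_ratio * second_pct):
        return "fatty_acyl", winner
    summary = LipidSpecies(
        winner.class_abbrev,
        (),
        False,
        winner.total_carbons,
        winner.total_double_bonds,
        winner.formula,
    )
    return "sum_composition", summary


# ---------------------------------------------------------------------------
# per-feature annotation pipeline


def _group_candidates(
    hits: list[InSilicoSpectrum],
) -> dict[tuple[str, int, int, str], list[InSilicoSpectrum]]:
    """Group library hits by (class, total C, total DB, adduct)."""
    groups: dict[tuple[str, int, int, str], list[InSilicoSpectrum]] = {}
    for h in hits:
        key = (*h.species.sum_key, h.adduct)
        groups.setdefault(key, []).append(h)
    return groups


def _lpc_sn_name(
    winner: LipidSpecies, composite: CompositeMS2, frag_tol_ppm: float
) -> str | None:
    """sn-position call for LPC from the m/z 104.107 choline diagnostic.

    The 104 fragment is unique to an acyl chain in the sn2 position of LPC
    [M+H]+; when observed, the single chain is placed at sn2 and the name is
    emitted with the sn-resolved '/' separator.
    """
    if winner.class_abbrev != "LPC" or len(winner.chains) != 1:
        return None
    diag = 104.1070
    tol = max(diag * frag_tol_ppm * 1e-6, 0.01)
    idx = np.flatnonzero(np.abs(composite.mz - diag) <= tol)
    if idx.size and composite.intensity[idx].sum() > 0:
        c, d = winner.chains[0]
        return f"LPC(0:0/{c}:{d})"
    return None


def annotate_feature(
    feature: ChromatographicFeature,
    composite: CompositeMS2 | None,
    library: SpectralLibrary,
    class_defs: dict[str, LipidClassDef],
    error_model: ErrorModel | None = None,
    thresholds: Thresholds | None = None,
    dominance_ratio: float = 2.0,
    mz_tol_ppm: float = 20.0,
    frag_tol_ppm: float = 20.0,
    k_isotopes: int = 2,
) -> AnnotationResult | None:
    """Annotate one feature: lookup -> rank across classes -> NNLS -> level.

    Features without MS/MS evidence are left unannotated (None) to limit
    false positives from in-source fragments and solvent clusters.  Returns
    None as well when no library candidate falls in the precursor window or
    when the winning annotation fails the score thresholds.
    """
    if error_model is None:
        error_model = ErrorModel()
    if thresholds is None:
        thresholds = Thresholds()
    if composite is None or composite.mz.size == 0:
        return None
    hits = library.lookup(feature.mz, tol_ppm=mz_tol_ppm)
    if not hits:
        return None

    scored: list[tuple[str, ScoreTriple]] = []
    payloads: list[tuple] = []
    for key, members in sorted(_group_candidates(hits).items()):
        cls, tc, td, adduct = key
        prec = float(np.mean([m.precursor_mz for m in members]))
        p_mass = mass_match_probability(feature.mz, prec, error_model)
        formula = members[0].species.formula
        if formula is not None:
            add = get_adduct(adduct)
            ion_formula = formula_add(
                formula, {e: n for e, n in add.delta_formula.items() if n > 0}
            )
            theo_iso = theoretical_isotope_pattern(ion_formula, k_isotopes + 1)
            p_iso = isotope_fidelity_probability(
                feature.observed_isotopes, theo_iso, error_model, k_isotopes
            )
        else:
            p_iso = 1.0
        design = build_design_matrix(members, composite, frag_tol_ppm)
        fit = nnls_percent_abundance(design)
        p_msms = msms_match_probability(design.observed, fit.fitted, error_model)
        name = f"{cls}({tc}:{td}) {adduct}"
        scored.append((name, combined_score(p_mass, p_iso, p_msms)))
        payloads.append((key, fit))

    winner, margin, _ranked = rank_cross_class_candidates(scored, payloads)
    (cls, tc, td, adduct), fit = winner.payload
    level, species = decide_annotation_level(fit, dominance_ratio)
    name = species.name_sum if level == "sum_composition" else species.name_constituent
    if level == "fatty_acyl":
        sn_name = _lpc_sn_name(species, composite, frag_tol_ppm)
        if sn_name is not None:
            name = sn_name
    flags = tuple(
        f for f, on in [("collinear", fit.collinear), ("degenerate", fit.degenerate)] if on
    )
    result = AnnotationResult(
        feature=feature,
        species_or_sum=species,
        structure_level=level,
        adduct=adduct,
        scores=winner.scores,
        mixture=fit,
        name=name,
        margin=margin,
        flags=flags,
    )
    s = result.scores
    if (
        s.p_mass < thresholds.mass
        or s.p_isotope < thresholds.isotope
        or math.isnan(s.p_msms)
        or s.p_msms < thresholds.msms
        or s.combined < thresholds.combined
    ):
        return None
    return result


@dataclass
class AnnotateStats:
    n_features: int = 0
    n_with_ms2: int = 0
    n_with_candidates: int = 0
    n_annotated: int = 0
    removed: dict = field(default_factory=dict)


def annotate_run(
    run,
    library: SpectralLibrary,
    class_defs: dict[str, LipidClassDef],
    error_model: ErrorModel | None = None,
    thresholds: Thresholds | None = None,
    dominance_ratio: float = 2.0,
    mz_tol_ppm: float = 20.0,
    precursor_tol_da: float = 0.7,
    min_height: float = 1000.0,
    min_points: int = 3,
    k_isotopes: int = 2,
) -> tuple[list[AnnotationResult], AnnotateStats]:
    """Full pipeline on a run: EICs -> features -> MS2 -> annotation."""
    from .feature_finding import (
        associate_and_average_ms2,
        attach_isotopes,
        detect_features,
        extract_eics,
    )
    from .scoring import filter_annotations

    if error_model is None:
        error_model = ErrorModel()
    if thresholds is None:
        thresholds = Thresholds()
    traces = extract_eics(run, mz_tol_ppm=mz_tol_ppm)
    features = detect_features(traces, min_height=min_height, min_points=min_points)
    stats = AnnotateStats(n_features=len(features))
    prelim: list[AnnotationResult] = []
    for feature in features:
        attach_isotopes(feature, run, mz_tol_ppm=mz_tol_ppm, n_peaks=k_isotopes + 1)
        composite = associate_and_average_ms2(
            feature, run, precursor_tol_da=precursor_tol_da
        )
        if composite is None:
            continue
        stats.n_with_ms2 += 1
        if library.lookup(feature.mz, tol_ppm=mz_tol_ppm):
            stats.n_with_candidates += 1
        # thresholds applied collectively below so removal counts are reported
        result = annotate_feature(
            feature,
            composite,
            library,
            class_defs,
            error_model=error_model,
            thresholds=Thresholds(0.0, 0.0, 0.0, 0.0),
            dominance_ratio=dominance_ratio,
            mz_tol_ppm=mz_tol_ppm,
            k_isotopes=k_isotopes,
        )
        if result is not None:
            prelim.append(result)
    kept, removed = filter_annotations(prelim, thresholds)
    stats.removed = removed
    stats.n_annotated = len(kept)
    return kept, stats
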