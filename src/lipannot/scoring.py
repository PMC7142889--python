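"""Probability scores for candidate lipid annotations.

Three evidence channels — precursor mass accuracy, isotope-pattern fidelity,
and MS/MS match quality — are scored independently under normal error models
and combined multiplicatively into a final score normalised to 100.  Each
channel maps its standardized error z to the two-sided normal tail
probability 2(1 - Phi(|z|)), which lives natively in [0, 1]: a perfect match
scores 1, a 1-sigma error 0.3173, a 1.96-sigma error 0.05.

Cross-class candidate ranking treats the combined probabilities as
likelihoods under a uniform prior (every candidate lipid equally likely a
priori) and picks the posterior mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import IsotopePattern

#: sentinel for features with no MS/MS evidence (excluded from confirmed output)
MSMS_UNAVAILABLE = float("nan")


@dataclass(frozen=True)
class ErrorModel:
    """Normal error widths for the three evidence channels.

    sigma_ppm            - precursor mass error std, ppm
    sigma_isotope_rel    - relative error std on each A+k isotope ratio
    sigma_fragment_rel   - std of the MS/MS residual fraction
    isotope_rel_floor    - lower bound on the ratio used to scale isotope
                           errors, so near-zero theoretical ratios do not
                           blow up the z-score
    """

    sigma_ppm: float = 5.0
    sigma_isotope_rel: float = 0.15
    sigma_fragment_rel: float = 0.5
    isotope_rel_floor: float = 0.01

    def __post_init__(self):
        for name in ("sigma_ppm", "sigma_isotope_rel", "sigma_fragment_rel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Thresholds:
    """Per-score minima for keeping an annotation (user modifiable)."""

    mass: float = 0.05
    isotope: float = 0.05
    msms: float = 0.05
    combined: float = 1.0  # on the 0-100 scale


@dataclass(frozen=True)
class ScoreTriple:
    p_mass: float
    p_isotope: float
    p_msms: float

    @property
    def combined(self) -> float:
        p3 = 0.0 if math.isnan(self.p_msms) else self.p_msms
        return 100.0 * self.p_mass * self.p_isotope * p3


def two_sided_tail(z: float) -> float:
    """P(|Z| >= |z|) for standard normal Z, i.e. 2(1 - Phi(|z|))."""
    return math.erfc(abs(z) / math.sqrt(2.0))


def mass_match_probability(
    observed_mz: float, theoretical_mz: float, model: ErrorModel
) -> float:
    """Two-sided tail probability of the observed ppm mass error."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    dppm = 1e6 * (observed_mz - theoretical_mz) / theoretical_mz
    return two_sided_tail(dppm / model.sigma_ppm)


def isotope_fidelity_probability(
    observed: IsotopePattern,
    theoretical: IsotopePattern,
    model: ErrorModel,
    k_peaks: int = 2,
) -> float:
    """Geometric-mean tail probability over the A+1..A+k isotope ratios.

    Each ratio's error is standardized by sigma_isotope_rel times the
    theoretical ratio (floored); an isotopologue missing from the observed
    envelope counts as ratio 0.
    """
    if observed.ratios[0] != 1.0 or theoretical.ratios[0] != 1.0:
        raise ValueError("patterns must be base-normalized (entry 0 = 1.0)")
    logs = []
    for k in range(1, k_peaks + 1):
        theo = theoretical.ratios[k] if k < len(theoretical) else 0.0
        obs = observed.ratios[k] if k < len(observed) else 0.0
        scale = model.sigma_isotope_rel * max(theo, model.isotope_rel_floor)
        p = two_sided_tail((obs - theo) / scale)
        logs.append(math.log(max(p, 1e-300)))
    return math.exp(sum(logs) / len(logs)) if logs else 1.0


def msms_residual_fraction(
    observed: np.ndarray, fitted: np.ndarray
) -> float:
    """Absolute residual of the fitted composite model as a fraction of the
    total observed fragment intensity.  Unexplained experimental intensity
    (artifact peaks no candidate predicts) counts fully in the numerator."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    total = observed.sum()
    if total <= 0:
        return 1.0
    return float(np.abs(observed - fitted).sum() / total)


def msms_match_probability(
    observed: np.ndarray, fitted: np.ndarray, model: ErrorModel
) -> float:
    """Tail probability of the MS/MS residual fraction.

    ``observed`` and ``fitted`` are intensity vectors aligned on the same
    fragment bins (see deconvolution.build_design_matrix); ``fitted`` is the
    NNLS-weighted sum of candidate spectra on the observed intensity scale.
    An empty composite has no defined MS/MS probability: the sentinel
    MSMS_UNAVAILABLE (NaN) is returned.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0 or observed.sum() <= 0:
        return MSMS_UNAVAILABLE
    r = msms_residual_fraction(observed, fitted)
    return two_sided_tail(r / model.sigma_fragment_rel)


def combined_score(p_mass: float, p_isotope: float, p_msms: float) -> ScoreTriple:
    """Bundle the three probabilities; combined = 100 * product."""
    return ScoreTriple(p_mass, p_isotope, p_msms)


# ---------------------------------------------------------------------------
# cross-class candidate ranking


@dataclass(frozen=True)
class RankedCandidate:
    name: str
    scores: ScoreTriple
    posterior: float
    payload: object = field(default=None, compare=False)


def rank_cross_class_candidates(
    candidates: list[tuple[str, ScoreTriple]],
    payloads: list[object] | None = None,
) -> tuple[RankedCandidate, float, list[RankedCandidate]]:
    """Choose the most probable sum composition among co-isolated candidates.

    Under a uniform prior the posterior of each candidate is its combined
    probability product renormalised over candidates.  Ties break by higher
    p_msms, then lexicographic name (deterministic).  Returns (winner,
    margin, ranked) where margin = winner posterior / runner-up posterior
    (``inf`` for a single candidate or a zero runner-up).
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    if payloads is None:
        payloads = [None] * len(candidates)
    weights = []
    for _name, s in candidates:
        p3 = 0.0 if math.isnan(s.p_msms) else s.p_msms
        weights.append(s.p_mass * s.p_isotope * p3)
    total = sum(weights)
    posts = [w / total if total > 0 else 1.0 / len(weights) for w in weights]
    ranked = sorted(
        (
            RankedCandidate(name, s, post, payload)
            for (name, s), post, payload in zip(candidates, posts, payloads)
        ),
        key=lambda rc: (
            -rc.posterior,
            -(0.0 if math.isnan(rc.scores.p_msms) else rc.scores.p_msms),
            rc.name,
        ),
    )
    winner = ranked[0]
    if len(ranked) == 1 or ranked[1].posterior == 0.0:
        margin = float("inf")
    else:
        margin = winner.posterior / ranked[1].posterior
    return winner, margin, ranked


def filter_annotations(
    results: list, thresholds: Thresholds
) -> tuple[list, dict[str, int]]:
    """Keep annotations passing every per-score minimum and the combined one.

    Returns (kept, removal_counts) where removal_counts tallies, per
    criterion, how many results failed it (a result can fail several).
    """
    removed = {"mass": 0, "isotope": 0, "msms": 0, "combined": 0}
    kept = []
    for r in results:
        s = r.scores
        ok = True
        if s.p_mass < thresholds.mass:
            removed["mass"] += 1
            ok = False
        if s.p_isotope < thresholds.isotope:
            removed["isotope"] += 1
            ok = False
        if math.isnan(s.p_msms) or s.p_msms < thresholds.msms:
            removed["msms"] += 1
            ok = False
        if s.combined < thresholds.combined:
            removed["combined"] += 1
            ok = False
        if ok:
            kept.append(r)
    return kept, removed
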