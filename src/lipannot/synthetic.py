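"""Ground-truth synthetic LC-MS/MS runs for testing every pipeline stage.

The generator plants lipid species as Gaussian chromatographic peaks with
theoretical isotope envelopes, schedules top-N data-dependent MS/MS with
dynamic exclusion, and builds MS2 spectra as proportion-weighted sums of the
in silico spectra of the planted constituents (co-eluting isomer mixtures at
planted proportions) plus configurable noise.  Every run comes with a truth
table.  All randomness is drawn from a single seeded generator, so a fixed
seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import theoretical_isotope_pattern, formula_add, get_adduct
from .constants import ISOTOPE_MZ_SPACING
from .library import (
    LipidClassDef,
    default_class_defs,
    in_silico_spectrum,
    species_formula,
)
from .nomenclature import LipidSpecies
from .spectra_io import Run, Scan


@dataclass(frozen=True)
class PlantedAnalyte:
    """One planted precursor: a species plus optional co-eluting isomers.

    ``mixture_partners`` lists (species, proportion) pairs sharing the same
    precursor m/z and retention time; the lead species takes the remaining
    proportion so that all proportions sum to 1.
    """

    species: LipidSpecies
    adduct: str
    rt_apex: float  # minutes
    peak_sigma: float = 0.05  # minutes
    height: float = 1e6
    mixture_partners: tuple[tuple[LipidSpecies, float], ...] = ()

    def __post_init__(self):
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be > 0")
        partner_total = sum(p for _, p in self.mixture_partners)
        if not (0.0 <= partner_total < 1.0 + 1e-9):
            raise ValueError("partner proportions must sum to < 1")

    @property
    def proportion(self) -> float:
        return 1.0 - sum(p for _, p in self.mixture_partners)

    @property
    def constituents(self) -> list[tuple[LipidSpecies, float]]:
        return [(self.species, self.proportion), *self.mixture_partners]


@dataclass(frozen=True)
class NoiseSpec:
    mz_jitter_ppm: float = 0.0  # m/z jitter std
    intensity_rel_noise: float = 0.0  # multiplicative intensity noise std
    baseline_level: float = 0.0  # decoy intensity scale
    decoy_peak_rate: float = 0.0  # expected decoy peaks per spectrum

    def __post_init__(self):
        for name in ("mz_jitter_ppm", "intensity_rel_noise", "baseline_level",
                     "decoy_peak_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DdaParams:
    cycle_time_s: float = 1.0  # one MS1 plus top_n MS2 per cycle
    top_n: int = 3
    min_precursor_intensity: float = 1e4
    exclusion_window_s: float = 10.0
    isolation_width: float = 1.3  # Da
    mz_range: tuple[float, float] = (100.0, 1200.0)


@dataclass
class _Planted:
    analyte: PlantedAnalyte
    precursor_mz: float
    fragments_mz: np.ndarray  # proportion-weighted mixture spectrum
    fragments_int: np.ndarray  # relative (max over constituents = per-spectrum)
    isotope_ratios: np.ndarray


def _mixture_spectrum(
    analyte: PlantedAnalyte, class_defs: dict[str, LipidClassDef]
) -> tuple[float, np.ndarray, np.ndarray]:
    """Proportion-weighted sum of constituent in silico spectra.

    Each constituent's spectrum is L1-normalised before weighting: a
    precursor's total fragment current is proportional to its abundance, so a
    constituent's share of the summed MS/MS signal equals its planted
    proportion (the quantity NNLS percent abundance estimates).
    """
    merged: dict[int, list[float]] = {}
    prec = None
    for species, prop in analyte.constituents:
        cdef = class_defs[species.class_abbrev]
        spec = in_silico_spectrum(species, analyte.adduct, cdef)
        prec = spec.precursor_mz if prec is None else prec
        total = sum(inten for _mz, inten, _label in spec.fragments)
        for mz, inten, _label in spec.fragments:
            key = round(mz * 1e4)
            merged.setdefault(key, [mz, 0.0])[1] += prop * inten / total
    items = sorted(merged.values())
    mzs = np.array([m for m, _ in items])
    ints = np.array([i for _, i in items])
    return float(prec), mzs, ints


def _prepare(
    analytes: list[PlantedAnalyte], class_defs: dict[str, LipidClassDef], n_isotopes: int
) -> list[_Planted]:
    out = []
    for analyte in analytes:
        prec, fmz, fint = _mixture_spectrum(analyte, class_defs)
        species = analyte.species
        formula = species.formula or species_formula(
            species, class_defs[species.class_abbrev]
        )
        add = get_adduct(analyte.adduct)
        ion_formula = formula_add(
            formula, {e: n for e, n in add.delta_formula.items() if n > 0}
        )
        iso = theoretical_isotope_pattern(ion_formula, n_isotopes)
        out.append(_Planted(analyte, prec, fmz, fint, iso.ratios))
    return out


def _jitter(rng: np.random.Generator, mz: np.ndarray, ppm: float) -> np.ndarray:
    if ppm <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, ppm * 1e-6, size=len(mz)))


def _noisy(rng: np.random.Generator, inten: np.ndarray, rel: float) -> np.ndarray:
    if rel <= 0:
        return inten
    return inten * np.clip(rng.normal(1.0, rel, size=len(inten)), 0.0, None)


def _decoys(
    rng: np.random.Generator, noise: NoiseSpec, mz_range: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    if noise.decoy_peak_rate <= 0 or noise.baseline_level <= 0:
        return np.array([]), np.array([])
    n = rng.poisson(noise.decoy_peak_rate)
    mz = rng.uniform(mz_range[0], mz_range[1], size=n)
    inten = rng.exponential(noise.baseline_level, size=n)
    return mz, inten


def simulate_run(
    analytes: list[PlantedAnalyte],
    noise: NoiseSpec | None = None,
    gradient_length: float = 10.0,
    dda: DdaParams | None = None,
    class_defs: dict[str, LipidClassDef] | None = None,
    seed: int = 0,
    polarity: str = "positive",
    n_isotopes: int = 3,
    exclude: list[tuple[float, float]] | None = None,
    exclude_rt_window_min: float = 0.5,
) -> tuple[Run, pd.DataFrame]:
    """Simulate one DDA LC-MS/MS injection.

    Returns the run plus a truth table (one row per planted constituent) with
    columns: name, class, adduct, precursor_mz, rt, proportion, ms2_covered,
    chimeric.  ``exclude`` is a list of (m/z, rt) pairs that may not trigger
    MS/MS within ±``exclude_rt_window_min`` of their rt (iterative
    exclusion); ``dda.exclusion_window_s`` is the within-run dynamic
    exclusion applied after a precursor is fragmented.
    """
    noise = noise or NoiseSpec()
    dda = dda or DdaParams()
    class_defs = class_defs or default_class_defs()
    rng = np.random.default_rng(seed)
    planted = _prepare(analytes, class_defs, n_isotopes)

    exclude = exclude or []
    dyn_exclusion: dict[int, float] = {}  # planted index -> excluded-until rt
    covered = [False] * len(planted)
    chimeric = [False] * len(planted)

    scans: list[Scan] = []
    cycle_min = dda.cycle_time_s / 60.0
    rt = 0.0
    scan_no = 0
    while rt < gradient_length:
        # --- MS1 scan: isotope envelopes of every eluting analyte + decoys
        mz_list, int_list = [], []
        eluting: list[tuple[int, float]] = []
        for i, p in enumerate(planted):
            a = p.analyte
            h = a.height * np.exp(-0.5 * ((rt - a.rt_apex) / a.peak_sigma) ** 2)
            if h < 1.0:
                continue
            eluting.append((i, h))
            for k, ratio in enumerate(p.isotope_ratios):
                mz_list.append(p.precursor_mz + k * ISOTOPE_MZ_SPACING)
                int_list.append(h * ratio)
        dmz, dint = _decoys(rng, noise, dda.mz_range)
        mz_arr = np.concatenate([np.array(mz_list), dmz])
        int_arr = np.concatenate([np.array(int_list), dint])
        mz_arr = _jitter(rng, mz_arr, noise.mz_jitter_ppm)
        int_arr = _noisy(rng, int_arr, noise.intensity_rel_noise)
        scans.append(
            Scan(str(scan_no), 1, rt, mz_arr, int_arr, polarity=polarity)
        )
        scan_no += 1

        # --- DDA: pick top-N eluting precursors not excluded
        selectable = []
        for i, h in eluting:
            p = planted[i]
            if h < dda.min_precursor_intensity:
                continue
            if dyn_exclusion.get(i, -1.0) >= rt:
                continue
            if any(
                abs(p.precursor_mz - emz) <= dda.isolation_width / 2
                and abs(ert - rt) <= exclude_rt_window_min
                for emz, ert in exclude
            ):
                continue
            selectable.append((h, i))
        selectable.sort(key=lambda t: (-t[0], t[1]))
        for slot, (h, i) in enumerate(selectable[: dda.top_n]):
            p = planted[i]
            ms2_rt = rt + cycle_min * (slot + 1) / (dda.top_n + 1)
            fmz = p.fragments_mz.copy()
            fint = p.fragments_int * h
            # co-isolation: any other eluting analyte within the isolation window
            for j, hj in eluting:
                if j == i:
                    continue
                pj = planted[j]
                if abs(pj.precursor_mz - p.precursor_mz) <= dda.isolation_width / 2:
                    fmz = np.concatenate([fmz, pj.fragments_mz])
                    fint = np.concatenate([fint, pj.fragments_int * hj])
                    chimeric[i] = chimeric[j] = True
            dmz, dint = _decoys(rng, noise, (50.0, p.precursor_mz))
            fmz = np.concatenate([fmz, dmz])
            fint = np.concatenate([fint, dint])
            fmz = _jitter(rng, fmz, noise.mz_jitter_ppm)
            fint = _noisy(rng, fint, noise.intensity_rel_noise)
            scans.append(
                Scan(
                    str(scan_no), 2, ms2_rt, fmz, fint,
                    polarity=polarity,
                    precursor_mz=p.precursor_mz,
                    isolation_width=dda.isolation_width,
                )
            )
            scan_no += 1
            covered[i] = True
            dyn_exclusion[i] = ms2_rt + dda.exclusion_window_s / 60.0
        rt += cycle_min

    rows = []
    for i, p in enumerate(planted):
        for species, prop in p.analyte.constituents:
            rows.append(
                {
                    "name": species.name_constituent,
                    "class": species.class_abbrev,
                    "adduct": p.analyte.adduct,
                    "precursor_mz": p.precursor_mz,
                    "rt": p.analyte.rt_apex,
                    "proportion": prop,
                    "ms2_covered": covered[i],
                    "chimeric": chimeric[i],
                }
            )
    return Run(scans=scans, polarity=polarity), pd.DataFrame(rows)


def simulate_iterative_exclusion(
    analytes: list[PlantedAnalyte],
    noise: NoiseSpec | None = None,
    n_injections: int = 3,
    gradient_length: float = 10.0,
    dda: DdaParams | None = None,
    class_defs: dict[str, LipidClassDef] | None = None,
    seed: int = 0,
    polarity: str = "positive",
    rt_exclusion_window_min: float = 0.5,
) -> list[tuple[Run, pd.DataFrame]]:
    """Repeated injections, each excluding precursors fragmented before.

    Injection k places every (m/z, rt) fragmented in injections 1..k-1 on the
    exclusion list, so the DDA top-N slots fall to progressively
    lower-abundance precursors — MS/MS coverage grows across injections.
    """
    dda = dda or DdaParams()
    results = []
    exclude: list[tuple[float, float]] = []
    for k in range(n_injections):
        run, truth = simulate_run(
            analytes,
            noise=noise,
            gradient_length=gradient_length,
            dda=dda,
            class_defs=class_defs,
            seed=seed + k,
            polarity=polarity,
            exclude=list(exclude),
            exclude_rt_window_min=rt_exclusion_window_min,
        )
        results.append((run, truth))
        for scan in run.ms2_scans():
            exclude.append((scan.precursor_mz, scan.rt))
    return results
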