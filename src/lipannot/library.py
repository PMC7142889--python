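"""In silico lipid libraries.

Lipid species are enumerated from per-class combinatorial templates (backbone
+ fatty-acyl chain multisets); each species/adduct pair gets a predicted
MS/MS spectrum from the class's fragment rules, a precursor m/z, and a
theoretical isotope pattern on demand.  A validator checks every predicted
fragment for elemental plausibility (a subformula of the precursor
composition must explain its m/z) and for internal consistency of
fragmentation across constituents of a class.
"""

from __future__ import annotations

import bisect
import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml

from .chem import (
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    Formula,
    FormulaError,
    formula_add,
    get_adduct,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
    precursor_mz,
)
from .nomenclature import Chain, LipidSpecies

_H2O = {"H": 2, "O": 1}


@dataclass(frozen=True)
class FragmentRule:
    """A head-group fragment: fixed ion composition or fixed neutral loss."""

    label: str
    polarity: str  # "positive" | "negative"
    kind: str  # "ion" | "nl"
    formula: Formula
    intensity: float
    sn: str | None = None  # e.g. "sn2" for position-diagnostic fragments


@dataclass(frozen=True)
class AcylRule:
    """A chain-dependent fragment rule, applied once per fatty-acyl chain."""

    label: str
    polarity: str
    kind: str  # "acyl_anion" | "nl_fa" | "nl_ketene"
    intensity: float


@dataclass(frozen=True)
class LipidClassDef:
    class_abbrev: str
    backbone_formula: Formula
    n_chains: int
    allowed_adducts: dict[str, tuple[str, ...]]  # polarity -> adduct names
    head_group_fragments: tuple[FragmentRule, ...] = ()
    acyl_fragment_rules: tuple[AcylRule, ...] = ()

    def __post_init__(self):
        if self.n_chains < 0:
            raise ValueError("n_chains must be >= 0")
        for rule in (*self.head_group_fragments, *self.acyl_fragment_rules):
            if rule.polarity not in ("positive", "negative"):
                raise ValueError(f"bad polarity {rule.polarity!r} in {rule.label!r}")
            if not (0.0 < rule.intensity <= 1.0):
                raise ValueError(f"intensity outside (0, 1] in {rule.label!r}")

    def adducts_for(self, polarity: str) -> tuple[str, ...]:
        return self.allowed_adducts.get(polarity, ())


@dataclass(frozen=True)
class InSilicoSpectrum:
    """Predicted fragments for one species/adduct: (mz, rel_intensity, label)."""

    species: LipidSpecies
    adduct: str
    precursor_mz: float
    fragments: tuple[tuple[float, float, str], ...]

    @property
    def mzs(self) -> list[float]:
        return [f[0] for f in self.fragments]

    @property
    def labels(self) -> set[str]:
        return {f[2] for f in self.fragments}


def load_class_defs(path: str | Path | None = None) -> dict[str, LipidClassDef]:
    """Load class templates from a YAML file (default: packaged classdefs)."""
    if path is None:
        text = (
            resources.files("lipannot").joinpath("data/classdefs.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out: dict[str, LipidClassDef] = {}
    for abbrev, spec in raw["classes"].items():
        head = tuple(
            FragmentRule(
                label=r["label"],
                polarity=r["polarity"],
                kind=r["kind"],
                formula=parse_formula(r["formula"]),
                intensity=float(r["intensity"]),
                sn=r.get("sn"),
            )
            for r in spec.get("head_fragments", []) or []
        )
        acyl = tuple(
            AcylRule(r["label"], r["polarity"], r["kind"], float(r["intensity"]))
            for r in spec.get("acyl_rules", []) or []
        )
        out[abbrev] = LipidClassDef(
            class_abbrev=abbrev,
            backbone_formula=parse_formula(spec["backbone"]),
            n_chains=int(spec["n_chains"]),
            allowed_adducts={
                pol: tuple(names) for pol, names in (spec.get("adducts") or {}).items()
            },
            head_group_fragments=head,
            acyl_fragment_rules=acyl,
        )
    return out


_DEFAULT_DEFS: dict[str, LipidClassDef] | None = None


def default_class_defs() -> dict[str, LipidClassDef]:
    global _DEFAULT_DEFS
    if _DEFAULT_DEFS is None:
        _DEFAULT_DEFS = load_class_defs()
    return _DEFAULT_DEFS


def acyl_contribution(chain: Chain) -> Formula:
    """Atoms an esterified/amidated chain adds to the backbone.

    A fatty acid CnH(2n-2db)O2 loses H2O on ester/amide formation, leaving
    CnH(2n-2-2db)O.  A 0:0 chain is a free hydroxyl and contributes nothing.
    """
    c, d = chain
    if c == 0:
        return {}
    h = 2 * c - 2 - 2 * d
    if h < 0:
        raise FormulaError(f"chain {c}:{d} is over-unsaturated")
    return {"C": c, "H": h, "O": 1}


def fatty_acid_formula(chain: Chain) -> Formula:
    c, d = chain
    return {"C": c, "H": 2 * c - 2 * d, "O": 2}


def species_formula(species: LipidSpecies, class_def: LipidClassDef) -> Formula:
    """Elemental composition of a constituent-level species."""
    if not species.chains:
        raise ValueError(f"{species.name_sum}: chains must be populated")
    formula = dict(class_def.backbone_formula)
    for chain in species.chains:
        formula = formula_add(formula, acyl_contribution(chain))
    if any(n < 0 for n in formula.values()):
        raise FormulaError(f"invalid class_def for {species.name_constituent}")
    return formula


def with_formula(species: LipidSpecies, class_def: LipidClassDef) -> LipidSpecies:
    return LipidSpecies(
        species.class_abbrev,
        species.chains,
        species.sn_known,
        species.total_carbons,
        species.total_double_bonds,
        species_formula(species, class_def),
    )


def chain_space(
    carbons: Iterable[int], double_bonds: Iterable[int]
) -> list[Chain]:
    """Cartesian chain grid, dropping over-unsaturated combinations."""
    return [
        (c, d)
        for c in sorted(set(carbons))
        for d in sorted(set(double_bonds))
        if 2 * c - 2 - 2 * d >= 0
    ]


def enumerate_species(
    class_def: LipidClassDef, chains: Sequence[Chain]
) -> list[LipidSpecies]:
    """All species of a class over unordered chain multisets from ``chains``.

    Output is duplicate-free and lexicographically ordered by chain tuple,
    with formulas populated.
    """
    pool = sorted(set(chains))
    out = []
    for combo in itertools.combinations_with_replacement(pool, class_def.n_chains):
        sp = LipidSpecies(class_def.class_abbrev, tuple(combo))
        out.append(with_formula(sp, class_def))
    return out


def in_silico_spectrum(
    species: LipidSpecies, adduct: str, class_def: LipidClassDef
) -> InSilicoSpectrum:
    """Predicted MS/MS spectrum for one constituent-level species and adduct.

    Fragments are the class head-group rules plus one product per chain per
    acyl rule; coinciding m/z values merge by intensity sum and the result is
    renormalised so the base fragment is 1.0.  Deterministic for identical
    inputs.
    """
    if not species.chains:
        raise ValueError(
            f"{species.name_sum}: sum composition has no constituent spectrum"
        )
    add = get_adduct(adduct)
    polarity = add.polarity
    if adduct not in class_def.adducts_for(polarity):
        raise ValueError(
            f"adduct {adduct} not allowed for class {class_def.class_abbrev}"
        )
    formula = species.formula or species_formula(species, class_def)
    prec = precursor_mz(formula, adduct)

    raw: list[tuple[float, float, str]] = []
    for rule in class_def.head_group_fragments:
        if rule.polarity != polarity:
            continue
        if rule.kind == "ion":
            mz = ion_mz(rule.formula, polarity)
        elif rule.kind == "nl":
            mz = prec - monoisotopic_mass(rule.formula)
        else:
            raise ValueError(f"unknown head fragment kind {rule.kind!r}")
        raw.append((mz, rule.intensity, rule.label))
    for rule in class_def.acyl_fragment_rules:
        if rule.polarity != polarity:
            continue
        for chain in species.chains:
            if chain[0] == 0:
                continue
            fa = monoisotopic_mass(fatty_acid_formula(chain))
            if rule.kind == "acyl_anion":
                mz = fa - PROTON_MASS
            elif rule.kind == "nl_fa":
                mz = prec - fa
            elif rule.kind == "nl_ketene":
                mz = prec - (fa - monoisotopic_mass(_H2O))
            else:
                raise ValueError(f"unknown acyl rule kind {rule.kind!r}")
            label = f"{rule.label} ({chain[0]}:{chain[1]})"
            raw.append((mz, rule.intensity, label))

    # merge coinciding fragments (identical chains fire the same rule twice)
    merged: dict[tuple[int, str], list] = {}
    for mz, inten, label in raw:
        key = (round(mz * 1e4), label)
        if key in merged:
            merged[key][1] += inten
        else:
            merged[key] = [mz, inten, label]
    frags = sorted(v for v in merged.values() if v[0] < prec + 0.5)
    if frags:
        top = max(f[1] for f in frags)
        frags = [(mz, inten / top, label) for mz, inten, label in frags]
    return InSilicoSpectrum(species, adduct, prec, tuple(frags))


# ---------------------------------------------------------------------------
# library validation


@dataclass(frozen=True)
class ValidationFlag:
    spectrum_name: str
    adduct: str
    fragment_label: str
    fragment_mz: float
    reason: str  # "no subformula" | "inconsistent across constituents"


def _subformula_exists(
    target_mass: float, limits: list[tuple[str, int]], tol: float
) -> bool:
    """True if some subformula within the per-element limits has mass within
    ``tol`` of ``target_mass``.  DFS over elements (heaviest first) with
    mass-bound pruning."""

    def dfs(idx: int, remaining: float) -> bool:
        if idx == len(limits):
            return abs(remaining) <= tol
        elem, max_n = limits[idx]
        m = MONOISOTOPIC_MASS[elem]
        # max mass the remaining elements (idx..end) can still contribute
        hi = min(max_n, int((remaining + tol) // m)) if m > 0 else max_n
        rest_max = sum(
            MONOISOTOPIC_MASS[e] * n for e, n in limits[idx + 1 :]
        )
        for n in range(hi, -1, -1):
            left = remaining - n * m
            if left < -tol:
                continue
            if left - tol > rest_max:
                break  # even taking everything later cannot reach the target
            if dfs(idx + 1, left):
                return True
        return False

    return dfs(0, target_mass)


def validate_library(
    spectra: Sequence[InSilicoSpectrum],
    class_defs: dict[str, LipidClassDef] | None = None,
    mass_tol: float = 0.005,
) -> list[ValidationFlag]:
    """Flag chemically impossible or internally inconsistent fragments.

    A fragment is flagged "no subformula" when no elemental subformula of the
    precursor composition (molecule plus adduct atoms) explains its m/z within
    ``mass_tol`` Da, and "inconsistent across constituents" when a fragment
    label present for one constituent of a class/adduct group is missing for
    another.  The returned report is empty for a library generated by the
    package's own rules.
    """
    if class_defs is None:
        class_defs = default_class_defs()
    flags: list[ValidationFlag] = []

    for spec in spectra:
        cdef = class_defs.get(spec.species.class_abbrev)
        formula = spec.species.formula
        if formula is None and cdef is not None and spec.species.chains:
            formula = species_formula(spec.species, cdef)
        if formula is None:
            continue
        add = get_adduct(spec.adduct)
        ion_formula = formula_add(formula, {e: max(n, 0) for e, n in add.delta_formula.items()})
        limits = sorted(
            ion_formula.items(), key=lambda kv: -MONOISOTOPIC_MASS[kv[0]]
        )
        electron = -0.000548579909 if add.polarity == "positive" else 0.000548579909
        for mz, _inten, label in spec.fragments:
            target = mz - electron  # neutral-atom mass the subformula must hit
            if mz > spec.precursor_mz + 0.5 or not _subformula_exists(
                target, limits, mass_tol
            ):
                flags.append(
                    ValidationFlag(
                        spec.species.name_constituent, spec.adduct, label, mz,
                        "no subformula",
                    )
                )

    # internal consistency: same class + adduct must share rule labels
    groups: dict[tuple[str, str], list[InSilicoSpectrum]] = {}
    for spec in spectra:
        groups.setdefault((spec.species.class_abbrev, spec.adduct), []).append(spec)
    for (_cls, adduct), members in groups.items():
        # compare base labels (chain annotations stripped) across constituents
        def base_labels(s: InSilicoSpectrum) -> set[str]:
            return {lab.split(" (")[0] for lab in s.labels}

        union: set[str] = set()
        for s in members:
            union |= base_labels(s)
        for s in members:
            for missing in sorted(union - base_labels(s)):
                flags.append(
                    ValidationFlag(
                        s.species.name_constituent, adduct, missing, float("nan"),
                        "inconsistent across constituents",
                    )
                )
    return flags


# ---------------------------------------------------------------------------
# library container


DEFAULT_CHAINS: list[Chain] = chain_space(
    carbons=range(12, 23, 2), double_bonds=range(0, 7)
)


class SpectralLibrary:
    """In silico spectra indexed by precursor m/z for fast window lookup."""

    def __init__(self, spectra: Iterable[InSilicoSpectrum]):
        self.spectra = sorted(spectra, key=lambda s: s.precursor_mz)
        self._mzs = [s.precursor_mz for s in self.spectra]

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[InSilicoSpectrum]:
        return iter(self.spectra)

    def lookup(self, mz: float, tol_ppm: float = 20.0) -> list[InSilicoSpectrum]:
        """All spectra whose precursor lies within ±tol_ppm of ``mz``."""
        tol = mz * tol_ppm * 1e-6
        lo = bisect.bisect_left(self._mzs, mz - tol)
        hi = bisect.bisect_right(self._mzs, mz + tol)
        return self.spectra[lo:hi]

    @classmethod
    def build(
        cls,
        class_defs: dict[str, LipidClassDef] | None = None,
        chains: Sequence[Chain] | None = None,
        polarity: str | None = None,
        classes: Sequence[str] | None = None,
    ) -> "SpectralLibrary":
        """Enumerate species x adducts for the given classes and chain space."""
        if class_defs is None:
            class_defs = default_class_defs()
        if chains is None:
            chains = DEFAULT_CHAINS
        spectra = []
        for abbrev, cdef in class_defs.items():
            if classes is not None and abbrev not in classes:
                continue
            for sp in enumerate_species(cdef, chains):
                for pol, adducts in cdef.allowed_adducts.items():
                    if polarity is not None and pol != polarity:
                        continue
                    for adduct in adducts:
                        spectra.append(in_silico_spectrum(sp, adduct, cdef))
        return cls(spectra)

    def export_tsv(self, path: str | Path) -> None:
        """Tab-separated export: name, adduct, precursor m/z, fragment pairs."""
        with open(path, "w") as fh:
            fh.write("name\tadduct\tprecursor_mz\tfragments\n")
            for s in self.spectra:
                frags = ";".join(f"{mz:.4f}:{inten:.3f}" for mz, inten, _ in s.fragments)
                fh.write(
                    f"{s.species.name_constituent}\t{s.adduct}\t"
                    f"{s.precursor_mz:.5f}\t{frags}\n"
                )
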