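"""Lipid shorthand nomenclature: parsing and naming.

Supports the common shorthand levels:

* sum composition      — ``PC(34:1)``: class, total acyl carbons : double bonds
* fatty acyl, sn-unknown — ``PC(16:0_18:1)``: individual chains, ``_`` separator
* fatty acyl, sn-known   — ``PC(16:0/18:1)``: ``/`` separator, positions resolved

Sphingolipid hydroxyl prefixes (``d``/``t`` as in ``SM(d18:1/16:0)``) are
accepted and stripped; the di-hydroxy sphingoid convention is baked into the
SM/Cer class templates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .chem import Formula

Chain = tuple[int, int]  # (carbons, double_bonds)


class LipidNameError(ValueError):
    """Malformed lipid shorthand or unknown class abbreviation."""


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid at sum-composition or fatty-acyl-constituent level.

    ``chains`` is empty when only the sum composition is known.  ``sn_known``
    records whether chain order carries sn-position information (the ``/``
    separator) — chains are otherwise an unordered multiset, stored sorted.
    """

    class_abbrev: str
    chains: tuple[Chain, ...] = ()
    sn_known: bool = False
    total_carbons: int = 0
    total_double_bonds: int = 0
    formula: Formula | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.chains:
            tc = sum(c for c, _ in self.chains)
            td = sum(d for _, d in self.chains)
            if (tc, td) != (self.total_carbons, self.total_double_bonds):
                object.__setattr__(self, "total_carbons", tc)
                object.__setattr__(self, "total_double_bonds", td)
            if not self.sn_known and list(self.chains) != sorted(self.chains):
                object.__setattr__(self, "chains", tuple(sorted(self.chains)))

    @property
    def name_sum(self) -> str:
        return f"{self.class_abbrev}({self.total_carbons}:{self.total_double_bonds})"

    @property
    def name_constituent(self) -> str:
        if not self.chains:
            return self.name_sum
        sep = "/" if self.sn_known else "_"
        body = sep.join(f"{c}:{d}" for c, d in self.chains)
        return f"{self.class_abbrev}({body})"

    @property
    def sum_key(self) -> tuple[str, int, int]:
        """Grouping key: same class + same totals = isomeric sum composition."""
        return (self.class_abbrev, self.total_carbons, self.total_double_bonds)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name_constituent


_NAME_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)\(([^()]*)\)$")
_CHAIN_RE = re.compile(r"^[dt]?(\d+):(\d+)$")


def parse_chain(token: str) -> Chain:
    m = _CHAIN_RE.match(token)
    if not m:
        raise LipidNameError(f"malformed chain token {token!r}")
    return (int(m.group(1)), int(m.group(2)))


def parse_lipid_name(name: str, known_classes: dict | None = None) -> LipidSpecies:
    """Parse shorthand like ``TG(50:2)``, ``PC(16:0_18:1)`` or ``PC(16:0/18:1)``.

    ``known_classes`` maps class abbreviation to its :class:`LipidClassDef`
    (defaults to the packaged classes).  A single ``c:d`` token is a sum
    composition, except for single-chain classes where the two levels
    coincide and chains are populated.
    """
    if known_classes is None:
        from .library import default_class_defs

        known_classes = default_class_defs()
    m = _NAME_RE.match(name.strip())
    if not m:
        raise LipidNameError(f"malformed lipid name {name!r}")
    cls, body = m.group(1), m.group(2)
    if cls not in known_classes:
        raise LipidNameError(f"unknown lipid class {cls!r} in {name!r}")
    class_def = known_classes[cls]

    if "/" in body and "_" in body:
        raise LipidNameError(f"mixed '/' and '_' separators in {name!r}")
    sn_known = "/" in body
    tokens = [t for t in re.split(r"[/_]", body) if t != ""]
    if not tokens:
        raise LipidNameError(f"empty composition in {name!r}")
    chains = tuple(parse_chain(t) for t in tokens)

    if len(tokens) == 1 and class_def.n_chains != 1:
        # a lone c:d on a multi-chain class is a sum composition
        c, d = chains[0]
        return LipidSpecies(cls, (), False, c, d)
    if len(chains) != class_def.n_chains:
        raise LipidNameError(
            f"{cls} has {class_def.n_chains} chain positions, "
            f"got {len(chains)} in {name!r}"
        )
    return LipidSpecies(cls, chains, sn_known)
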