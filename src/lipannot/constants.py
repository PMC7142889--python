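"""Pinned physical constants: monoisotopic atomic masses and isotope abundances.

Values are shipped with the package (rather than taken from a third-party
library at run time) so that every m/z and isotope-ratio computation is
bit-reproducible across environments.  Masses in Da (CODATA/AME-derived,
rounded to the precision printed below); abundances are natural terrestrial
isotopic compositions.
"""

from __future__ import annotations

# Monoisotopic (principal-isotope) atomic masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "F": 18.99840322,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = 1.00727646688

# Per-element isotope abundance vectors indexed by nominal mass shift
# (A+0, A+1, A+2, ...) relative to the principal isotope.  Unit-mass binning
# is appropriate for Q-TOF isotope envelopes, which are compared per A+k peak.
ISOTOPE_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Na": (1.0,),
    "K": (0.932581, 0.000117, 0.067302),
    "F": (1.0,),
    "Cl": (0.7576, 0.0, 0.2424),
}

# Average spacing of one neutron addition in lipid-range ions, Da.  Used to
# locate A+k isotopologue peaks in observed MS1 spectra.
ISOTOPE_MZ_SPACING = 1.0033548
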