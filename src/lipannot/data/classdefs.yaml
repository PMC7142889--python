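# Built-in lipid class templates.
#
# Each class gives a backbone elemental composition, the number of fatty-acyl
# chain positions, allowed adducts per polarity, head-group fragment rules and
# chain-dependent (acyl) fragment rules.  A species formula is
# backbone + sum over chains of CnH(2n-2-2db)O (the esterified/amidated acyl
# contribution); a "0:0" chain contributes nothing (free hydroxyl).
#
# Fragment rule kinds:
#   ion     - fixed-composition fragment ion; m/z from its formula
#   nl      - neutral loss; m/z = precursor m/z - loss mass
# Acyl rule kinds (one product per chain):
#   acyl_anion - carboxylate anion [FA-H]- of the chain's fatty acid
#   nl_fa      - neutral loss of the chain's fatty acid RCOOH
#   nl_ketene  - neutral loss of the chain's ketene (RCOOH - H2O)
#
# Predicted relative intensities are template defaults in (0, 1], user
# overridable; they are declared per rule, not modelled against chain length
# or unsaturation.  SM and Cer templates assume the di-hydroxy (d) sphingoid
# convention, with the sphingoid base occupying the first chain position.
classes:
  PC:
    backbone: C8H20NO6P
    n_chains: 2
    adducts:
      positive: ["[M+H]+", "[M+Na]+"]
      negative: ["[M+CH3COO]-"]
    head_fragments:
      - {label: "phosphocholine head group", polarity: positive, kind: ion, formula: C5H15NO4P, intensity: 1.0}
      - {label: "demethylated phosphocholine", polarity: negative, kind: ion, formula: C4H11NO4P, intensity: 0.2}
    acyl_rules:
      - {label: "fatty acid neutral loss", polarity: positive, kind: nl_fa, intensity: 0.3}
      - {label: "ketene neutral loss", polarity: positive, kind: nl_ketene, intensity: 0.2}
      - {label: "acyl anion", polarity: negative, kind: acyl_anion, intensity: 1.0}
  LPC:
    backbone: C8H20NO6P
    n_chains: 1
    adducts:
      positive: ["[M+H]+", "[M+Na]+"]
      negative: ["[M+CH3COO]-"]
    head_fragments:
      - {label: "phosphocholine head group", polarity: positive, kind: ion, formula: C5H15NO4P, intensity: 1.0}
      - {label: "sn2 choline diagnostic", polarity: positive, kind: ion, formula: C5H14NO, intensity: 0.3, sn: sn2}
      - {label: "demethylated phosphocholine", polarity: negative, kind: ion, formula: C4H11NO4P, intensity: 0.2}
    acyl_rules:
      - {label: "fatty acid neutral loss", polarity: positive, kind: nl_fa, intensity: 0.2}
      - {label: "acyl anion", polarity: negative, kind: acyl_anion, intensity: 1.0}
  PE:
    backbone: C5H14NO6P
    n_chains: 2
    adducts:
      positive: ["[M+H]+"]
      negative: ["[M-H]-"]
    head_fragments:
      - {label: "phosphoethanolamine neutral loss", polarity: positive, kind: nl, formula: C2H8NO4P, intensity: 1.0}
    acyl_rules:
      - {label: "acyl anion", polarity: negative, kind: acyl_anion, intensity: 1.0}
      - {label: "fatty acid neutral loss", polarity: positive, kind: nl_fa, intensity: 0.3}
  LPE:
    backbone: C5H14NO6P
    n_chains: 1
    adducts:
      positive: ["[M+H]+"]
      negative: ["[M-H]-"]
    head_fragments:
      - {label: "phosphoethanolamine neutral loss", polarity: positive, kind: nl, formula: C2H8NO4P, intensity: 1.0}
    acyl_rules:
      - {label: "acyl anion", polarity: negative, kind: acyl_anion, intensity: 1.0}
  PS:
    backbone: C6H14NO8P
    n_chains: 2
    adducts:
      positive: ["[M+H]+"]
      negative: ["[M-H]-"]
    head_fragments:
      - {label: "serine neutral loss", polarity: negative, kind: nl, formula: C3H5NO2, intensity: 1.0}
      - {label: "phosphoserine neutral loss", polarity: positive, kind: nl, formula: C3H8NO6P, intensity: 1.0}
    acyl_rules:
      - {label: "acyl anion", polarity: negative, kind: acyl_anion, intensity: 0.8}
      - {label: "fatty acid neutral loss", polarity: positive, kind: nl_fa, intensity: 0.3}
  PG:
    backbone: C6H15O8P
    n_chains: 2
    adducts:
      positive: ["[M+NH4]+"]
      negative: ["[M-H]-"]
    head_fragments:
      - {label: "glycerophosphate anion", polarity: negative, kind: ion, formula: C3H8O6P, intensity: 0.3}
    acyl_rules:
      - {label: "acyl anion", polarity: negative, kind: acyl_anion, intensity: 1.0}
      - {label: "fatty acid neutral loss", polarity: positive, kind: nl_fa, intensity: 0.5}
  PI:
    backbone: C9H19O11P
    n_chains: 2
    adducts:
      positive: ["[M+NH4]+"]
      negative: ["[M-H]-"]
    head_fragments:
      - {label: "inositol phosphate anion", polarity: negative, kind: ion, formula: C6H10O8P, intensity: 0.6}
    acyl_rules:
      - {label: "acyl anion", polarity: negative, kind: acyl_anion, intensity: 1.0}
      - {label: "fatty acid neutral loss", polarity: positive, kind: nl_fa, intensity: 0.5}
  PA:
    backbone: C3H9O6P
    n_chains: 2
    adducts:
      negative: ["[M-H]-"]
    head_fragments:
      - {label: "glycerophosphate - water anion", polarity: negative, kind: ion, formula: C3H6O5P, intensity: 0.3}
    acyl_rules:
      - {label: "acyl anion", polarity: negative, kind: acyl_anion, intensity: 1.0}
  TG:
    backbone: C3H8O3
    n_chains: 3
    adducts:
      positive: ["[M+H]+", "[M+NH4]+", "[M+Na]+"]
    acyl_rules:
      - {label: "fatty acid neutral loss (DAG fragment)", polarity: positive, kind: nl_fa, intensity: 1.0}
  DG:
    backbone: C3H8O3
    n_chains: 2
    adducts:
      positive: ["[M+H]+", "[M+NH4]+", "[M+Na]+"]
    head_fragments:
      - {label: "water neutral loss", polarity: positive, kind: nl, formula: H2O, intensity: 0.4}
    acyl_rules:
      - {label: "fatty acid neutral loss (MAG fragment)", polarity: positive, kind: nl_fa, intensity: 1.0}
  MG:
    backbone: C3H8O3
    n_chains: 1
    adducts:
      positive: ["[M+H]+", "[M+NH4]+"]
    head_fragments:
      - {label: "water neutral loss", polarity: positive, kind: nl, formula: H2O, intensity: 0.5}
    acyl_rules:
      - {label: "fatty acid neutral loss", polarity: positive, kind: nl_fa, intensity: 0.5}
  SM:
    backbone: C5H17N2O4P
    n_chains: 2
    adducts:
      positive: ["[M+H]+", "[M+Na]+"]
      negative: ["[M+CH3COO]-"]
    head_fragments:
      - {label: "phosphocholine head group", polarity: positive, kind: ion, formula: C5H15NO4P, intensity: 1.0}
      - {label: "demethylated phosphocholine", polarity: negative, kind: ion, formula: C4H11NO4P, intensity: 0.2}
  CE:
    backbone: C27H46O
    n_chains: 1
    adducts:
      positive: ["[M+NH4]+", "[M+Na]+"]
    head_fragments:
      - {label: "cholestadienyl cation", polarity: positive, kind: ion, formula: C27H45, intensity: 1.0}
    acyl_rules: []
  Cer:
    backbone: H5NO
    n_chains: 2
    adducts:
      positive: ["[M+H]+"]
      negative: ["[M-H]-"]
    head_fragments:
      - {label: "water neutral loss", polarity: positive, kind: nl, formula: H2O, intensity: 1.0}
    acyl_rules:
      - {label: "ketene neutral loss", polarity: positive, kind: nl_ketene, intensity: 0.3}
  FA:
    backbone: H2O
    n_chains: 1
    adducts:
      negative: ["[M-H]-"]
    acyl_rules:
      - {label: "acyl anion", polarity: negative, kind: acyl_anion, intensity: 1.0}
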