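# lipannot

Probability-based lipid annotation for LC-HRMS/MS data-dependent acquisition
(DDA) lipidomics.

Untargeted lipidomics produces thousands of MS/MS spectra per run, and many
of them are *mixed*: isomeric lipids of one sum composition (same class, same
total acyl carbons and double bonds, e.g. PC(34:1)) co-elute and are
co-isolated, so one fragmentation spectrum carries evidence for several
fatty-acyl constituents at once. Annotating such spectra with simple
tolerance windows or ad hoc weighted scores over-annotates: it reports chain
structure the spectrum cannot actually support. `lipannot` addresses this
for analysts who want (a) calibrated, interpretable scores instead of
arbitrary weights and (b) annotations whose structural precision matches the
spectral evidence.

## Method

For every MS1 chromatographic feature with associated MS/MS, three
independent evidence channels are scored as probabilities under normal error
models and combined multiplicatively (scale 0–100):

- **mass**: with Δppm = 10⁶·(m/z_obs − m/z_theo)/m/z_theo,
  p_mass = 2·(1 − Φ(|Δppm|/σ_ppm));
- **isotope fidelity**: for the observed A+k/A intensity ratios versus the
  ratios predicted from the candidate's elemental composition,
  z_k = (r_obs − r_theo)/(σ_iso·r_theo) and p_iso is the geometric mean of
  the two-sided tails over k = 1..K;
- **MS/MS**: candidate in silico spectra for the feature's sum composition
  are fit to the composite experimental spectrum by non-negative least
  squares, ŵ = argmin_{w≥0} ‖Aw − y‖₂; with residual fraction
  r = Σ|y − Aŵ|/Σy, p_msms = 2·(1 − Φ(r/σ_frag)).

Candidates from different lipid classes that fall in the same precursor
window (e.g. a PC versus a PE one CH₂ apart) are ranked by posterior
probability under a uniform prior — the candidate whose combined probability
product is highest wins. Within the winning sum composition, the NNLS
weights give each constituent's **percent abundance**
(100·ŵᵢ‖aᵢ‖₁ / Σⱼŵⱼ‖aⱼ‖₁, its share of the explained fragment signal). The
feature is annotated at fatty-acyl level (e.g. `PC(16:0_18:1)`) only when
the top constituent's percent is at least a dominance ratio (default 2×)
above the runner-up; otherwise the sum-composition name (`PC(34:1)`) is
used. For lysophosphatidylcholines in positive mode, the m/z 104.107 choline
fragment — specific to an acyl chain in the sn2 position — upgrades the name
to sn-resolved form (`LPC(0:0/18:1)`).

In silico libraries are generated combinatorially per lipid class (backbone
composition + fatty-acyl chain multisets + per-class fragment rules) and can
be validated: every predicted fragment must be explainable by an elemental
subformula of its precursor composition within 5 mDa, and fragment types
must be internally consistent across the constituents of a class.

A seeded synthetic-data generator produces complete ground-truth DDA runs
(Gaussian elution, theoretical isotope envelopes, top-N MS/MS scheduling
with dynamic exclusion, planted isomer mixtures, decoy noise) as standard
mzML plus a truth table, including multi-injection iterative-exclusion
series.

## Worked example

Two co-eluting triglyceride isomers, both 50 carbons and 2 double bonds,
planted at a 70/30 signal ratio under a single chromatographic peak:

```python
from lipannot import parse_lipid_name
from lipannot.library import SpectralLibrary, default_class_defs
from lipannot.synthetic import PlantedAnalyte, NoiseSpec, simulate_run
from lipannot.deconvolution import annotate_run

class_defs = default_class_defs()
analytes = [
    PlantedAnalyte(
        parse_lipid_name("TG(16:0_16:0_18:2)"), "[M+NH4]+",
        rt_apex=7.0, height=1e6,
        mixture_partners=((parse_lipid_name("TG(16:0_16:1_18:1)"), 0.3),),
    ),
]
run, truth = simulate_run(analytes, NoiseSpec(), gradient_length=9.0, seed=1)

library = SpectralLibrary.build(class_defs, polarity="positive", classes=["TG"])
results, stats = annotate_run(run, library, class_defs)

for r in results:
    print(f"{r.name}  level={r.structure_level}  adduct={r.adduct}")
    print(f"  p_mass={r.scores.p_mass:.3f}  p_isotope={r.scores.p_isotope:.3f}  "
          f"p_msms={r.scores.p_msms:.3f}  combined={r.scores.combined:.1f}")
    for sp, pct in zip(r.mixture.candidates, r.mixture.percent_abundances):
        if pct > 1:
            print(f"  {sp.name_constituent}: {pct:.1f}%")
```

prints

```
TG(16:0_16:0_18:2)  level=fatty_acyl  adduct=[M+NH4]+
  p_mass=1.000  p_isotope=1.000  p_msms=1.000  combined=100.0
  TG(16:0_16:0_18:2): 70.0%
  TG(16:0_16:1_18:1): 30.0%
```

The mixed MS/MS spectrum is deconvoluted back to the planted 70/30 split;
because the top constituent is more than twice the runner-up, the feature is
annotated by fatty-acyl constituents rather than as the sum composition
TG(50:2). All three probabilities are 1.0 here because the run is
noise-free.

## Command line

```bash
lipannot simulate analytes.yaml --out run.mzML --seed 1     # mzML + truth CSV
lipannot simulate-ie analytes.yaml --out-prefix ie --n-injections 3
lipannot annotate run.mzML --out-prefix results             # CSVs + target list
lipannot validate-library --classes PC,PE
lipannot export-targets results_annotations.csv targets.tsv
```

`annotate` writes a full annotation table, a per-feature constituent
percent-abundance report, and a three-column target list (name, m/z, rt)
usable for targeted peak picking in downstream software. Error-model sigmas,
filter thresholds and the dominance ratio live in a YAML config
(`--config`); every default is echoed into a provenance header in the
outputs.

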