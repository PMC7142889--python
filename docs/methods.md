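# Methods

## The annotation model

`lipannot` annotates DDA LC-HRMS/MS lipidomics data in five stages:

1. **Feature finding.** MS1 peaks are linked across scans into
   extracted-ion chromatograms (±20 ppm, clusters split where the m/z gap
   between neighbouring centroids exceeds twice the tolerance).
   Chromatographic peaks are strict local maxima above a height threshold;
   each peak's boundaries sit at the nearest local minimum or the
   10%-of-apex crossing, whichever is closer to the apex, and the area is
   trapezoidal over retention time. A peak-shape quality score in [0, 1] is
   the Pearson correlation of the segment against a moment-fit Gaussian.
   The feature m/z is computed apex-locally — the intensity-weighted mean
   over the peak's own scans — so a trace shared with a temporally resolved
   near-isobar (typically the A+2 isotopologue of a lipid two mass units
   lighter) does not bias it.
2. **MS/MS association.** MS2 scans whose precursor lies within ±0.7 Da of
   the feature m/z (half a typical Q-TOF isolation width) and whose rt falls
   inside the peak bounds are averaged into a composite spectrum: fragments
   are binned at max(20 ppm, 0.01 Da) and each bin's intensity is the sum
   over scans divided by the number of scans, so a fragment absent from a
   scan counts as zero. One scan suffices; averaging favours MS/MS coverage
   over precursor-profile reconstruction, which would need many scans per
   precursor. The average is an unweighted mean across scans; whether
   weighting by per-scan precursor abundance would be preferable is an open
   question for real data.
3. **Candidate scoring.** Library candidates within ±20 ppm of the feature
   m/z are grouped by (class, sum composition, adduct). Three independent
   probabilities are computed per group (below) and combined
   multiplicatively; groups compete under a uniform prior and the posterior
   mode wins, with ties broken by higher MS/MS probability, then
   lexicographic name.
4. **Deconvolution.** Within the winning group, all constituent candidate
   spectra and the composite are laid out on a shared fragment-bin grid
   (greedy ascending-m/z merge at 20 ppm, the same tolerance as composite
   binning). Non-negative least squares gives candidate weights; percent
   abundance is each candidate's share of explained signal,
   100·wᵢ‖aᵢ‖₁/Σⱼwⱼ‖aⱼ‖₁, so candidates predicting few fragments are not
   inflated relative to fragment-rich ones. These percentages are
   qualitative: a handful of MS/MS scans cannot represent the true isomer
   distribution under a peak exactly.
5. **Decision and filtering.** Fatty-acyl-level annotation requires the top
   constituent percent to be at least `dominance_ratio` (default 2.0) times
   the runner-up; otherwise the sum-composition name is reported. Results
   must pass per-score minima and a combined-score minimum; removal counts
   per criterion are reported.

### Probability construction

Errors in mass, isotope ratios and fragment intensities are modelled as
normal. Each channel standardizes its error to z and maps it to the
two-sided tail probability 2(1 − Φ(|z|)) = erfc(|z|/√2), which is 1 at zero
error, 0.3173 at 1σ and 0.0500 at 1.96σ, and lives natively in [0, 1]. The
three channels are treated as independent, so the combined score is
100·p_mass·p_iso·p_msms; "normalized to 100" applies to the product, with
the per-channel values reported in [0, 1].

- Mass: z = Δppm/σ_ppm.
- Isotopes: per A+k ratio, z_k = (r_obs − r_theo)/(σ_iso·max(r_theo, 0.01));
  the floor keeps near-zero theoretical ratios from exploding the z-score.
  The channel probability is the geometric mean of the per-ratio tails over
  k = 1..K (default K = 2); a missing observed isotopologue counts as ratio
  0. Theoretical patterns include the adduct atoms.
- MS/MS: the residual fraction r = Σ|y − Aŵ|/Σy over the shared bins, where
  Aŵ is the NNLS-fitted composite model on the observed intensity scale.
  Observed intensity no candidate explains counts fully in the numerator,
  which is how spectral artifacts penalise the match; z = r/σ_frag.

Features without any associated MS/MS are left unannotated rather than
annotated on mass alone: in-source fragments (e.g. lyso-lipids shed by
intact phospholipids) and solvent clusters produce MS1 features whose
mass-only annotations would be false positives.

### Error-model and filter defaults

| parameter | default | unit | meaning |
|---|---|---|---|
| `sigma_ppm` | 5 | ppm | precursor mass error std (Q-TOF scale) |
| `sigma_isotope_rel` | 0.15 | – | relative error std per isotope ratio |
| `sigma_fragment_rel` | 0.5 | – | std of the MS/MS residual fraction |
| `thresholds.mass/isotope/msms` | 0.05 | – | per-channel minimum probability |
| `thresholds.combined` | 1.0 | 0–100 | minimum combined score |
| `dominance_ratio` | 2.0 | – | top/runner-up percent ratio for fatty-acyl naming |
| `mz_tol_ppm` | 20 | ppm | EIC linking, candidate window, fragment bins |
| `precursor_tol_da` | 0.7 | Da | MS2-to-feature association window |

The sigmas are calibration targets for a well-tuned Q-TOF, not measured
instrument constants; all are user-configurable and echoed into output
provenance headers. Ideally they would be estimated per instrument from QC
data, which is out of scope here.

## In silico libraries

Each lipid class is a template: a backbone elemental composition, a chain
count, allowed adducts per polarity, head-group fragment rules (fixed ion
composition or fixed neutral loss) and per-chain acyl rules (carboxylate
anion, fatty-acid neutral loss, ketene neutral loss). A species formula is
backbone + Σ CnH(2n−2−2·db)O per chain (the fatty acid minus the water of
esterification/amidation; amide formation loses the same atoms, so the
delta also serves SM/Cer N-acyl chains). A `0:0` chain is a free hydroxyl
and contributes nothing. SM and Cer backbones are parameterised so that the
standard di-hydroxy (d) sphingoid species formulas come out exactly
(e.g. SM(d18:1/16:0) → C39H79N2O6P), with the sphingoid base occupying the
first chain position; tri-hydroxy (t) species would need a user template.

Fragment intensities are declared per rule (head-group fragments near 1.0,
chain-dependent fragments 0.2–1.0 depending on class) rather than modelled
against chain length or unsaturation — a known simplification of real
fragmentation behaviour. Neutral-loss fragments are computed relative to
the actual precursor ion, so e.g. the TG [M+NH4]+ "DAG" fragment here
retains the adduct; generator and annotator share the templates, so the
pipeline is internally consistent, but users matching against external
spectra should adjust templates per instrument.

Atomic monoisotopic masses and isotope abundances are pinned in a
versioned constants table for bit-reproducibility. Isotope envelopes are
computed by per-element convolution in unit-mass (nominal mass-shift) bins
— the resolution at which Q-TOF A+k peaks are compared — and base-peak
normalised.

Library validation flags (a) any fragment whose m/z no elemental subformula
of the precursor-plus-adduct composition can explain within 5 mDa
(depth-first search over element counts with mass-bound pruning), and
(b) any fragment type present for one constituent of a class/adduct group
but absent for another. A library generated by the package's own rules
validates clean; the checks exist for user-supplied or hand-edited
libraries.

Built-in classes: PC, PE, PS, PG, PI, PA, LPC, LPE, TG, DG, MG, SM, CE,
Cer, FA. Others are added via user class-definition YAML files with the
same schema. Supported adducts: [M+H]+, [M+Na]+, [M+NH4]+, [M−H]−,
[M+HCOO]−, [M+CH3COO]−.

## Synthetic data

The generator emulates what the pipeline must handle: Gaussian elution
profiles (default σ = 0.05 min), isotope envelopes from the species formula
plus adduct, top-N DDA scheduling (default 1 s cycles, top 3, 10 s dynamic
exclusion, 1.3 Da isolation) with chimeric MS2 when another planted
precursor falls inside the isolation window, co-eluting isomer mixtures at
planted proportions, normal m/z jitter, multiplicative intensity noise, and
uniform-m/z decoy peaks with exponential intensities as a simple stand-in
for chemical noise. Constituent spectra are L1-normalised before
proportion-weighting, so a constituent's share of the summed fragment
current equals its planted proportion — exactly the quantity the NNLS
percent abundance estimates. Iterative-exclusion series exclude previously
fragmented (m/z, rt) pairs (±0.5 min by default) in later injections.

What the generator does **not** emulate: in-source fragmentation, solvent
clusters, retention-time structure by lipid class, chromatographic tailing,
detector saturation, or imperfect in silico intensities (the generator uses
the same templates the annotator matches against). Passing the synthetic
benchmarks therefore demonstrates the correctness of the algorithms —
feature integration, scan averaging, scoring calibration, NNLS recovery,
decision logic — not annotation accuracy on real instrument data, where
library fidelity dominates.

All randomness flows from one seeded NumPy generator; a fixed seed gives
byte-identical mzML output.

## Numerical choices

- NNLS via an active-set solver (`scipy.optimize.nnls`); on interior optima
  it agrees with the closed-form normal-equation solution to ~1e-14
  relative (tested to 1e-6). Rank-deficient designs (collinear candidate
  spectra, e.g. constituents whose rule products coincide) still return a
  fit but carry a collinearity flag; a design whose candidates overlap no
  observed signal is flagged degenerate.
- Fragment-bin merging is greedy in ascending m/z with threshold
  max(m/z·20 ppm, 1e-6 Da); bin centers are the member mean.
- Percent abundances sum to 100 (±1e-6) whenever any weight is positive and
  permute with candidate order; the level decision depends only on percent
  ratios and is scale-invariant.
- Ties in cross-class ranking break deterministically (higher p_msms, then
  lexicographic name). A single candidate has posterior 1 and infinite
  runner-up margin.
- Empty composites have no defined MS/MS probability; the sentinel (NaN) is
  excluded from MS/MS-confirmed output by every filter path.
- Degenerate inputs: zero-atom formulas, over-unsaturated chains
  (2c−2−2db < 0), non-positive sigmas, dominance ratios ≤ 1 and profile-mode
  spectra are rejected with explicit errors.

## Problem sizes in the shipped benchmarks

The test suite and `scripts/acceptance.py` use compact study conditions
chosen to exercise every code path at desk scale: 50 random NNLS designs
(2–3 columns), 200 two-constituent mixtures with proportions U(0.1, 0.9)
and 5% multiplicative fragment noise, a 20-lipid / 5-class zero-noise run
over a 13-min gradient, and a 10-analyte top-2 DDA iterative-exclusion
series of 6 injections. The zero-noise run is expected to be recovered
completely (20/20 at fatty-acyl level, no false positives above default
thresholds); the noisy mixture benchmark is expected to recover the top
constituent's percent to within 5 points on average.

## Known limitations

- Percent abundances are qualitative (single-scan MS/MS sampling, declared
  in silico intensities).
- Double-bond position, chain branching and (outside the LPC m/z 104 rule)
  sn-position are not resolvable from the supported MS/MS evidence and are
  never reported.
- No retention-time or collision-cross-section scoring channel; adding an
  orthogonal channel would further suppress in-source-fragment false
  positives.
- Non-fatty-acyl lipids (sterols, prenols) need experimental libraries and
  are out of scope; oxidized and ether lipids require user class templates.
- Cross-sample alignment and quantification are downstream concerns; the
  target-list export (name, m/z, rt) is the hand-off point.
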