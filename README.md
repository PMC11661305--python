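# smnd — single-molecule neighbor-density analysis of membrane-protein oligomers

Many membrane proteins work as small homo-oligomers whose composition shifts
with signaling state — the copper importer CTR1, for instance, is a
plasma-membrane trimer whose population partially de-trimerizes under copper
stress. Individual complexes (~10 nm) sit far below the resolution of even
single-molecule localization microscopy reconstructions, so their oligomeric
state cannot be read off an image directly. `smnd` implements the
**single-molecule neighbor-density (smND) assay**, which infers the
monomer/dimer/trimer composition of a protein population from the spatial
statistics of PALM localizations, together with everything the measurement
chain needs around it:

- **`smnd.synthetic`** — generators with ground truth for every input the
  pipeline consumes: oligomer localization fields, raw PSF movies,
  gold-nanosphere z-scan stacks, and puncta images.
- **`smnd.localization`** — raw movies → quality-filtered localization
  tables: temporal background subtraction, local-maximum detection, weighted
  2D Gaussian PSF fitting, per-localization error
  (σ²/N + a²/12N + 8πσ⁴b²/a²N²), FWHM/error/SNR filters, duplicate merging,
  redundant-cross-correlation drift correction.
- **`smnd.tirf`** — evanescent penetration-depth calibration from nanosphere
  z-scans ("raisin cake"): Gaussian z-profile fits, tilt-plane removal,
  bottom-14% noise floor, exponential ⊛ Gaussian depth fit.
- **`smnd.puncta`** — endocytic hot-spot (Rab5⁺) segmentation (rolling ball,
  Moments threshold, area/circularity particle filters), ROI selection
  (< 0.3 µm²) with congruent randomly placed control regions, per-ROI
  localization densities.
- **`smnd.neighbor`** — the assay core: neighbor density ND (other
  localizations within a 40 nm **diameter** circle), its distribution PND,
  the two-nearest-pairwise-distance statistic TNPD, Monte-Carlo theoretical
  PND, and mixture fitting by residual-square grid search over the
  (f_M, f_D, f_T) simplex. The weighted average subunit number is
  N̄ = Σₖ k·fₖ.
- **`smnd.dissociation`** — the two trimer-dissociation limiting models that
  bracket the trimer fraction: model 1 (T → M + D, fractions
  (x, x, 1−x)/(1+x)) gives the lower limit and model 2 (T → 3M, fractions
  (3x, 0, 1−x)/(1+2x)) the upper, with N̄ = 3/(1+x) and 3/(1+2x).
- **`smnd.pipeline`** — two-condition comparison (mean ± SEM per condition,
  two-sample Student t-test) with a reproducible JSON/Markdown report.

A thin `smnd` command-line tool (`simulate`, `localize`, `calibrate-depth`,
`rois`, `fit`, `compare`) wraps the library; `examples/` holds one short
narrative script per capability.

## Worked example

`examples/05_fit_oligomer_mixture.py` simulates a partially dissociated
field — 3000 complexes at true fractions (0.35, 0.15, 0.50) with 60%
detection efficiency and 10 nm localization precision — and runs the assay:

```
localizations: 3971; PND over ND=0..5: [0.537, 0.363, 0.098, 0.001, 0.0, 0.001]
median TNPD: 108 nm
true fractions (M, D, T):   (0.35, 0.15, 0.5)
fitted fractions (M, D, T): (0.26, 0.27, 0.47) +- (0.04, 0.04, 0.03)
N-bar = 2.21 +- 0.06
trimer fraction bounds: [0.50, 0.60] (model-1 extent 0.33, model-2 extent 0.18)
```

The PND says: 54% of localizations have no neighbor inside 20 nm, 36% have
one, 10% have two — the fingerprint of a mixed monomer/trimer population
after 60% detection thinning. The fit recovers the trimer share within its
bootstrap uncertainty (N̄ 2.21 ± 0.06 vs true 2.25); the monomer/dimer split
is the weakly identified direction at this field size. The two dissociation
models bracket the trimer fraction from below and above.

`examples/06_condition_comparison.py` runs the full two-condition contrast
(10 fields per condition, basal 65% vs stressed 44% trimer) and prints

```
basal        N-bar = 2.41 +- 0.03 (SEM), trimer = 0.63 +- 0.01
Cu-stressed  N-bar = 1.95 +- 0.03 (SEM), trimer = 0.43 +- 0.01
t-test N-bar:  t = 11.69, p = 7.7e-10
```

a clearly significant de-trimerization readout.

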