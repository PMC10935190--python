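# silagescan

Chemometrics pipeline for timing whole-plant corn silage harvest from
handheld near-infrared (NIR) scans of intact ears.

Whole-plant moisture (WP, % wet basis) is the standard surrogate for corn
maturity, but measuring it requires cutting and chopping whole plants. Ear
moisture (EM) is far easier to sense in the field, and the two are linked by
an established quadratic

    EM = 0.028·WP² − 2.24·WP + 78.3        (vertex at WP = 40, EM = 33.5)

`silagescan` implements the full estimation chain around that relationship:

- **synthetic data** — a generator for multi-season, multi-instrument ear
  scanning campaigns (truncated-normal WP, the quadratic EM link, Gaussian
  water/dry-matter absorbance bands on a variable-step 1350–2550 nm grid,
  per-instrument signatures, scatter and noise);
- **spectral I/O** — wide-format spectra CSVs, replicate averaging in the
  reflectance domain, conversion to absorbance A = log₁₀(1/R);
- **preprocessing** — autoscaling, multiplicative scatter correction (MSC),
  Savitzky–Golay derivatives (shorthand `D-2,2,11` = 2nd derivative,
  quadratic polynomial, 11-variable window), and a ranked pretreatment
  survey;
- **PLS core** — single-response NIPALS partial least squares, Venetian
  blinds cross-validation (10 splits, thickness 1), and latent-variable
  selection at the first RMSECV local minimum under an RMSECV/RMSEC
  divergence guard;
- **evaluation** — RMSEC/RMSECV/RMSEP (divisor N), bias, SEC/SECV/SEP
  (bias-corrected, divisor N−1), R², both RPD forms (1/√(1−R²) and SD/SEP),
  and the standard RPD performance classes;
- **moisture chain** — the three estimation strategies: oven EM → WP
  (method 1), NIRS EM → WP (method 2), NIRS → WP directly (method 3);
- **transfer experiment** — calibrations from every instrument subset of
  season A validated per-instrument on season B, quantifying
  spectrometer-to-spectrometer bias.

## Worked example

`examples/three_methods.py` simulates the default two-season campaign
(610 calibration ears, 330 validation ears, three instruments, three scans
each), calibrates ear- and whole-plant-moisture PLS models with the
`D-2,2,11` pretreatment, and compares the three strategies on the held-out
season:

```
method                    RMSEP   SEP   bias   R2P  RPD  class
method1_oven_chain         2.17  2.17  -0.02 0.860  2.7  screening
method2_nirs_chain         2.63  2.61  -0.41 0.796  2.2  rough screening
method3_direct             2.78  2.59  -1.01 0.805  2.3  rough screening
```

RMSEP and SEP are in moisture percentage points. The oven-reference chain
(method 1) sets the precision ceiling; chaining a NIRS ear prediction
through the quadratic (method 2) loses a little precision; the direct model
(method 3) trades a further loss for needing only one calibration. The other
examples cover campaign simulation, the pretreatment survey, and the
instrument-transfer matrix — each prints the numbers it computes with a note
on what they mean.

A thin CLI wraps the same library for shell use:

```sh
silage-scan simulate --config examples/sim_config.yaml --out scratch/run
silage-scan calibrate --spectra scratch/run/spectra.csv \
    --ref scratch/run/reference.csv --target ear --out scratch/model.json
```

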