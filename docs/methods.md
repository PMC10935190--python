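# Methods

## The estimation problem

Corn silage must be ensiled inside a fairly narrow whole-plant moisture
window (roughly 55–81 % wet basis, %w.b.); outside it fermentation quality
and storage stability suffer. Whole-plant moisture (WP) is expensive to
measure directly, so the pipeline estimates it from the intact, de-husked
ear, whose moisture (EM) is linked to WP by a fixed quadratic

EM = a₂·WP² + a₁·WP + a₀,  a₂ = 0.028, a₁ = −2.24, a₀ = 78.3  (all %w.b.)

with vertex at WP = −a₁/(2a₂) = 40 (EM = 33.5). The coefficients are
constants of the package: refitting them would require the original
two-year reference dataset, which is not available. Inversion takes the
larger root (the increasing branch, WP ≥ 40), since every field-relevant WP
lies above the vertex and ear moisture rises with plant moisture there. An
EM below 33.5 has no real solution on that branch; the inversion raises an
error per ear rather than clamping, and the chain runners collect such ears
in `failed_ears` instead of silently dropping them.

Three estimation strategies share this chain:

1. **method 1** — oven-dried EM inverted through the quadratic;
2. **method 2** — EM predicted from NIR ear spectra by PLS, then inverted;
3. **method 3** — WP predicted from ear spectra directly by PLS.

## Synthetic campaigns

No raw spectra are distributed with the package; every analysis runs on
synthetic campaigns whose statistical structure mirrors a two-season field
survey. The generator draws, per season:

- WP ~ truncated normal. Presets: season "2021" (calibration) mean 62.5,
  SD 6.9 on [42, 85]; season "2022" (validation) mean 67.2, SD 6.1 on
  [55, 81]. These were derived by inverting the quadratic at the target EM
  statistics (2021: mean 49, SD 9.6; 2022: mean 55, SD 10), including the
  curvature correction a₂σ² to the mean and the variance shrinkage from
  truncation. A 2·10⁵-draw check reproduces EM mean 49.0 / SD 9.4 and
  55.3 / 9.1 respectively.
- EM_true = quadratic(WP) + N(0, `em_residual_sd`); default 3.2 points,
  chosen so the quadratic explains ≈89 % of EM variance (3.2 ≈ 9.6·√0.11).
- Oven references EM_oven, WP_oven = truth + N(0, SEL) with SEL = 0.35
  points, the laboratory reference error.
- EM_scan = EM_true + N(0, `scan_moisture_sd`), default 2.8 points: the
  moisture actually encoded in a scan of the ear surface differs from the
  whole-ear oven value. This term is the irreducible error floor of any
  spectral calibration here; 2.8 was set a priori so that SEC² ≈
  scan_sd² + SEL², matching the ear-calibration error scale the pipeline is
  meant to reproduce (SEC ≈ 2.8, R²C ≈ 0.92).

Spectra are rendered on a wavelength grid whose step grows linearly from
2.5 nm at 1350 nm to 8.8 nm at 2550 nm (241 points, average step 5 nm),
emulating a scanning-interferometer export. Absorbance is

A(λ) = baseline(λ) + (em/100)·Σ water bands + (1 − em/100)·Σ dry bands,

with Gaussian water bands at 1450/1950 nm (widths 60/80 nm, amplitudes
0.6/1.0) and dry-matter bands at 1730/2100/2270 nm — standard O–H, C–H and
starch assignments; amplitudes are free parameters of the simulator, not
fitted quantities. Each (ear, instrument) sample receives multiplicative
scatter (SD 0.05) and an additive offset (SD 0.02); replicate scans then
share that realization and differ only by instrument noise
(SD 0.004 absorbance), so averaging three replicates reduces noise by √3 as
in the real protocol. Reflectance R = 10^(−A) is floored at 10⁻⁶ before any
log transform. With all noise off, absorbance is exactly affine in em/100,
so a 1-latent-variable PLS recovers moisture to numerical precision — a
property the tests assert.

### Instrument signatures

Each simulated spectrometer has a wavelength shift (applied analytically,
bands evaluated at λ − shift), photometric gain, baseline offset and noise
SD — and additionally a moisture-response distortion em_eff =
`em_response_gain`·em + `em_response_offset`. The latter is deliberate:
derivative preprocessing removes baseline and, to first order, gain effects,
and the per-sample scatter already teaches PLS to ignore overall gain, so
purely photometric differences produce almost no cross-instrument bias. A
response distortion — different collection optics effectively sampling
wetter or drier ear volume — is collinear with the moisture signal and
survives any linear pretreatment, which is what makes single-instrument
calibrations transfer poorly in practice. Defaults: instrument 1 clean;
instrument 2 offset −1.5; instrument 3 gain 0.96, offset +4.5 plus a 3 nm
shift and 1.03 photometric gain. This yields same-instrument |bias| ≲ 0.5,
single-instrument cross-instrument bias up to ≈ 4–5 points, and pooled
("All") calibration bias ≲ 2 — the qualitative transfer structure the
experiment is designed to expose.

What the generator does *not* emulate: kernel-level phenology (milk line),
radiative transfer/Kubelka–Munk scattering physics, seasonal drift of an
individual instrument, and measurement-geometry effects within an ear
(an ear is one homogeneous spectrum source). Passing tests therefore show
the pipeline's statistical machinery is correct under the stated error
structure, not that a real instrument would achieve these numbers.

## Calibration pipeline

Fixed processing order: replicate scans are averaged per (ear, instrument)
in the **reflectance** domain, then converted to absorbance A = log₁₀(1/R)
(base 10, the chemometrics convention). The two operations do not commute;
a regression test pins the order.

Pretreatments are train/apply separable: column statistics (autoscaling,
sample SD with n−1) and the MSC reference (mean calibration spectrum) are
frozen at training time and applied unchanged to validation rows.
Savitzky–Golay derivatives operate in variable-index space — window widths
count variables, not nm, matching how such filters are specified for
instruments with non-uniform grids — with edges filled by evaluating the
terminal fitted polynomial frame at the edge positions, keeping the grid
length stable. The survey grid is: none, autoscale, MSC, and SG derivatives
over derivative order {1,2} × window {9,11,…,27} × polynomial order {2,3}
(43 candidates), ranked by RMSECV, ties broken by fewer latent variables,
then by the SECV/SEC ratio.

PLS is single-response NIPALS with deflation — deterministic, no random
initialization; regression vectors are stored for every LV count up to
`max_lv` (default 20). Rank deficiency truncates with a warning. X and y are
always mean-centered inside PLS, independent of pretreatment.
Cross-validation is Venetian blinds (10 splits, thickness 1, row i → split
⌊i/thickness⌋ mod n_splits, in file order); both the pretreatment statistics
and the PLS fit are recomputed inside every split, so held-out rows never
leak into the transform applied to them. The LV count is the first local
minimum of RMSECV (position 1 qualifies if RMSECV₁ ≤ RMSECV₂; the last
position never qualifies) subject to RMSECV/RMSEC ≤ 1.25 — a concrete
reading of "not divergent", which is otherwise unquantified; fallbacks are
the guarded global minimum, then the ratio-minimizing LV with a warning.

## Statistics and conventions

RMSE uses divisor N; bias is mean(predicted − reference); SEC/SECV/SEP are
the bias-corrected residual SDs (divisor N−1). The exact identity

N·RMSE² = N·bias² + (N−1)·SEP²

holds for every evaluated pair set and is enforced on every report. R² is
the squared Pearson correlation — under this definition RPD = 1/√(1−R²)
reproduces the conventional headline ratios (0.88 → 2.9, 0.79 → 2.2), which
the SD/SEP form does not; both forms are reported, the R²-derived one drives
classification. The slope/intercept regress predicted on reference
(predicted as response), the plotting convention for predicted-vs-actual
figures; the reverse regression is equally defensible and the choice is
noted as such. The published RPD class boundaries leave gaps (e.g. 1.9–2.0);
they are closed into contiguous half-open bins [0,2.0), [2.0,2.5),
[2.5,3.0), [3.0,3.5), [3.5,4.0), [4.0,∞) so classification is total and
monotone, keeping 2.9 in "screening". Note one literature inconsistency: an
RPD of 2.2 is sometimes labelled "screening" in prose; under these bins it
is "rough screening", and the package follows the bins. Reported table
values are rounded to one decimal at magnitude ≥ 1 and two significant
figures below 1; JSON outputs keep full precision.

A related published-table caveat: among the printed validation triples used
as cross-checks, one cell (calibration 2&3 → instrument 1: RMSEP 2.7,
SEP 2.6, bias 2.7) violates the identity above — |bias| alone would exceed
RMSEP — and is treated as a typo; the package never emits an inconsistent
cell. Similarly, the printed season totals "5481 scans / 1827 averaged"
equal 609 × 9 and 609 × 3, not 610 × 9: one ear's scans were evidently lost
in the original campaign. The generator stays faithful to its configuration
(610 ears → 5490 scans); the printed totals are reproduced exactly by a
609-ear season.

## Transfer experiment

Calibrations are built from every non-empty subset of instruments on season
A (one averaged spectrum per ear per instrument, pooled across the subset)
and validated on season B per instrument plus pooled "All". The LV count is
re-selected per subset; the pretreatment is shared across subsets by default
(`D-2,2,11`), as a single-table report implies, with an optional per-subset
survey. A subset with no data becomes a recorded failure row; the run
continues.

## Problem sizes and determinism

Default study sizes are the full design (610 + 330 ears, 3 instruments,
3 replicates, 241 wavelengths); the whole acceptance run completes in well
under a minute on one CPU, and unit tests use scaled-down campaigns
(40–150 ears) for speed. Every stochastic stage flows from a single root
seed through stage-keyed derived seeds (`config.derive_seed`), making full
campaigns bit-reproducible; the CLI's simulate command writes byte-identical
outputs for identical configs.

## Known limitations

- The quadratic's coefficients and its increasing-branch inversion are
  assumed, not estimated; ears below EM 33.5 cannot be mapped to WP.
- Linear instrument distortion model; no piecewise direct standardization
  or other spectral transfer corrections (the experiment varies calibration
  composition only).
- MSC uses a single mean-spectrum reference; no SNV, detrending, OSC or
  wavelet pretreatments.
- Venetian blinds operate on file order; sorting rows changes split
  composition and hence RMSECV slightly.
- Single-response PLS only; no variable selection or prediction intervals.
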