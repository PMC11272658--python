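# Methods

## Wall shear stress models

All three methods instantiate τ = η·σ with the wall shear rate derived
from the Doppler-measured maximal (centreline) velocity Vmax and the inner
diameter D.

**Theoretical Newtonian (tN).** Blood as a homogeneous Poiseuille fluid:
the parabolic profile gives Vmax/Vm = 2 and σ = 4·Vmax/D, so
τt = ηb·4·Vmax/D with the measured whole-blood viscosity ηb. ηb measured at
high shear rate is itself an apparent quantity, which is why this simple
form tracks the plug/sheath model closely.

**Corrected Newtonian (cN).** In small arteries the measured
centreline-to-mean velocity ratio is ≈1.39–1.54 rather than 2; with the
conventional 1.45 the general form τ = η·(8/ratio)·Vmax/D becomes
τc = η·5.5·Vmax/D. The rounded coefficient 5.5 is the default for fidelity
to the published form; `exact_coefficient=True` uses 8/ratio = 5.5172.
The viscosity is the caller's choice among plasma ηp, whole-blood ηb, and
apparent ηapp = 1.78·ηp (the 1.78 correction is the literature value for
converting plasma to effective whole-blood viscosity in this regime); the
cohort driver computes all three variants.

**Fåhræus-type plug/sheath (F).** Blood modelled as a central plug
containing all red cells, moving at Vmax, inside a cell-free plasma sheath
across which the velocity falls to zero at the wall. Solving the
axisymmetric sheath flow yields

    |σF| = (4·Vmax/D) · f(Ht),   f(Ht) = (1 − Ht) / (1 − Ht·(1 − ln Ht)),

and τF = ηp·|σF| with the group-pooled plasma viscosity (plasma is pooled
per sex before measurement, so ηp is one scalar per group). f is > 1 on
(0, 1), strictly increasing, → 1 as Ht → 0 (the Newtonian plasma limit,
asserted to 1e-4 relative at Ht = 1e-6) and diverges as Ht → 1. The shear
vector points against the flow; magnitudes are reported throughout.
Printed variants of the sheath formula circulate with a "1 − 2·ln Ht"
inner term; this package uses the 1 − ln Ht form, which is the one
consistent with the published per-group WSS values (the alternative
reading is rejected on that numerical ground).

**Hematocrit–viscosity regression.** ηb [Pa·s] = 0.01258·Ht − 0.001443
with Ht a fraction. The coefficients only make dimensional sense on this
scale (0.43 → 3.97×10⁻³ Pa·s ≈ 4 cP, matching measured values ~3.9–4.1 cP);
the line has a positive root at Ht ≈ 0.115 below which the prediction is
non-physical and the function raises. Substituting this line into the tN
formula makes hematocrit an explicit parameter of both methods, which is
what the sensitivity sweeps compare. The regression's weak fit on real
data (R² ≈ 0.35) is a property of biological scatter; the synthetic
cohort can emulate it but no test can reproduce it from printed summaries.

## Sensitivity analysis

Sweeps hold all inputs but one constant at sex-pooled diastolic means
(D = 0.3815 mm, Vmax = 162 mm/s, Ht = 0.43, pooled ηp = 1.265 cP — the
arithmetic means of the printed per-sex means, since pooled values are not
printed; the choice is immaterial for the headline statistic, see below)
and report the difference normalized to the two-method mean,
Δ% = 100·(τt − τF)/((τt + τF)/2). Because τt/τF = ηb(Ht)/(ηp·f(Ht))
contains no D or Vmax, Δ% is exactly constant over the diameter
(0.1–1.0 mm, 0.1 steps) and velocity (100–1,100 mm/s) grids — asserted to
1e-10 relative — at ≈13.01% for Ht = 0.43, and increases monotonically
from ≈7.1% to ≈15.8% over Ht = 38%–48% (1-point steps; only the range is
prescribed, the step is a package choice).

## Image pipeline

**Background threshold.** Foreground (labelled organelles) occupies a few
percent of voxels at most, so the grey-level histogram is dominated by a
Gaussian background mode. μ_bg and σ_bg are estimated by least-squares
fitting a Gaussian to the contiguous histogram run around the tallest peak
(bins ≥ 5% of the peak); integer-valued (8-bit) data are binned one bin
per grey level to avoid bin/level aliasing. Fallbacks: moment estimates of
the selected bins if the fit fails; whole-image mean with σ = 0 for a
constant image (yielding an empty mask rather than an error). Voxels
strictly above μ_bg + k·σ_bg with k = 3.89 are foreground; for Gaussian
background this retains Φ(3.89) = 99.995% of background voxels. On
quantized 8-bit noise the realized tail depends on where the threshold
falls between grey levels, so the exact-tail check is meaningful only on
continuous noise; the 8-bit guarantee asserted is retention ≥ 99.99%.

**Despeckle.** One pass of a 3×3 median filter (majority of 9,
zero-padded borders), which removes isolated foreground voxels and
preserves solid regions. Note a checkerboard is *not* removed: a True
cell has itself plus its four diagonal neighbours True (5 of 9), so the
majority keeps it — the filter is validated against a brute-force oracle
rather than against intuition.

**Objects.** Connected components with 8-connectivity; size segmentation
discards components below 10 µm² (nuclei) or 2 µm² (Golgi). Centroids are
intensity-independent sub-pixel component centroids; axes are
ellipse-equivalent (second image moments). Touching organelles merge into
one component — a known limitation shared with any connectivity-based
labelling. The minor axis is floored at one pixel so the elongation ratio
is always defined.

**Pairing and classification.** Each nucleus pairs with its nearest Golgi
centroid (Euclidean); a Golgi may serve several nuclei (per-nucleus
pairing; whether the original analysis allowed reuse is not documented, so
the more permissive convention is the default), ties break to the lowest
Golgi id. The nucleus→Golgi angle to the flow direction, on the [0°, 180°]
semicircle, is classified with half-open bins dromic [0°, 60°), lateral
[60°, 120°), antidromic [120°, 180°]; the printed class brackets overlap
at 60° and 120°, and the half-open convention resolves them (boundary
mass is measure-zero for continuous angles). Zero-length vectors are
flagged and excluded from classification. Polarity is summarized by the
mean ± SEM of the N-G length [µm] and the nucleus elongation
(major/minor ≥ 1). The original colour-merge-then-threshold step reduces
to independent per-channel processing when channels are kept separate
digitally; this is functionally identical and is what the pipeline does.

## Synthetic data

**Cohorts.** Truncated-normal draws (at zero; hematocrit also at one) per
field, defaults equal to the published group means ± SD — normality is the
minimal assumption given only mean ± SD summaries. Per-animal quantities
(Ht, ηb, heart rate) are shared across an animal's two phases. With
`viscosity_coupling`, ηb is the regression line plus Gaussian noise with
SD = slope·sd(Ht)·√((1−R²)/R²), which makes the expected regression R²
equal the target (default 0.35).

**Images.** Nuclei are rendered as filled ellipses at uniform random
orientation; each Golgi is a disk placed at the nucleus centre plus an
N-G length along a direction drawn uniformly within the cell's assigned
class interval (random sign — the semicircle angle is sign-invariant).
Class assignment defaults to exact counts (largest-remainder rounding)
with multinomial sampling as an option. Gaussian background noise is
added everywhere and the result quantized to 8-bit. Size draws are
truncated at ±2 SD, and nucleus centres are rejection-sampled with
minimum separation max(1.05·max major axis, 2·max N-G length + 0.5 µm) —
this guarantees no nucleus overlap and that every nucleus's nearest Golgi
is its own, so ground-truth recovery failures indicate pipeline bugs.
An infeasible density raises a packing error after a bounded number of
attempts. Defaults emulate the acquisition geometry (2051 px at 78 nm =
160 µm field) with 25 cells; tests use a 1024 px / 234 nm (240 µm) field
with 50 cells, which keeps the density well below the packing limit and
each image under a second of processing. Default morphology (nucleus
11 × 5.5 µm, N-G length 5 ± 1 µm, Golgi 12 µm², background 20 ± 5 grey
levels, foreground 200) is a realistic mouse-EC choice; the spec enforces
foreground > background mean + 6 SD.

What the generator does *not* emulate: confocal point-spread blur, photon
(Poisson) noise, intensity gradients, touching/confluent cells, partial
cells at field borders, and autofluorescent artefacts. Passing recovery
tests therefore demonstrates correctness of the measurement chain on
well-separated, well-exposed objects, not segmentation robustness on
difficult real images.

## Statistics

Mann-Whitney U (two-sided) for male-vs-female comparisons, OLS for the
hematocrit–viscosity relation (fit on the Pa·s/fraction scale, reported
also in cP), χ² goodness-of-fit against the equiprobable one-third null
for orientation classes (df = 2) plus a two-sample contingency χ², and a
two-sided one-sample Wilcoxon signed-rank test of elongation against 1.
Rank tests use the exact null distribution for n ≤ 25 and the normal
approximation with continuity correction above (the sources are silent on
this; the cut-off is a package convention). If every elongation equals 1
the Wilcoxon statistic is undefined and the result is reported
non-significant with a warning. Significance is α = 0.05 throughout, with
no multiple-testing correction (none is applied in the workflow this
package supports). Type-I calibration is checked by simulation at 10,000
null replicates in the asymptotic regime; the continuity correction makes
the rank tests mildly conservative, so calibration is asserted within
0.035–0.065 rather than at the Monte-Carlo error alone.

## Problem sizes and tolerances

Closed-form WSS checks run on single records; consistency
(τ = η·σ after unit conversion) is asserted to 1e-12 relative and sweep
invariance to 1e-10 relative. The threshold calibration uses a 2048²
continuous-noise image (≈210 expected foreground voxels; tolerance 4
binomial SDs plus a small estimator allowance). End-to-end polarity
recovery uses 10 seeded 50-cell fields (500 cells; class fractions within
the 95% binomial CI, lengths/elongations within 10%). The whole suite
runs in well under a minute on one CPU.
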