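# Methods

`scfs` re-implements the analysis chain of AFM-based single-cell force
spectroscopy (SCFS): a live cell glued to a tipless cantilever is pressed
onto a cell monolayer and retracted at constant velocity; discontinuities
in the retract force curve report the breakage of individual
cadherin-mediated adhesion bonds ("jumps") and the release of membrane
tethers ("plateaus").  Because the analysis is only testable against known
ground truth, the package pairs the detector with a physics-based
generator; this note documents both halves, the parameters that matter,
and what the synthetic results do and do not demonstrate.

## Unit system

Forces in pN, lengths in nm, time in s, pulling velocities in um/s,
frequencies in Hz, spring constants in pN/nm, energies in pN nm.
Conversions happen only at I/O boundaries.  kB T is computed from the
measurement temperature (default 310.15 K, i.e. 4.282 pN nm); every
temperature-dependent quantity takes the temperature from the curve
metadata.

Sign conventions: deflection is positive when the cantilever is pushed
away from the surface, so adhesion during retract is negative; reported
step heights and rupture forces are positive magnitudes.  Piezo extension
`z` is largest in contact; tip-sample separation is
`s = (z_contact - z) - d`, zero at contact and increasing during retract.

## Synthetic force curves

A retract trace is the superposition of

* **bond ramps.** Each engaged bond is loaded through an effective
  stiffness `k_eff` (cell body, linkers and cantilever in series; default
  0.2 pN/nm, far softer than the 60 pN/nm lever, as appropriate for a
  cell-height contact).  Under constant pulling velocity `v` the force on
  the bond ramps at `r = k_eff * v` (600 pN/s at 3 um/s).  Rupture forces
  follow the Bell escape model: off-rate `k(F) = k0 exp(F x_beta / kBT)`,
  giving the ramp-loading survival
  `S(F) = exp(-(k0 kBT/(x_beta r)) (e^{F x_beta/kBT} - 1))`, sampled
  exactly by inverse CDF.  Bonds engage at separations drawn uniformly
  over `[anchor_offset, anchor_offset + engagement_span]` (defaults
  100-500 nm) and rupture independently; the number of bonds per curve is
  Poisson with mean `n_bonds` (default 3).
* **tether plateaus.** Constant pulling force (default 30 pN) from an
  engagement separation until an exponentially distributed detachment
  length (default scale 1000 nm), then an abrupt drop.  Poisson mean 1 per
  curve.
* **noise and drift.** White Gaussian deflection noise (default 0.05 nm,
  i.e. 3 pN of force noise at 60 pN/nm -- typical for a soft lever in
  liquid) and a linear baseline drift (default 0.002 pN per nm of piezo
  travel).

Steps are instantaneous (single sample): a detector must not depend on
unobservable rise kinetics.  The approach is a linear contact ramp to the
maximum load (3 nN) and the dwell is constant; the retract covers 10 um of
piezo travel at 2 kHz sampling.  Every curve carries its ground-truth
event list (index, true force, class).  All randomness descends from one
seed through a stable `(seed, map_id, curve_index)` tree, so any curve of
a force map can be regenerated alone.

### Condition presets

Presets encode the studied cell pairings (three Dupuytren-patient
fibroblast types NF/SF/DF and MDCK epithelial cells, homo- and
hetero-cellular) by calibrating `k0` in closed form so that the Bell
median at the 3 um/s anchor equals the pairing's published median rupture
force; `x_beta` is fixed at 0.1 nm so the median roughly doubles over the
3-10 um/s series, matching the reported trend's magnitude.  Treatments:
EGTA (calcium chelation) sets the bond rate to ~0 instead of rescaling
forces; cytochalasin D (actin depolymerisation) scales each pairing's
target median by the published drug/control ratio (0.26-0.57); ML-7
(myosin-light-chain-kinase inhibition) scales only the DF-DF pairing (x
1.874) because no other pairing showed a significant change -- the small
tabulated differences elsewhere are treated as sampling noise, otherwise
"no change except DF-DF" would be untestable at simulation sample sizes.
DMSO (vehicle) shares the control scale.

Over a 3.3-fold velocity range a logarithmic (Bell) and a linear
force-velocity law are experimentally indistinguishable; the presets
assume Bell kinetics for internal consistency and the package makes no
claim that either functional form is validated by the match.

### Thermal deflection records

Calibration input is synthesised in the frequency domain: independent
complex-Gaussian Fourier coefficients shaped by the simple-harmonic-
oscillator (SHO) line at `f0` with quality factor `Q` (defaults 2 kHz,
2 -- a liquid-damped soft lever), optionally plus a white readout floor,
normalised so the expected sample variance is exactly `kBT/k`
(equipartition).  The series is stationary and Gaussian by construction.

## Spring-constant calibration

`estimate_k_equipartition` removes mean and linear trend and returns
`k = kBT / var(d)`, with a chi-square confidence interval at the record's
effective sample size (n over the integrated autocorrelation time).
`fit_sho_psd` fits a Welch-averaged spectrum to SHO + white floor and
integrates the fitted resonance only (`var = A pi f0 Q / 2`), which
excludes readout noise from the force scale; a record without a credible
resonance (fitted peak < 3x the floor, or Q < 0.5) raises an error rather
than returning a number.  The optional first-bending-mode correction
factor is exposed and defaults to 1.0.  On clean synthetic records the
two routes agree within a few percent; their ratio is a useful QC check.

## Event detection

Per curve: (1) a straight baseline is least-squares fitted to the final
quarter of the retract (farthest from the surface, assumed event-free)
and subtracted; the per-sample noise `baseline_sd` is 1.4826 x MAD of the
corrected tail, robust to tethers reaching into it.  (2) The contact
point is the last sample of the initial repulsive region (force > 3
baseline_sd); curves starting off-contact fall back to index 0 and are
flagged.  (3) Steps are found and (4) classified.

**Step statistic.**  At every interior boundary a straight line is fitted
to `window_w` (15) samples on each side and both lines are extrapolated
to the boundary; the step estimate is their difference.  This is exactly
zero on any piecewise-linear stretch -- loaded ramps, drift, the contact
kink -- which plain window means are not.  The estimate is divided by its
standard error: the larger of the local fit-residual scale and
`baseline_sd`, times the exact extrapolation leverage of the two fits.
Using the local residual scale makes slope kinks (where the local-line
model itself is wrong) self-suppressing.  Candidates must exceed
`threshold_theta` (6) in the release direction and clear a force gate --
the larger of `min_force_factor x baseline_sd` (3 sigma) and an absolute
`min_step_force_pN` floor (5 pN, the practical force resolution of a soft
lever; without an absolute floor the noise-free limit would admit
arbitrarily small discontinuities).  The gate is applied to
`g = est + mean(fitted slopes)`, which equals the raw one-sample trace
difference exactly on piecewise-linear data, so the detector thresholds
the identical quantity as an exact finite-difference scan and agrees with
it sample-for-sample on noise-free curves.

Candidates are strict local maxima of the statistic, supplemented by
indices whose raw difference clears a pool gate (next to a neighbouring
event the global statistic is blind because the neighbour inflates the
local residual scale).  Negative-direction steps (tether engagements) are
detected symmetrically but kept internal.  Each candidate is verified
with windows truncated at its accepted neighbours, iterated to a fixed
point: this resolves genuinely distinct steps down to
`min_separation_events` (3 samples) apart while evicting side-lobe ghosts
of a single noisy step.  Steps closer than that resolution are physically
one trace discontinuity; the detector reports them as one event measured
across the whole cluster (summed height), and the benchmark merges ground
truth the same way before matching.

**Classification.**  A bond rupture releases its loading stiffness, so
the force-vs-separation slope relaxes by ~`k_eff` across the step; a
tether detach removes a constant-force plateau and leaves the slope
unchanged.  The class is decided by the slope change
(`|pre - post| >= slope_min`, default 0.05 pN/nm), not the pre-slope
alone, which stays correct when a tether lets go while other bonds are
still being loaded.  Slopes are fitted over windows grown adaptively
(up to `slope_window` = 60 samples) until the fit residuals exceed the
baseline noise -- an engagement kink of another bond stops the growth --
and truncated at neighbouring detected events of either sign.  The
evidence bar rises with the slope uncertainty of short usable segments
and is capped at 3x `slope_min` so a clear release stays callable.  The
loading rate is `|pre_slope| x v`; with several bonds engaged the local
slope is the summed stiffness, which is what the experiment measures too.

Detected events inside the contact region are discarded (non-specific
surface interactions are out of scope), and only jump-class forces enter
the rupture-force statistics.

## Statistics

Pooled jump forces per pairing x treatment x velocity are summarised by
25th/50th/75th percentiles (linear interpolation between order
statistics) and a histogram with 10 pN bins from zero.  The printed
quartile columns of the source tables are not ordered around their
medians and cannot be true percentiles; this package computes true
percentiles and does not attempt to reproduce those columns.  The
velocity series is summarised by a least-squares line through
(velocity, median) and the Spearman rank correlation.  Comparisons use
the two-sample Wilcoxon rank-sum (Mann-Whitney) test -- the study design
compares independent pooled populations -- with full enumeration of the
permutation null (tied ranks included) whenever the number of
assignments is at most 2e5, and the tie-corrected normal approximation
otherwise; two-sided p as twice the smaller tail, capped at 1, so
identical samples give p = 1.  Stars: `*` for p < 0.05, `**` for
p < 0.005.  Forces are pooled across curves and maps (no per-cell random
effect); per-map medians can be formed by the caller from the event
table if needed.

## What the synthetic results show -- and what they do not

Passing tests demonstrate that the detector recovers what the generator
hid (recall/precision >= 0.95 and RMSE <= 3 pN at >= 5 sigma step
height), that the sampler, calibration and rank-sum machinery are
mathematically correct, and that the pooled statistics reproduce the
qualitative study patterns (monotone velocity trend, EGTA abolition,
cytochalasin-D decrease with `**`, ML-7 increase for DF-DF only).  They
do not validate the biological parameter values: real curves have
viscoelastic rise times, worm-like-chain tether elasticity,
dwell-time-dependent bond maturation and correlated noise, none of which
the generator emulates.

Known, quantified biases at the default study conditions:

* **Detection-floor truncation.**  Events below ~3 sigma/5 pN are
  undetectable, so detected pooled medians run above the generative
  median (~+10% for a 52 pN population, more for weaker ones).  For the
  same reason the detected cytochalasin-D/control median ratio (~0.7) is
  compressed toward 1 relative to the generative ratio (0.53).  Presets
  deliberately calibrate the *distribution* median to the published
  value; correcting the target for the detector's floor would couple the
  generator to the detector under test.
* **Superposition limits classification.**  With ~3 bonds and ~1 tether
  per curve, events overlap; at the defaults ~86% of jumps and ~71% of
  tethers are classified correctly, the residue being genuinely
  ambiguous local geometry.  Misclassified tethers enter jump pools at
  the plateau force and slightly dilute medians; contrasts between
  treatment arms are unaffected because the dilution is common to both.
* **Sub-resolution merging.**  Ruptures closer than 3 samples are
  reported (and benchmarked) as one summed event.

## Problem sizes

Default desk-scale runs: acceptance-style checks use 200 noise-free and
500 noisy curves for the detector, 1e5/1e6 draws for the sampler, one
50 s (1e6-sample) thermal record, 6-10 maps of 24 curves per design cell
for the study-level quantities, and 1000 replicates for the type-I-error
calibration; these sizes put the Monte-Carlo error comfortably below
every tolerance asserted, and the full test suite plus acceptance script
completes in a few minutes on one CPU.
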