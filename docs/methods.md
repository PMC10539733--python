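# Methods

## Scope and data model

The package analyses ¹⁹F NMR observables of 4-fluoroproline (FPro)
residues embedded in polyproline peptides: relaxation rates and
heteronuclear NOEs as probes of segmental dynamics, chemical shift
perturbations (CSP) as probes of SH3-domain binding thermodynamics, and
exchange line broadening as a probe of binding kinetics. Raw spectra are
out of scope; inputs are tabulated quantities (distances, CSA tensors,
shifts, couplings, intensities, line widths) carried in small CSV tables,
and a synthetic-data module generates every input format with realistic
statistical structure.

## Spin relaxation model

A single ¹⁹F nucleus relaxes through pairwise dipole–dipole couplings to
the five pyrrolidine ring protons (Hγ, Hβ2, Hβ3, Hδ2, Hδ3) and through
its shielding anisotropy. Assumptions:

- **Pairwise additivity.** Each F–H vector contributes independently;
  H–H couplings, dipole–CSA cross-correlation and the antisymmetric CSA
  components are neglected. The antisymmetric components are parsed and
  stored on `SpinSystemGeometry` for future use. A full
  Liouville-space treatment of the 16-spin system would shift the
  slow-tumbling R1 maximum from the ≈4.1 ns this model yields to ≈4.4 ns
  and lower R1 of the high-CSA Cγ-endo conformer by a few tenths of s⁻¹;
  interval tolerances in the tests absorb this.
- **Rigid isotropic tumbling.** One correlation time τc; no internal
  order parameters. Justified by the strong pucker bias of (4R)/(4S)-FPro
  (one ring conformer dominates), which removes the picosecond
  pucker-exchange modulation of the CSA that would otherwise require a
  correlated-Hamiltonian model.
- **Spectral density convention.** J(ω) = (2/5)·τc/(1+ω²τc²) paired with
  the d²/4 and d²/8 dipolar prefactors and the (ΔσωF)²/3·(1+η²/3) CSA
  prefactor (Cavanagh-style). Δσ in ppm is converted with ωF at the
  configured field (default B0 = 14.1 T, i.e. 600 MHz ¹H / 565 MHz ¹⁹F).

The steady-state NOE upon selective saturation of one proton (default Hγ,
whose F–H distance is pucker-independent) uses the two-spin-plus-sink
approximation: NOE = (γH/γF)·σ_sat/ρ with ρ = R1 of the full system, the
non-saturated protons and the CSA acting as pure leakage. Ignoring
remote (non-ring) protons overestimates |NOE| by an estimated 1–3 %
absolute; this is the main reason NOE-derived τc values carry interval,
not point, accuracy.

Two exact limits are worth recording. In extreme narrowing the two-spin
NOE is +(γH/2γF) = +53.1 %. For slow tumbling the textbook limit
−γH/γF = −106.2 % is *not* attained exactly: every J(ω) decays as
1/(ω²τc), so σ/ρ tends to −(1−6(ωd/ωs)²)/(1+3(ωd/ωF)²+6(ωd/ωs)²) with
ωd = ωH−ωF, ωs = ωH+ωF — a field-independent ≈2.3 % correction giving
−103.9 % for the ¹H/¹⁹F pair. The tests assert the exact asymptote.

### Inversions

- NOE → τc: bisection on the monotonic branch, bracket fixed to
  [10 ps, 5 ns] (the NOE is a reliable dynamics probe for τc between
  ~0.1 and ~4 ns); out-of-range observations raise an error naming the
  attainable interval.
- R1 → τc: all crossings on [10 ps, 100 ns] are returned (0–4 for the
  double-humped curve); the caller selects the physical one. Crossings
  are located on a 200-points-per-decade log grid and refined by
  bisection (relative tolerance 1e−10, absolute 1e−16 s).
- R1 maxima: discrete detection on the evaluation grid (≥50 points per
  decade recommended; <10 triggers a warning), then bounded scalar
  minimisation on log10 τc to 1e−4 absolute in the exponent.

## Relaxation-series fitting

Inversion-recovery and echo/CPMG series use the three-parameter
monoexponential I(t) = A + B·e^(−Rt); NOE build-ups use
I(t) = I0 + (σ/ρ)(γH/γF)I0(1−e^(−ρt)), so the plateau is I0(1+NOEmax).
Levenberg–Marquardt least squares (lmfit), initial rate from a log-linear
regression on the deviation from the final point, ρ bounded positive.
Repeated time points are treated as independent observations and their
spread is also reported as an empirical noise estimate
(`DecaySeries.replicate_spread`). Constant series are rejected (the rate
is unidentifiable). Parameter uncertainties come from the fit covariance;
NOEmax uncertainty propagates σ/ρ in quadrature (the covariance between
σ and ρ is not tabulated for the published rates, so no cross term).

## Binding equilibria and CSP fitting

Stoichiometries: 1:1, and 1:2 (peptide:SH3) as two *sequential
macroscopic* dissociation constants P+L⇌PL (Kd1), PL+L⇌PL2 (Kd2) —
no statistical factors, no explicit cooperativity parameter.

Speciation: the 1:1 case uses the cancellation-safe closed form
2PL/(b+√(b²−4PL)), b = P+L+Kd, exact to machine precision; the 1:2 case
solves a monotone 1-D root problem for free SH3 by bracketed bisection.
An independent kinetic route (`solve_equilibrium_ode`) integrates the
mass-action equations (association constants normalised to 1, dissociation
= Kd) from the all-free state until all derivatives fall below 1e−10 of
the concentration scale; tests prove both routes agree to 1e−6 over
parameter grids. The algebraic route is used inside fits for speed.

Fast exchange: every signal is the population-weighted mean of its
states — peptide ¹⁹F signals weighted by the *peptide's* free/singly/
doubly-bound populations (the doubly bound state carries its own shift
parameter in the 1:2 model), protein amide signals by the *protein's*
bound fraction.

Joint objective: ¹⁹F shift-change residuals (Hz, converted from ppm with
the ¹⁹F spectrometer frequency when needed) weighted by 1/(1.6 Hz)², and
composite amide CSP residuals weighted by 1/(0.005 ppm)² — the first is
the back-calculation residual observed for this class of data, the second
a plumbing default, both configurable. The composite CSP is
√(ΔδN² + w·ΔδH²) with w = 5 by default, taken literally from the
published formula; the weight is configurable because conventions differ
(some scale the proton term by 25) and nothing downstream depends on its
absolute value. Per-residue amide pairs are composited then averaged per
titration point (nine-residue average convention). Reduced χ² is
computed on the noise-scaled residuals as Σr²/(N−NP). Fits whose
saturation range stays below 10 % or above 90 % warn that Kd is weakly
identified.

### Sensitivity to concentration errors

In the near-stoichiometric regime of these titrations (protein ≈ 3×Kd)
the fitted Kd responds to a systematic stock-concentration error with a
gain of ≈2–4: a 15 % peptide-stock deficit nearly doubles the apparent
Kd. This is a property of the experiment, not of the optimizer, and is
why the published Kd uncertainties (±30 µM on 96 µM) are much larger
than the shift-noise-only covariance. Recovery studies here therefore
report medians over many simulated titrations; with the 15 % biases
active the median stays inside the published bands while individual
realisations scatter by tens of percent. An optional global scale
nuisance parameter on the peptide stock is foreseen but off by default.

## Exchange kinetics

R2‡ = pf·R2f + pb·R2b + pf·pb·Δω²/kexc with kexc = kon([SH3]free+Kd),
valid for fast exchange; a validity flag is set when kexc < 5|Δω| (the
underlying condition is only kexc ≫ Δω; 5 is the chosen warning margin).
R2‡ is read off 1D spectra as π·FWHM of least-squares Lorentzian line
fits (sum of Lorentzians + constant baseline). The 8 Hz exponential
apodization applied during processing adds to the observed FWHM; the
synthetic generator adds the same constant, and subtracting it is left to
the caller (a constant π·8 s⁻¹ offset is absorbed into R2f/R2b and does
not affect kon). Peak pairs closer than FWHM/4 trigger a covariance
warning; a fitted amplitude within 3σ of zero is flagged as no detected
peak.

kon fitting: weighted least squares over (kon, R2f, R2b) per signal
(signals are fitted independently), multi-start over kon ∈ 10⁶–10¹⁰
M⁻¹s⁻¹ on a log grid, with Δω, Kd and the speciation fixed from the CSP
fit. The result is flagged unidentifiable when the exchange term never
reaches 10 % of R2‡.

## Conformational reporters

- cis/trans: Δδ(Cβ−Cγ) ≤ 5 ppm → trans; ≥ 8 ppm → cis; between →
  ambiguous (the literature criterion states only the trans side; the
  8 ppm cis bound is conservative so misclassification surfaces as
  "ambiguous" rather than silently). Cγ above 80 ppm marks a fluorinated
  Cγ (≈95 ppm) for which the indicator is not applicable.
- Hδ diastereotopic difference: signed Hδ2−Hδ3; assignment order taken
  as printed in the source table (first listed = Hδ2), which is not a
  stereo-assignment.
- Ring pucker: nearest reference (free (4R)/(4S)-FPro amino acids) by
  RMS over shared couplings (≥2 required); (4R) ↦ Cγ-exo, (4S) ↦
  Cγ-endo; ties reported together; the largest single residual is
  surfaced as the dominant deviation (e.g. the unexplained ≈5 Hz
  ³J(F,Hδ2) offset of peptide-bound (4S)-FPro, which the classifier
  flags but does not interpret).

## Synthetic data

What is emulated: the volumetric titration protocol (170 µL of 314 µM
protein; peptide stock 5.1 mM, the first four aliquots from a 2× diluted
stock; 12 points, ≈50 → ≈2100 µM peptide; protein diluted accordingly),
fast-exchange shifts, R2‡-derived line widths including the 8 Hz
broadening, monoexponential recoveries (1 ms–3 s, 20 points) and decays
(1–460 ms, 16 points), NOE build-ups (10 ms–2.6 s, 16 points), each
schedule containing one repeated point for empirical error estimation.
Noise: Gaussian 1.6 Hz on ¹⁹F shifts, 0.005 ppm on composite amide CSPs,
5 % relative on line widths, 1 % relative on series intensities —
defaults chosen to match the precision reported for this class of
measurements. Concentration error is a multiplicative bias drawn *once
per stock* (peptide and protein separately, σ = 15 %, clipped to
[0.5, 1.5]) because aliquots share their stock: per-point independent
errors would understate Kd uncertainty. Amide bound-state shifts are not
tabulated anywhere, so nine per-residue (ΔδN, ΔδH) pairs are drawn with
random signs and scaled so the average composite saturates at 0.1 ppm
(configurable); only Kd/Δν recovery, not absolute protein CSPs, is
therefore meaningful. Every generator returns a ground-truth record.

Fixed seeds make all generators bit-reproducible. What is *not*
emulated: FIDs and spectral processing, the non-binding minor species,
cis-conformer satellites, field drift. Passing recovery tests therefore
demonstrates estimator correctness and calibration under the stated
noise model, not robustness to artefacts absent from it.

## Problem sizes and numerical defaults

- τc curve grids: 100 points per decade over 10 ps–100 ns (401 points).
- Recovery studies: 100 simulated titrations per configuration in tests;
  300 per configuration in `scripts/acceptance.py`, where the
  Monte-Carlo error of the reported median Kd is ≈5–7 µM.
- Model-comparison and kinetics recovery studies run at measurement
  noise only (no stock bias): a systematic concentration bias is real
  model error that any more flexible stoichiometry will partially absorb,
  which is a statement about the experiment design rather than about the
  estimator being calibrated.
- Equilibrium tolerances: detailed balance 1e−9 (closed form is exact to
  machine precision), ODE steady state at derivative norm < 1e−10 of the
  concentration scale, 1:2 root bracket [0, SH3_total].

## Known limitations

- Absolute NOE(τc) and R1(τc) accuracy is limited by the pairwise
  approximation and the five-proton truncation; τc estimates are
  reliable as intervals and orderings, not third-digit values.
- No internal-motion order parameters; τc is an effective segmental
  correlation time.
- The fast-exchange R2‡ expression cannot describe signals with
  opposite-sign width trends (a signature of additional minor states);
  such behaviour surfaces as a poor per-signal fit, by design.
- No slow/intermediate-exchange line-shape analysis, no CPMG dispersion
  modelling, no vendor data formats, no 2D spectra.
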