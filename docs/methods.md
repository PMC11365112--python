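# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the open design decisions of `trfit`, in the order the analysis
chain runs. Units throughout: time in ns, wavelength in nm, wavenumber in
cm⁻¹, concentrations in µM (lipid, peptide) or M (quencher).

## Photophysical forward models

The intensity law is multi-exponential, F(t) = Σᵢ Aᵢ e^(−t/τᵢ), capped at
three components: Trp photophysics in peptides is conventionally summarized
at this order, and the empirical fits downstream never need more. The
measured observable is F convolved with the instrument response function
(IRF) plus a constant background, Poisson-counted per bin.

Polarized detection multiplies F by the anisotropy bracket
[1 + (3cos²θ − 1)·r(t)] with r(t) = B e^(−t/φ) + r∞ (single rotational mode
plus a residual — the minimal model that distinguishes "how fast it
tumbles" from "how constrained it stays"), and by the matching factor
k(θ)/3 = cos²θ + sin²θ/G. The printed special cases pin this form: 1 at
θ = 0, 1/G at θ = 90°, (2+G)/(3G) at the magic angle arccos(1/√3) ≈
54.7356°. Angles are taken in degrees as given; an input of 54.7° is used
as-is, no snapping to the exact magic angle. The one-photon limit
r₀ = B + r∞ ≤ 0.4 is enforced as a warning, not an error: fit excursions
above the physical limit must stay visible, not be masked by a validator.

Dipolar relaxation is parameterized as ν(t) = C e^(−t/t_relax) + ν∞, where
ν is the spectral center of gravity. C is only the *detectable* part of the
total shift (emission before the first resolvable delay is lost to the IRF),
which is why the zero-time intercept is never interpreted; ν∞ — the limiting
relaxation level — is the quantity carried forward. Wavenumbers are stored
in cm⁻¹ and reported as 10³ cm⁻¹ in summary tables. A fitted C < 0
(rising ν(t)) is flagged with a warning rather than rejected, since the fit
contract requires returning such fits for inspection.

Convolution is linear discrete convolution on the uniform grid with the IRF
pre-normalized to unit sum, zero-padded (no FFT wraparound — TCSPC tails
must not alias into t ≈ 0; the FFT-based implementation used in fitting
performs the same linear convolution).

## Synthetic-data generator

The generator emulates the study conditions of a TCSPC characterization of
Trp-substituted viscosin analogs (L1W, V4W, L5W, L7W) on POPC liposomes,
plus the NATA reference and the non-fluorogenic parent peptide.

* Per-peptide endpoints (Kd; r∞ and ν∞ in buffer and membrane) come from
  the published per-peptide fit table and are flagged `"table"` in each
  scenario's provenance map. Everything the study does not tabulate —
  lifetimes (0.6/1.8/4.5 ns with amplitudes 0.3/0.4/0.3), anisotropy
  amplitude and correlation times (B ≈ 0.12–0.15, φ 0.35 ns aqueous /
  1.5 ns membrane), relaxation amplitude C, band width, k_q — is an
  invented default, flagged `"invented"`, chosen once in `constants.py`.
  The deep-inserted analog overrides t_relax to 10 ns in the membrane with
  a 50% slow-relaxing fraction, emulating relaxation by water recruitment.
* The emission band is Gaussian in wavenumber with constant width
  (σ = 1400 cm⁻¹, FWHM ≈ 3.3×10³ cm⁻¹, Trp-like); the band model is not
  stated by the study, and a Gaussian makes the center-of-gravity and FWHM
  oracles analytic. Per-wavelength-channel intensities carry the ν²
  Jacobian of the nm → cm⁻¹ axis change, so the discrete center of gravity
  over a uniform wavelength grid is an unbiased estimator of the band
  center (residual error is grid truncation, a few cm⁻¹ when the grid
  spans ±3σ).
* The two-fraction ("heterogeneous") variant mixes two bands sharing C and
  ν∞ that differ only in t_relax — the minimal mechanism that produces the
  transient FWHM maximum used as a heterogeneity diagnostic.
* Counting noise is per-bin Poisson with the curve scaled to a requested
  peak expectation. Curves that belong to one acquisition (polarizer sets,
  quench titrations) share a single scale so their intensity ratios stay
  physical. Steady-state titration intensities instead get multiplicative
  Gaussian noise (CV-parameterized), reflecting analog detection.
* Default acquisition grid 0–50 ns; 4096 bins (dt ≈ 12 ps) as the
  general-purpose default, resolving the 0.4-ns calcein component; IRF
  Gaussian with 0.25 ns FWHM. Both are configurable everywhere.
* Every generator takes an integer seed and is bit-reproducible. Replicate
  seeds in the recovery studies derive from one master seed via
  `numpy.random.SeedSequence`.

Not modeled: pile-up, dead time, afterpulsing, dark counts,
wavelength-dependent detector sensitivity or IRF. Passing tests therefore
demonstrate correctness of the estimators under ideal counting statistics,
not robustness to instrument artifacts.

## Decay fitting

Objective: Neyman-weighted least squares, σ² = max(counts, 1), matching the
χ² convention of commercial TCSPC software; a Poisson-deviance (MLE) switch
exists but is not the default. The IRF temporal shift is a free parameter
bounded to ±5 bins (real TCSPC alignment drifts). The default fit window
runs from 0.5 ns before the IRF maximum to the end of the grid.

Amplitudes and background are linear given the lifetimes and shift, so they
are solved exactly at every objective evaluation — by NNLS in the default
non-negative mode — and the nonlinear optimizer sees only log-lifetimes and
the shift (variable projection). Without an explicit initialization, five
deterministic log-spaced lifetime sets are tried and the best kept; fits
are therefore reproducible. Components whose lifetimes agree within 5% are
merged (amplitude-weighted) in the reported model. Reduced χ² is reported
per fitted bin minus free parameters. Non-convergence flags the result
instead of raising.

**Signed amplitudes for spectral fits.** Per-wavelength decays on the red
edge of a relaxing band *rise* before they fall, which a sum of
non-negative exponentials cannot represent. The TRES chain therefore fits
with unconstrained amplitudes (`nonneg=False`); the linear subproblem is
solved by truncated SVD (relative cutoff 1e-8) because nearly degenerate
lifetime pairs otherwise produce huge cancelling amplitude pairs whose
extrapolation is numerically meaningless. The signed amplitudes travel on
`DecayFitResult.signed_amplitudes`; the `model` field keeps the
non-negative projection so the total-intensity invariants hold wherever a
`MultiExpModel` is consumed. With the constraint kept, the recovered
relaxation rate was biased ~9% low — a measured, not hypothetical, failure
mode.

## TRES

Spectra are built from the fitted (noise-free, IRF-free) reconstructed
decays, not raw counts — the same two-step empirical-fit-then-analyze
structure as the quenching analysis. The center of gravity is computed
directly on the wavelength grid exactly as the estimator is written
(intensity-weighted mean of 1/λ), with no resampling onto a uniform
wavenumber grid — that would introduce a Jacobian choice the estimator
itself does not make. It is invariant to intensity rescaling and to
zero-intensity padding.

FWHM is measured on the wavenumber axis with linear interpolation at the
half-maximum crossings and the outermost-crossing rule per flank (robust to
noisy shoulders). Spectra without an interior maximum, or with a flank that
never crosses half maximum, raise errors naming the flank; inside the
pipeline those delays yield NaN and are excluded.

Requested delays where the total reconstructed intensity has fallen below
1e-3 of its initial value are dropped before analysis: beyond roughly five
fluorescence lifetimes the histograms hold essentially no photons and the
tri-exponential tails are extrapolation. Without this cap the late-time
center-of-gravity drift inflated slow relaxation times by ~25%.

The relaxation fit is unweighted (the estimator produces no per-point
errors) and can be window-restricted, e.g. to the pre-rise interval when
ν(t) turns upward at late times in buffer. The heavy-water ratio
R_D/H = t_relax(D₂O)/t_relax(H₂O) carries a first-order propagated standard
error.

Per-wavelength fits warm-start from the neighboring wavelength's lifetimes
(band shape varies smoothly across the spectrum), with lifetime bounds
capped at a quarter of the grid span to keep tail components honest.

## Anisotropy

The global fit works in counts space by reconvolution — never by
constructing an r(t) curve first — so Poisson weighting stays valid; the
r(t) construction (I_VV − G·I_VH)/(I_VV + 2G·I_VH) is retained as an
independent oracle in the tests. φ and r∞ (and B) are single global values
across curves; lifetimes are fixed inputs; G is a measured instrument
property and never fitted. Shared amplitudes and the acquisition scale are
linear and solved by alternating closed forms inside each objective
evaluation.

All curves share **one** acquisition scale by default. This was a genuinely
open design point, resolved by experiment: giving each curve its own free
scale opens a near-degeneracy between the VH/VV scale ratio and r∞ — the
offset of r(t) can be absorbed into the ratio almost exactly — and noise
then sweeps the fitted r∞ across its whole physical range. The strict-ratio
default recovers the membrane endpoint r∞ = 0.080 to ±0.001 at 2×10⁴ peak
counts; per-curve scales remain available (`fit_scales=True`) for
diagnosing a mis-measured G. A fitted |B| < 0.005 flags φ as unconstrained.

## Quenching

Two steps, exactly mirroring the empirical procedure: tri-exponential
reconvolution per concentration, then a global one-parameter least-squares
fit of the reconstructed decays to F₀(t)·e^(−t·k_q·[Q]) with F₀ fixed to
the reconstructed zero-quencher decay. The step-2 objective is unweighted
on the window [0, 5·max τ] — reconstruction exists precisely to escape
per-photon weighting. k_q is bounded non-negative; an unconstrained optimum
below zero raises a data-quality warning and clamps to zero. Bulk [Q] is
used as given: the constant is *apparent*, and no local-concentration or
partitioning correction is applied.

## Leakage and partitioning

Leakage uses the two-lifetime decomposition with Q_stat = 1.2 (± 0.2)
default; the ±0.2 propagates into an (L_low, L, L_high) band by direct
evaluation (L is monotone in Q_stat). Raw leakage outside [0, 1] is clamped
with a logged warning — noise can push the ratio out of range, and silent
out-of-range fractions would corrupt summaries. Amplitudes are compared
across samples as fractions of the per-fit total, with the free-calcein
baseline B_F0 taken from a fitted no-peptide control — absolute TCSPC
amplitudes are acquisition-scaled and not comparable across samples. The
two-component calcein fit bounds the entrapped lifetime to [0.2, 0.8] ns
and the free lifetime to [3, 5] ns and refuses fits whose lifetimes
collapse within a factor 1.5.

The partition titration is fitted globally: for a trial K the
per-wavelength endpoint intensities are linear and solved exactly, leaving
a one-dimensional optimization over log K. Wavelengths are weighted
equally (the original procedure does not state otherwise). The NSSR
support-plane profile over Kd re-runs that exact endpoint re-optimization
at 81 log-spaced trial values spanning a factor 10 either side of the
optimum, with the interval at the 1.5 cutoff interpolated linearly; a side
that never crosses is reported at the grid bound with an open flag.

The partition-weighted decomposition fits the two endpoints of an
observable by (weighted) linear least squares with the bound fraction
computed from a *fixed* Kd — co-fitting Kd is degenerate with the
endpoints and is deliberately not the default.

## Validation studies and problem sizes

The recovery experiments in `trfit.experiments` (used by both the test
suite and `scripts/acceptance.py`) run on a 1024-bin, 0–50 ns grid
(dt ≈ 49 ps) with a 0.25-ns IRF — ample for lifetimes ≥ 0.5 ns and 20×
faster than the 4096-bin default; the calcein studies use a 2048-bin,
0–25 ns grid to resolve the 0.4-ns component. TRES studies use 16
wavelengths (294–390 nm), 2×10⁴ peak counts and 20 replicate seeds; the
relaxation-rate study recovers 1/t_relax = 0.10 ns⁻¹ to ~3% and the paired
H₂O/D₂O study the 1.53 ratio to ~1%.

## Known limitations

* Single-rotator anisotropy only; no associated (lifetime-linked)
  anisotropy, no wobble-in-cone geometric interpretation of r∞.
* No global lifetime linking across wavelengths; each wavelength is fitted
  independently before TRES assembly.
* The ν(0)/Δν estimate from nonpolar-solvent spectra is deliberately not
  computed: it is not applicable to solvent-exposed peptide Trp, and ν∞ is
  the reported relaxation endpoint instead.
* Static-quenching (sphere-of-action) and transient-diffusion terms are out
  of scope for the quenching model; kinetic (time-course) leakage is out of
  scope for the leakage model, which is an endpoint assay.
* The scattering-light correction that produces corrected titration
  intensities is upstream of this package; titration inputs are assumed
  already corrected.
* FWHM, unlike the center of gravity, is sensitive to whether spectra were
  peak-normalized against a steady-state reference; this package
  peak-normalizes per delay, so FWHM comparisons across datasets processed
  differently need care.
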