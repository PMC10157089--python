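# Methods

This note documents the models behind `lumibeads`, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and the
numerical decisions a maintainer should know about.

## Quantum-yield decomposition

For an antenna-sensitized Eu³⁺ emitter the overall quantum yield factorises as
Φ_tot = η_sens · Φ_int. The intrinsic quantum yield of the emitting ⁵D₀ level
is Φ_int = τ_obs/τ_r, and the radiative lifetime follows from the
magnetic-dipole-referenced emission spectrum:

    1/τ_r = A_MD,0 · n³ · (I_tot / I_MD),   A_MD,0 = 14.65 s⁻¹.

The ⁵D₀→⁷F₁ transition (~593 nm) is magnetic-dipole allowed; its vacuum
emission rate is insensitive to the ligand field, which is what makes the
corrected emission spectrum an internal standard. Assumptions: the emission is
fully captured by the ⁵D₀→⁷F₀…₄ bands (⁷F₅,₆ emission is negligible for these
complexes), the spectrum is instrument-corrected, and a single effective
refractive index describes the medium. `n` is always an explicit parameter:
for powderous KBr mixtures n = 1.5598 is appropriate, for polystyrene hosts
the caller should pass the polymer value — published radiative lifetimes do
not always state which was used.

Internally every efficiency is a fraction; percentages appear only in
reports, where Φ_int is rounded to integer percent and η_sens to two decimals
(the customary table precision). Φ_int > 1 (τ_obs > τ_r, physically
impossible, occasionally produced by inconsistent inputs) is **flagged, not
clamped**, so the evidence survives into the report. When a previously
reported η_sens is supplied for cross-checking, a mismatch beyond the second
decimal is likewise flagged rather than overwritten; the reference data for
the phenyl (btfa) complex triggers exactly this flag — its reported 0.86 is
not reproducible from its own lifetimes and quantum yield, which give
0.78/(662/717) = 0.845.

Lifetimes are microseconds everywhere at the interface; conversion to seconds
happens only inside the rate arithmetic.

## Band integration

Band areas are trapezoidal integrals on the native wavelength grid — exact
for piecewise-linear data and free of interpolation artifacts. Window edges
falling between grid points are handled by linear interpolation at the edge
(the clipped trapezoid), so areas are continuous in the window parameters.
Default windows (nm): F0 574–585, F1 585–603, F2 603–640, F3 640–672,
F4 672–720. These partition 574–720 nm around the line centres
579/593/614/654/701 nm; published analyses typically state peak positions but
not integration windows, so the partition is this package's choice and is
user-overridable (YAML config or explicit `BandWindow` sets). With ~2 nm line
widths the windows sit ≥ 2.5σ from every centre, so truncation biases the
I_tot/I_MD ratio by < 0.1%.

## Decay fitting

`MonoExponentialDecay` fits A·exp(−(t−t₀)/τ) + b by nonlinear least squares
(scipy `curve_fit`, bounded to A, τ > 0), initialised from a log-linear
regression on the baseline-subtracted tail. Defaults: the fit starts at the
signal maximum (skipping the excitation/gating artefact region), and a
constant baseline is fitted; both are overridable. Weighting is unweighted by
default — matching generic spectrometer software — with an optional
1/√y Poisson weighting for counting data. Degenerate inputs (constant signal,
fewer than 4 usable points) raise immediately; non-convergence raises an
error carrying the initial iterate. The model class is deliberately
single-exponential: published bead lifetimes are quoted as mono-exponential
fits, and multi-exponential model selection is out of scope.

## Bead stoichiometry

- Emitters per bead: N = w·ρ·(π/6)d³·N_A/M. Polystyrene density defaults to
  the handbook 1.05 g/cm³ (configurable); with the computed molar mass of
  Eu(ttfa)₃(TOPO)₂ (1588.8 g/mol from embedded IUPAC atomic masses, 5
  significant figures) a 100 nm bead at 1% wt carries ≈ 2.1×10³ emitters.
- Parking area: πd²/n_groups in Å² — exact surface conservation by
  construction.
- Protein capacity: sphere area over circular footprint, (2d_bead/d_protein)².
  A plain footprint division is used, with no hexagonal packing factor; it is
  the convention behind the usual "≈1,600 proteins on a 100 nm bead at 5 nm
  per protein" estimate, and adding a packing factor would silently change
  comparability.
- Detection limit: n_beads · molecules_per_bead / N_A. A mass↔count converter
  (`beads_from_mass`) is provided, but when a bead count is stated directly it
  should be preferred: per-well weight fractions and bead counts quoted
  together in the literature are not always mutually consistent (a weight
  fraction of 2.5×10⁻⁴ % in a 200 µl well implies ~10⁸ beads of 190 nm, not
  10³), so the count is treated as the authoritative input.
- Counts are returned as reals; rounding to significant figures belongs to
  the report layer.

## Lateral-flow densitometry

Lightness is the mean grayscale of the stored image in [0, 1]; RGB input is
collapsed with Rec. 601 luma weights. Whether a published "lightness" is CIE
L* or mean gray is often unstated; only relative measures within one imaging
session are meaningful, and all downstream quantities (peak heights, titration
signals) are ratios or positions, which are insensitive to that choice.

Line detection subtracts a rolling-median baseline (window = 5× the expected
line width, default 1 mm) — robust against the bright "debris" blobs left by
agglomerated beads — then finds peaks with a MAD-based robust noise estimate;
peaks below the requested SNR are discarded. Heights are baseline-subtracted
by construction, hence invariant to global offsets.

The biotin-blocking titration endpoint ("onset of signal permanence") is a
two-segment least-squares changepoint: a declining line for sub-saturating
doses and a constant plateau beyond, fitted over all split points; the
endpoint is the dose where the fitted segments intersect. A changepoint fit
was chosen over first-crossing rules because it uses all points and is
reproducible under noise. If the best-fitting plateau still deviates from
constancy by more than 3× the series' noise floor, the series has not reached
permanence and an error is raised instead of extrapolating. Dividing the
endpoint dose by the 4 biotin sites of tetrameric (Neutr)avidin converts it
to surface proteins per bead.

## Synthetic-data generators

Every generator is a pure function of its integer seed and ships its analytic
truth, so parameter-recovery tests need no laboratory data.

- **Spectra**: sums of Gaussian bands (default σ = 2 nm) at
  579/593/614/654/701 nm on a 570–720 nm, 0.2 nm grid. Default areas
  0.2/1.0/24.0/0.5/1.76 give I_tot/I_MD = 27.46 — a strongly hypersensitive,
  thienyl-diketonate-like emitter whose radiative lifetime in a KBr host
  (n = 1.5598) is 655 µs. Real f–f lines are not Gaussian (Stark-split,
  slightly asymmetric); an optional second F2 component at 617.5 nm emulates
  the thienyl Stark shoulder, but the exact line shape is immaterial to area
  ratios, which is all the pipeline consumes.
- **Decays**: exact exponentials plus additive Gaussian noise (fraction of
  peak) or Poisson counts. No instrument response function is convolved —
  real gated traces have a finite rise that the default fit-start-at-maximum
  rule skips.
- **Dilution series**: the primary inner-filter law I ∝ 1 − 10^(−A) with A
  linear in concentration. Deliberately minimal: no wavelength-dependent
  scattering term is modelled (the turbid-medium problem is acknowledged as
  quantitatively intractable), so only qualitative step-ratio behaviour —
  e.g. a tenfold dilution from A = 2 costing only a factor ≈ 2.7, the next
  ≈ 8.2, the dilute limit exactly 10 — is claimed or tested.
- **Strips**: uniform background + full-width Gaussian line bands + random
  circular debris blobs + pixel noise, 0.05 mm/pixel, 40×5 mm by default.
  Real strips add membrane texture, flow streaks and uneven illumination that
  are not emulated; passing tests demonstrate correct densitometry on clean
  geometry, not robustness to every field artefact.
- **Titrations**: signal0 · max(0, 1 − dose/endpoint) + plateau + Gaussian
  noise on a dose grid spanning twice the endpoint in 16 steps. The default
  endpoint (4 × 1000 sites) and 3% noise emulate a microscopy-read titration
  of ~1000 surface proteins per bead; real titrations add per-strip
  chromatography variability beyond simple additive noise.

Because the generators define these conditions, the recovery guarantees in
the test suite (decay τ median error < 2% at 2% noise over 100 seeds;
titration endpoint within one dose-grid step in ≥ 90% of 50 runs; line
position/height within 5%) are statements about the pipeline's estimators
under the stated noise models, not about any particular instrument.

## Problem sizes

Default sizes were chosen as realistic for the instruments emulated: 751-point
spectra (0.2 nm over 150 nm), 601-point decay traces (5 µs steps over 3 ms ≈
4.6 lifetimes), 800×100-pixel strip images, 17-point titrations. The test
suite and the acceptance script run these sizes directly.

## Known limitations

- No instrument-response deconvolution and no multi-exponential decay models.
- No Judd–Ofelt intensity parameters; the radiative rate comes solely from
  the magnetic-dipole reference.
- The inner-filter model ignores scattering; it is a qualitative generator,
  not a turbid-media simulator.
- Absolute radiometry is out of scope throughout: spectra, profiles and
  titration signals are treated as relative quantities.
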