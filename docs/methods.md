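# Methods

This note documents the modeling choices behind `sccosol`: what the data
look like, how the correlations are parameterized and fitted, how the
derived physical quantities are defined, what the synthetic-data generator
does and does not emulate, and the known limitations of agreement with the
printed source tables.

## Data model and packaged tables

A solubility record is one equilibrium measurement at a supercritical
condition: temperature T (K, > 304.1), pressure P (MPa, > 7.38), the CO₂
density ρ (kg/m³) at that condition, and the solute mole fraction y₂ (plus
the cosolvent mole fraction y₃ for ternary records). Datasets validate
record invariants on construction, reject duplicate (T, P) conditions, and
match conditions between datasets after rounding to the instrument
resolution (0.1 K, 0.1 MPa).

Two curated tables ship with the package, transcribed once from their
printed sources with the ×10⁻⁵/×10⁻⁴/×10⁻³ column scalings applied at
fixture-build time: 28 binary records (ketoconazole in SC-CO₂, a full
4-temperature × 7-pressure factorial over 308–338 K and 12–30 MPa) and 28
ternary records (the same grid with menthol as cosolvent, per-condition y₃).
Molecular weights are fixed at 531.0 (ketoconazole), 44.01 (CO₂) and 156.26
(menthol) g/mol. Ternary records reuse the binary densities at matching
conditions, i.e. the cosolvent's effect on the bulk density is neglected —
consistent with the ternary correlations being written in the pure-CO₂
density ρ₁.

Densities are treated as *inputs*: the packaged values come from a reference
equation-of-state evaluation printed alongside the measurements, and
`density_at` either looks them up on the measured grid or delegates to a
user-registered external property backend. A reference Helmholtz-energy
equation of state is deliberately not re-implemented here.

Known internal inconsistencies of the printed binary table, found during
transcription and pinned by tests: recomputing the g/L solubility column as
S = ρ·y₂·M₂/M₁ (dilute-mixture conversion, the convention that reproduces
the printed column) agrees within the columns' printed rounding for 25 of 28
rows, but three rows (318 K/15 MPa, 328 K/15 MPa, 338 K/18 MPa) disagree by
8–20 %, beyond any rounding explanation. The mole fractions, not the S
values, are taken as authoritative — at 318 K/15 MPa the printed ternary
enhancement factor corroborates the y₂ value — and all fitting is done on
y₂. The dilute conversion mode is the default; the exact mixture-molar-mass
mode is available and differs by the factor 1 + y₂(M₂−M₁)/M₁ (≈0.1 % at the
top of the measured range).

## Correlation registry

Twelve density-based correlations are registered: eight binary (Chrastil,
Kumar–Johnston, Bartle, MST, Sparks, Bian, Jouyban, Sodeifian) and four
ternary (MST-ternary, Sodeifian–Sajadian, González, Soltani–Mazloumi). Each
is stored with its response transform (ln c, ln y₂, T·ln(y₂P),
ln(y₂P/P_ref), T·ln(y₂P/P_ref)), its coefficient count Z, the number of
independent state variables Q (used by the adjusted correlation
coefficient: Chrastil-family ρ,T → Q = 2; pressure-explicit binary models →
Q = 3; ternary models add y₃), and the physical constants it needs.

Conventions:

- T in K, ρ in kg/m³, P in **bar** inside all formulas (the dominant
  convention for these correlations). The choice is configurable
  (`pressure_unit="MPa"`), and for every model whose feature span absorbs a
  constant — all except Sodeifian–Sajadian, which has no intercept degree of
  freedom — the unit constant is absorbed exactly by the coefficients, so
  predictions and AARD are invariant (property-tested at the least-squares
  level).
- Bartle-type reference constants: P_ref = 0.1 MPa (1 bar), ρ_ref = 700
  kg/m³; the ternary MST form uses the same P_ref.
- Sparks reduced variables: ρ_r = ρ/467.6, T_r = T/304.1 (CO₂ critical
  constants).
- Chrastil and Sparks predict a mass concentration; predictions are
  converted to y₂ so all models are scored on the same quantity.

Every registered formula is linear in its coefficients on its response
scale. This is exploited throughout: exact least-squares starting points,
identifiability of noiseless synthetic data, and a clean predict/response
consistency invariant (applying the response transform to a model's own
predictions reproduces the linear predictor to 10⁻¹⁰ relative).

At their fitted coefficients, eleven of the twelve models predict
monotonically increasing solubility along every measured isotherm, matching
the physical picture (density-driven solvation). The exception is the
six-parameter Jouyban form, whose pressure polynomial (P², PT, T/P) wiggles
non-monotonically at its optimum; it is also the worst-ranked binary model
here.

## Fitting

The default objective is the degrees-of-freedom AARD of Eq.-style form
100/(N−Z)·Σ|Δy/y|, minimized directly (it is the criterion the models are
ranked by). Alternatives: the plain 100/N mean (identical argmin — the two
differ by the exact factor N/(N−Z)), a log-space sum of squares
(`sse_log`), and `aard_s`, which scores against a dataset's independently
recorded g/L column where present.

The search is multi-start and fully seeded: start 0 polishes the
transformed-space least-squares solution with an adaptive Nelder–Mead
simplex (the AARD objective is non-smooth, so a derivative-free polisher is
used; xatol 10⁻¹⁰, fatol 10⁻¹², up to 4·10⁴ evaluations); the remaining
starts (default 8 total) run differential evolution (popsize 15, ≤300
generations, seeded per start) inside per-coefficient bounds, each polished
the same way. Default bounds are a data-driven box around the least-squares
start, ±(5|aᵢ| + 10) per coefficient: the relevant optimum is a deformation
of the least-squares optimum, and a box of that shape always contains it,
whereas fixed ±10⁵ boxes in six dimensions make population search
unreliable. Bounds are overridable. Coefficient vectors whose predictions
overflow or leave (0, 1) are mapped to a large finite penalty so the global
search can traverse them. Ties between starts go to the lowest start index;
identical seeds and inputs give bit-identical results (property-tested).

On the packaged binary data the global optimum of the 3-parameter models is
insensitive to the search settings: a wide-bounds differential evolution
sweep (popsize 40, 3000 generations) reproduces the packaged fit's Chrastil
optimum to 10⁻⁹.

## Goodness-of-fit statistics and reporting conventions

R² uses the uncentered-minus-correction total sum of squares
Σy² − (Σy)²/N (algebraically the centered sum of squares; the identity is
property-tested with a condition-aware tolerance, since the uncentered form
cancels catastrophically on near-constant vectors). The adjusted
correlation coefficient is the absolute-value square-root form
√|R² − Q(1−R²)/(N−Q−1)| used alongside these correlations in the solubility
literature; the textbook adjusted R² is available behind a flag.

Both AARD normalizations are computed on every fit, because the printed
reference tables for the shipped system are internally inconsistent about
which they used: refitting all twelve models shows the ternary reference
AARDs follow the N−Z form (all four models reproduced within 0.6 points,
two within 0.15) while the binary ones follow the plain mean (the
six-parameter Sodeifian value is reproduced to 0.04 points under the plain
form but misses by 1.8 under N−Z). Reports and the reproduction script
therefore quote binary AARDs as the plain mean and ternary AARDs in the N−Z
form.

Two binary reference values (Chrastil 10.01 %, Bartle 7.55 %) are *not*
reachable from the printed table under any convention: the verified global
minima are 12.06 % and 9.30 % (plain). The gap is attributable to rounding
in the printed data — the three hottest 12 MPa rows print y₂ with a single
significant digit (e.g. 0.02×10⁻⁵), contributing 30–77 % relative
deviations to any smooth model — and, decisively, the printed Chrastil
coefficients themselves score 12.6 % (plain) on the printed data. The
acceptance tests assert the printed tolerances faithfully and document
these two as expected failures of the source table, not of the fit.

## Thermodynamic analysis

- Enthalpies from temperature coefficients (R = 8.314 J mol⁻¹ K⁻¹,
  reported in kJ/mol to two decimals): ΔH_total = −R·a₁ from the Chrastil
  1/T coefficient (or −R·T_c·a₃ from the Sparks 1/T_r coefficient);
  ΔH_vap = −R·a₁ from the Bartle coefficient, whose density term separates
  out the solvation contribution; ΔH_sol = ΔH_total − ΔH_vap, negative
  (exothermic solvation) for this system.
- Cosolvent effect: e = y₂′(T, P, y₃)/y₂(T, P) at every shared condition
  (matched at 0.1 K/0.1 MPa; unmatched conditions are skipped with a
  warning). From the rounded printed mole fractions, e decreases strictly
  with pressure on three of the four isotherms and up to 27 MPa on the
  328 K isotherm; the printed enhancement column itself is inconsistent
  with the printed mole fractions at several conditions, so the recomputed
  ratio is authoritative here.
- Crossover window: for each adjacent-temperature isotherm pair, the
  difference of the piecewise-linear ln y₂ vs P curves is scanned for sign
  changes. The default report is the crossover *area* — the union of the
  grid segments bracketing the intersections — because an intersection
  interpolated between measured pressures is only localized to its segment;
  the tighter min/max of the interpolated intersection pressures is
  available as `method="interpolated"`, and a model-based variant evaluates
  a fitted correlation on a dense pressure grid (densities from the smooth
  interpolated surface) for smooth estimates. On the packaged data the
  area-style windows are 15–21 MPa (binary) and 12–15 MPa (ternary),
  consistent with the visually reported crossover regions of 19–20 and
  13–15 MPa; the interpolated binary point estimates (15.3–18.8 MPa) sit
  slightly below the visually reported region, which is expected when the
  region is read off smooth plotted curves rather than computed from
  piecewise-linear interpolation of a 3-MPa-spaced grid.

## Synthetic data

The generator mirrors the study design: a T × P factorial grid (default the
measured 4 × 7 grid), densities either from the measured table or from a
smooth surface (tensor monotone piecewise-cubic interpolation of the
measured grid — monotone-preserving along each axis, unlike an
unconstrained low-order polynomial), and mole fractions
y₂ = model(T, P, ρ)·exp(ε) with ε ~ N(0, cv²) i.i.d., seeded. The
multiplicative lognormal noise reflects the relative (not absolute)
character of the assay's uncertainty; the default cv = 0.05 matches the
stated upper bound of the replicate relative standard uncertainty, and at
that scale the lognormal mean bias (cv²/2 ≈ 0.1 %) is ignored. Ternary
grids default to the measured per-condition cosolvent loadings (a constant
y₃ would make the González ln y₃ feature collinear with the intercept and
destroy identifiability); a constant override is available for off-grid
grids.

Recovery experiments repeat generate + fit with per-replicate seeds
(seed + replicate index), reporting per-coefficient bias and RMSE and the
fitted-AARD distribution. Expected calibration: for an ideal fit under this
noise model the mean absolute relative deviation is cv·√(2/π), so at
cv = 0.05 the plain AARD should sit near 4 %; the recovery tests assert the
fitted median within a factor two of this closed form, and exact
coefficient recovery (≤10⁻³ relative) from noiseless data for every
registered model.

What the generator does not emulate: replicate-level measurement mechanics
(sampling-loop volume, spectrophotometric calibration), rounding of the
reported values (real printed tables quantize small mole fractions
aggressively — the dominant source of the reference-value gaps discussed
above), correlated errors within an isotherm, and any cosolvent effect on
the bulk density. Passing recovery tests therefore demonstrate that the
estimation machinery is unbiased and identifiable under the assumed noise
model, not that the correlations are adequate for any particular real
system.

## Uncertainty bookkeeping

Replicate statistics follow the standard n−1 form (standard deviation,
standard deviation of the mean, relative standard uncertainty sd/mean), and
expanded uncertainty combines sensitivity-weighted relative components in
quadrature, U = k·y·√(Σ(Pᵢ·u(xᵢ)/xᵢ)²), with coverage factor k = 2 by
default. The packaged tables carry their printed expanded-uncertainty
columns as data; they cannot be reconstructed from the printed standard
deviations alone (the additional components are not published), so no test
attempts to.

## Known limitations

- The fitted coefficients are reported without uncertainty estimates
  (no bootstrap/profile machinery), matching the scope of the correlation
  workflow.
- The crossover analysis assumes a shared pressure grid across isotherms.
- The parametric density surface is an interpolant of the measured grid and
  refuses extrapolation outside 308–338 K × 12–30 MPa.
- `density_at`'s external provider is a hook; no property library is
  bundled.
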