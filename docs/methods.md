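# Methods

## The problem

The octanol-water partition coefficient K_OW of a solute is the
organic/aqueous concentration ratio of its *neutral* species at the
limit of zero solute concentration (log K_OW = log P as c → 0). For
the roughly 95% of drug-like molecules that are weak acids or bases,
what a shake-flask experiment measures is the *distribution*
coefficient log D — the ratio of total (neutral + charged)
concentrations — and log D depends strongly on how ionized the solute
is, hence on concentration and pH. Naively extrapolating log D against
concentration to zero is ill-conditioned: log D drops sharply as the
solute dilutes and ionizes, and the extrapolated value depends on which
concentration window was measured. This is the dominant source of the
multi-log-unit scatter among published K_OW values for ionizable drugs,
which the packaged literature table documents (spreads up to 4.5 log
units for the same substance).

## Quantities and conversions

For a monoprotic acid AH (conjugate-acid pKa convention throughout, so
a base B uses the pKa of BH+ unchanged):

- ionized fraction at pH: `1/(1 + 10^(pKa-pH))` (acid),
  `1/(1 + 10^(pH-pKa))` (base);
- ionization correction: `log P = log D + log10(1 + 10^(pH-pKa))`
  (acid; exponent `pKa-pH` for a base). It assumes dilute species and a
  charged species confined to the aqueous phase, and is implemented
  with `log1p` so the correction is accurate when it is tiny;
- activity route: `K_OW = (v_aq/v_org)·(γ∞_neutral_aq/γ∞_neutral_org)`
  and `D_OW = (v_aq/v_org)·(γ∞_charged_aq/γ∞_charged_org)·
  (γ∞_H3O+_aq/γ∞_H3O+_org)`; D_OW contains no neutral-species term
  because the solute is fully ionized at infinite dilution. Molar
  volumes and activity coefficients are user inputs (strictly those of
  the mutually saturated phases; pure-solvent values are an
  approximation). Ideal and Debye-Hückel limiting-law
  (`log10 γ = -0.509 z² √I`, 25 °C, valid for I ≲ 0.01 mol/L) activity
  models are provided;
- the solubility ratio `log P_SLE = log10(c_sat_org/c_sat_aq)` from the
  pure binary solvents is computed but labelled diagnostic-only: the
  saturated binaries are not the ternary system and the value does not
  approximate K_OW.

## The two data-reduction methods

Both start from a series of measurements at several overall
concentrations `c_total` (total moles over total liquid volume — this
basis is fixed in the CSV schema).

**Method 1 (pH extrapolation).** Fit `log D = a·pH + b` and evaluate at
pH 7, the pH the aqueous phase attains at zero solute concentration;
the read-off is log D_OW, and the ionization correction at pH 7
converts it to log K_OW. The fit is linear in pH (not in hydronium
concentration). A span warning is raised when pH 7 is farther from the
nearest datum than the whole pH range of the data.

**Method 2 (concentration extrapolation).** Convert each log D to log P
with that measurement's own pH, fit `log P = a·c_total + b` (molar
abscissa, not log-scaled), and take the intercept as log K_OW.

For neutral solutes log D ≡ log P and the plain intercept of log P vs
c_total is the only route (`fit_logp_vs_conc`).

Fits are unweighted ordinary least squares; inverse-variance weights
(propagated from replicate standard deviations of the phase
concentrations) are applied only when every measurement carries them.
Reported standard errors are the OLS standard error of the fitted mean
response at the extrapolation point; pKa uncertainty is not propagated.
A fitted estimate requires at least 3 points with non-degenerate
abscissa (the classical design uses 4 concentrations).

### Where the methods are exact

`log D(pH) = log P − log10(1 + 10^(pH−pKa))` (acid). The second term is
linear in pH only where `10^(pH−pKa) ≫ 1`, i.e. where the solute is
nearly fully ionized — equivalently at high dilution, where the
measured pH approaches 7. In that regime both methods are exact and
agree. When the data sit near pH ≈ pKa (typical lab concentrations
around the OECD 0.01 mol/L ceiling for a pKa ≈ 4 acid), the fitted line
inherits the curvature of the correction term and Method 1 acquires a
bias of up to several tenths of a log unit; the Method 1/Method 2
disagreement reported by `reduce --method all` is precisely this
diagnostic. Recovery validation in the test suite therefore uses a
four-point grid at 10⁻⁹–10⁻⁶ mol/L (the asymptotic regime), while the
simulator's *default* scenario keeps the lab-style design
(1:3 organic:aqueous volumes, 25 °C, 10⁻³–10⁻² mol/L) that exhibits
the characteristic sharp log D drop.

## The forward simulator

The synthetic-data generator solves the full ternary speciation rather
than sampling from the fitted model, so it can serve as an independent
oracle for the reduction methods.

Unknowns and constraints (acid; the base case mirrors it):

- dissociation: `Ka = c_A⁻·c_H3O⁺ / c_AH` (concentration-based;
  activity corrections are ignored, a good approximation at the small
  species concentrations involved);
- autoprotolysis: `c_H3O⁺·c_OH⁻ = K_W = 10⁻¹⁴` (fixed, 25 °C);
- electroneutrality: `c_H3O⁺ = c_A⁻ + c_OH⁻` (acid, forces pH < 7);
  `c_BH⁺ + c_H3O⁺ = c_OH⁻` (base, forces pH > 7); no counterions;
- partitioning: `c_AH_org = P_N·c_AH_aq` with
  `log10 P_N = log10 P_N0 + s·c_total` (s = 0 by default), and
  optionally `c_A⁻_org = P_ion·c_A⁻_aq` (P_ion = 0 by default since
  ionization is strongly suppressed in octanol);
- mass balance over both phases at fixed volumes (no mutual
  octanol/water solubility, no volume of mixing; only the
  dilute-solute corner of the ternary system is modelled).

The residual is monotone in the aqueous charged-species concentration,
which is used (log-scaled) as the root variable; electroneutrality then
gives the hydronium concentration through the stable root of
`h − K_W/h = ±c_charged`. Parametrizing by the charged species rather
than by pH avoids the catastrophic cancellation in `h − K_W/h` near
neutrality that would otherwise dominate the mass balance for weakly
ionized solutes. Guaranteed bisection (equivalent to bracketing
hydronium over [10⁻¹⁴, 1] mol/L) is driven to floating-point
resolution; solutions satisfy mass balance and electroneutrality to
better than 10⁻⁹ relative (in practice ~10⁻¹⁵), and a failed bracket
raises a diagnostic error rather than clipping.

Measurement noise is multiplicative lognormal on both phase
concentrations (σ = 5%, the typical scatter of triplicate shake-flask
analyses) plus additive Gaussian pH noise (σ = 0.02, routine electrode
precision), driven by a seeded generator: equal seeds give bit-identical
series.

### What the generator does and does not emulate

It reproduces the structure of real shake-flask data — the sharp log D
drop toward dilution for ionizable solutes, near-linear log D vs pH in
the dilute regime, pH on the correct side of 7, the near-linear
concentration dependence of apparent log P — and the magnitude of
analytical noise. It does not model added salts or buffers (ionic
strength 0), ion pairing, zwitterions or polyprotic chemistry,
temperature dependence of pKa or K_W, or the full ternary phase
boundary. Passing recovery tests therefore demonstrate correctness of
the data-reduction arithmetic and its conditioning, not robustness to
matrix effects absent from the model.

## Literature screening

The curated tables transcribe published octanol/water values for 18
drugs (54 entries) and the four-drug method comparison. The headline
statistic is the per-substance spread (max − min of all published
values, pooling experimental, converted and calculated entries; an
experimental-only filter is available). Recomputed from the packaged
table, the mean spread is ≈1.1 log units for the four nonionizable
drugs and ≈1.9 for the fourteen ionizable ones — the qualitative
hundredfold-scatter contrast the screening is meant to expose. The
consistency check flags entries whose stated property (e.g. "log P")
differs from what the described experiment actually reported (e.g. a
log D at unstated pH), and, where pH and pKa allow, computes the
ionization-corrected companion value for cross-source comparison.

## Numerical and policy choices

- OECD concentration ceiling (0.01 mol/L per phase) is an advisory QC
  flag, inclusive at the boundary; it never excludes data.
- Mole-fraction conversion `x = v_n·c` errors above x = 1 and warns
  above x = 0.1 (dilute-regime formula).
- pKa values outside [2, 12] warn (the dilute speciation model is
  questionable for very strong acids/bases); outside (0, 14) they are
  rejected.
- Estimates are invariant under measurement reordering; series must
  share temperature within 1 °C.
- CSV round-trips preserve full float precision (`%.17g` on write,
  round-trip parsing on read); all outputs embed tool version, config
  hash and seed.

## Problem sizes used in validation

The acceptance computations sweep pKa ∈ {3, 4.18, 4.42, 7.92, 10} ×
log K_OW ∈ {0, 1.5, 3, 5} for both acids and bases (consistency and
conservation at four concentrations each; noise-free recovery on the
four-point dilute grid), run 200 noisy replicates for each of the three
ionizable reference drugs, and use 10-point series for the linearity
diagnostics. The whole suite completes in a few seconds on one CPU.
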