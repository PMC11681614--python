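# Methods

## Scope and conventions

The package analyses initial-rate, binding, pH-dependence, and
pre-steady-state data for a two-substrate dehydrogenase with an ordered
bi–bi mechanism in which the cofactor NAD⁺ (substrate A) binds before
the aldehyde SSA (substrate B), and the aldehyde additionally acts as a
partial non-competitive inhibitor of its own turnover.

Rates are stored internally as turnover per **tetramer** (s⁻¹):
μM·s⁻¹ inputs are divided by the tetramer concentration at ingestion,
so Vmax and kcat coincide after normalisation. The tetramer convention
is adopted because the functional species is the tetramer; steady-state
data alone cannot distinguish it from a per-active-site convention (a
factor of 4 in kcat), so reported kcat values are tied to this choice.
Temperature is metadata only — datasets collected at different
temperatures are fitted independently, with no Arrhenius correction.

## Rate laws

Five nested laws are evaluated exactly as written (no simplification),
vectorised over concentrations; negative concentrations raise. The
partial-inhibition law tends to b·Vmax as B → ∞ and reduces to the
plain bi–bi law as K_is → ∞. "Infinite" reductions in tests use
explicit large values (10¹²·scale) rather than symbolic limits; at that
scale the agreement with the reduced law is better than 10⁻⁹ relative.

Absorbance converts to NADH with ε₃₄₀ = 6.22 mM⁻¹ cm⁻¹ (μM = 1000·A /
(6.22·path)). The low-temperature fluorescence assay instead uses a
linear NADH calibration (`nadh_fluorescence_calibration`), whose inverse
maps intensity to concentration.

## Regimes and fitting

SSA ≤ 10 μM is subinhibitory, SSA ≥ 12 μM inhibitory, and the open
interval (10, 12) μM belongs to neither — the partition mirrors the
experimental concentration ranges verbatim rather than using a single
cut; both thresholds are configurable. The plain bi–bi law may only be
fitted to subinhibitory data and the inhibitory-regime model only to
inhibitory data; the partial-inhibition law takes the full range.

Global fits use bounded trust-region least squares (scipy
`least_squares`, tolerances 10⁻¹², ≤ 5000 evaluations per start) with
multistart initialisation: the heuristic start (Vmax₀ = 1.2·max rate,
Michaelis constants from half-max/median concentrations, K_is from the
rate-peak SSA, b₀ from the residual rate at top SSA) plus seeded
log-uniform perturbations of it (default 10 starts). Lowest RSS wins;
ties (ΔRSS < 10⁻⁹) go to the smaller parameter norm. All constants are
bounded positive; b ∈ [0, 1]. A parameter landing on a bound raises a
warning, as does the K_iA estimate from the full-range law, which is
intrinsically poorly determined there (the spectroscopic K_D is the
better estimate of cofactor dissociation).

Residuals are unweighted by default — mirroring common practice for
published initial-rate fits — with `weighting="relative"` available for
proportional error. The closed-loop recovery studies in
`ssadhkin.recovery` default to relative weighting because their
generator's noise *is* proportional, making that the matched
(maximum-likelihood) estimator; on the stated 5%-noise world the
unweighted fit leaves kcat coverage of its published range marginal
(~80%), while the matched fit is comfortably inside with identical
medians.

Standard errors come from the Jacobian covariance at the optimum
(σ² = RSS/(n−k)); residual-resampling bootstrap (default n = 500,
seeded) is the fallback for singular Jacobians and the cross-check
otherwise.

### Model comparison

Each fit reports AIC and BIC (Gaussian form, n·ln(RSS/n) + penalty).
`select_model` defaults to **BIC**: for nested models two parameters
apart, AIC's fixed +2-per-parameter penalty is exceeded by chance
improvement with probability P(χ²₂ > 4) ≈ 14%, so AIC cannot
distinguish the bi–bi and partial-inhibition generators at a ≥95%
correct rate even in principle; BIC's ln(n) penalty (≈ 4.4 per
parameter at the 84-point grid) holds the false-selection rate near 1%.

### Secondary replots

The graphical estimate inverts the bi–bi law: at fixed B the NAD⁺
saturation curve is Michaelis–Menten with
1/appVmax = 1/Vmax + (K_B/Vmax)(1/B) and
appKm/appVmax = K_A/Vmax + (K_iA·K_B/Vmax)(1/B), so two straight
replots against 1/B return all four constants. Estimates are flagged
lower-precision; non-positive replot slopes flag them unreliable.

### Product inhibition

One double-reciprocal line (1/v vs 1/[NAD⁺]) per NADH level. The
pattern is competitive when all pairwise intersection abscissae lie
within 15% (configurable) of zero relative to the sampled 1/[NAD⁺]
range ("converging on the y-axis"), uncompetitive when slopes are
parallel with distinct intercepts, noncompetitive for a common
intersection at negative abscissa, ambiguous otherwise (including
coincident lines). K_i is the negated x-intercept of the slope-vs-[NADH]
replot. The synthetic competitive generator scales **both** A-free
denominator terms (K_A·B and K_iA·K_B) by (1 + [NADH]/K_i) — NADH
binding free enzyme — which is the construction under which that
x-intercept equals −K_i exactly.

## pH-ionization models

K_D series are fitted on the linear scale (the titration equation is
linear in K_D); kcat and kcat/Kᵐ series on the log₁₀ scale (the models
are log equations). Two printed-form ambiguities are handled with
switches, defaulting to the standard interpretation:

- the bell denominator is the Cleland form 1 + 10^(pKa1−pH) +
  10^(pH−pKa2); the literal flattened rendering would add a second
  unity (plateau at log C − log 2) and is available as
  `bell_form="literal"`;
- the single-ionization titration is implemented as printed (value
  rising toward C with pH); the mirrored decreasing form is available
  as `direction="decreasing"` because the described trend of K_D with
  pH runs opposite to the printed equation.

Identifiability guards: a series whose dynamic range is below 1.25-fold
flags the pKa unidentifiable; a pKa outside the sampled pH span (or
with SE > 1 pH unit) flags the corresponding limb unsampled; a bell
optimum with pKa1 ≥ pKa2 is an error carrying the best iterate.

## Binding and bursts

Quenching is fractional, (F₀−F)/F₀ at the emission peak, so Qmax is
bounded by 1 and directly interpretable. The default isotherm assumes
free ≈ total ligand (enzyme at 0.1 μM, K_D in the μM range); the
depletion-aware quadratic form is available via `depletion=True` when
K_D approaches the site concentration. A fitted K_D above half the top
titration concentration is flagged poorly identified. Inner-filter
corrections are not applied.

Burst traces are fitted to offset + amplitude·(1 − e^(−λt)) +
v_ss·t after absorbance→NADH conversion; the offset absorbs any
constant baseline, making the amplitude invariant to absorbance
offsets. The phases separate only when λ·t_max ≥ 5; below that, or
when the amplitude is indistinguishable from zero, an unresolved-burst
warning is raised. The default instrument dead time is 1 ms
(generator-side truncation; fit-side cutoff configurable). Active-site
titration regresses amplitude on **monomer** (active-site)
concentration; slope 1 means all sites complete the first turnover.

## Synthetic data

Generators emulate the experimental designs: a 25 °C grid (SSA 1–200 μM
× NAD⁺ 1–1500 μM, 8 nM enzyme), a 14 °C grid (SSA 0.2–500 μM × NAD⁺
5–500 μM, 2 nM enzyme), the ten-point pH series 5.4–10, twelve
log-spaced ligand points over 0.1–100 μM, burst traces at 4–14 μM
sites, and NADH panels at 17–220 μM with SSA saturating at 10 μM. The
exact grid spacings within the published ranges are this package's
choice (log-ish spacing bracketing the Michaelis constants, plus levels
on both sides of the regime gap). Default noise is proportional
Gaussian, cv = 0.05 — typical initial-rate scatter — truncated at zero
unless blank-subtraction mode applies; binding noise is additive
(sd 0.015 on fractional quench, i.e., 3% of a 0.5 plateau). One named
RNG per dataset; the seed and generating truth are recorded in the
output metadata.

What a green recovery test establishes: the stated design + noise
identify the model parameters. What it does not: real assays add
systematic structure the generator omits — pipetting correlations,
enzyme-batch drift, inner-filter effects, instrument dead-time
artefacts beyond simple truncation — so recovery here is necessary, not
sufficient, for field performance.

## Recovery studies and reported medians

`ssadhkin.recovery` runs the closed-loop studies end to end: 100
replicate six-parameter fits of the 14 °C design (5% noise), 200
bell-model pH-profile fits (plateau C set to 41.5 μM⁻¹s⁻¹, the measured
kcat/Kᵐ scale — its value is immaterial to pKa recovery), and 200
binding fits. Per-replicate seeds derive deterministically from one
base seed (modular linear map, < 2³¹). Medians are reported as the
central estimates; they are robust to the occasional replicate landing
on a distorted noise realisation.

## Known limitations

- No progress-curve integration or microscopic rate constants: the
  steady-state laws are taken as the operational models.
- kcat carries the tetramer-vs-site factor-of-4 ambiguity noted above.
- The uncertainty convention on published values (SD vs SE vs CI) is
  unstated in the field sources this emulates; recovery criteria treat
  them as symmetric absolute ranges.
- Double-exponential bursts and fluorescence photophysics are out of
  scope.
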