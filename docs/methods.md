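# Methods

`promix` quantifies how much of *Prochlorococcus* growth is supported by
dissolved organic carbon (DOC) rather than photosynthesis, using four
linked analyses: a photo-physiological growth-profile model, an
individual-based water-column simulation, single-cell isotope uptake
rates, and an ecotype light-threshold time-series analysis. This note
documents the models, their assumptions, the parameters that matter, and
the choices made where the design was genuinely open.

## Photo-autotrophic growth profiles

### Carbon fixation

Chlorophyll-specific carbon fixation follows the Platt
photosynthesis–irradiance curve

    P_chl(I) = P_S^Chl (1 − e^(−α_Chl I / P_S^Chl)) e^(−β_Chl I / P_S^Chl)

with initial slope `α_Chl`, maximum `P_S^Chl` and photo-inhibition
`β_Chl` (`β_Chl = 0` disables inhibition). The carbon-specific,
daily-averaged fixation rate is the 24 h time average of
`(qChl/qC) · P_chl(I(t))`, where `I(t)` scales the observed noon PAR by
`max(0, cos θ_z)` from standard solar geometry (declination from the
day of year, hour angle over the day), normalized so the exact-noon
factor is 1. Hourly resolution (24 steps per day, evaluated at step
centres) is the default; the average spans the full 24 h including the
night, which is what makes the result a daily rate. Polar-night inputs
return an all-zero, flagged factor set rather than an error.

### Photo-acclimation and the growth fixed point

Chlorophyll:carbon ratios were not part of the observable inputs, so the
acclimation state is modelled. The package uses compact functional forms

    qChl/qC = (a0 + a1 μ) / (1 + a2 I)        mol Chl (mol C)⁻¹
    μ_max(I) = μ̂ I / (I + K_I)               day⁻¹

which preserve the two monotonicities that matter — more chlorophyll per
carbon at low light, and at high growth rate — and a light-saturating
allocation ceiling, while remaining swappable for a full
macromolecular-allocation model by users who have one. The light-limited
autotrophic rate solves the fixed point

    V_C^auto = min(P − K_R, μ_max(I)),    qChl/qC = f(V_C^auto, I)

by damped iteration (under-relaxation 0.5, absolute tolerance 10⁻⁶
day⁻¹, at most 200 iterations; non-convergence raises an error carrying
the last iterate). Rates are clamped at zero for limitation profiles;
the raw value (negative in the dark, where respiration exceeds
fixation) is retained for diagnosing respiration-driven decline.

Defaults: `K_R = 0.05` day⁻¹ (small positive maintenance respiration),
`a0 = 6·10⁻⁴`, `a1 = 2·10⁻⁴`, `a2 = 8·10⁻⁴`, `μ̂ = 0.8` day⁻¹,
`K_I = 20` µmol photons m⁻² s⁻¹. These are calibrated so that the
high-light (HL) parameterization yields surface growth of ~0.5 day⁻¹
over a 600 µmol photons m⁻² s⁻¹ noon profile and light-limited growth
vanishing near 1–2% of surface PAR. The two named P–I presets ("HL",
acclimation tag MIT9215 @70; "LL", MIT9211 @9) are editable YAML config
entries and stand in for laboratory-derived coefficients; the LL preset
carries stronger photo-inhibition and a higher initial slope, so it
out-grows HL at depth and under-performs at the surface. One caveat of
the contracted acclimation form: because `qChl/qC ∝ 1/(1 + a2 I)` decays
faster at very high irradiance than the P–I curve saturates, the solved
growth rate has a broad interior maximum near ~400 µmol photons m⁻² s⁻¹
even with `β_Chl = 0`; monotonicity in irradiance holds over the
light-limited range (≲300 µmol photons m⁻² s⁻¹).

### Nutrient limitation and the minimum law

Nitrogen and phosphorus uptake are quota-normalized Michaelis–Menten
rates `(V_max/Q) · S/(S + K)`; dissolved iron uptake is linear in cell
surface area, `k_Fe^SA · SA · Fe / Q_Fe`. Default constants are chosen
so that 10 nmol l⁻¹ surface DIN yields N-limited growth of ~0.4 day⁻¹;
they are config entries standing in for empirical allometric scalings.
Iron below a 0.03 nmol l⁻¹ detection limit (numeric or `<0.03` tokens in
input CSVs) is replaced by the limit and logged.

At each depth the modelled purely autotrophic rate is the minimum of the
light-, N-, P- and (when measured) Fe-limited rates; the limiting
resource is recorded. Ties break in the fixed order light, N, P, Fe
(first minimum wins); in practice ties occur only at exact zeros.
Observed growth rates are linearly interpolated across gaps in depth and
never extrapolated beyond the outermost observations. The inferred
heterotrophic rate is `μ_het = max(0, μ_obs − μ_auto)`.

Two onset depths are reported because they answer different questions:
the shallowest depth where `μ_het > 0` (any organic-carbon subsidy) and
the shallowest depth where `μ_het > μ_auto` (heterotrophy dominating
photosynthesis), both linearly interpolated. Production integrals are
trapezoidal in `rate · cell density · carbon quota` on the native depth
grid (carbon quota default 50 fg C cell⁻¹, configurable); heterotrophic
fractions are reported for the whole column and below the dominance
onset. The four-scenario envelope ({HL, LL} × {β as configured, β = 0})
is the per-depth min/max of `μ_auto`.

## Individual-based column model

### State and processes

Super-agents (each representing ~10⁹ real cells via a multiplicity
factor) carry a structural size `s` and C, N, P reserve quotas bounded
per unit size (`q_min·s ≤ q ≤ q_max·s`, so bounds scale through growth
and halve consistently at division). Structural stoichiometry is
Redfield (C:N:P = 106:16:1 on 4·10⁻¹⁵ mol C per unit size). Each
timestep, in fixed order:

1. light at each agent's depth (surface noon PAR × diel factor ×
   exponential attenuation);
2. photosynthesis on the Platt curve with a fixed chl:C ratio (the IBM
   deliberately omits the iterative acclimation model), filling the
   carbon reserve up to its cap — excess fixation is implicitly exuded;
   the quota-regulation factor below applies to DOC uptake only;
3. quota-regulated Michaelis–Menten DIN and PO₄ uptake depleting the
   local tracer (per-grid-cell demand is scaled down so no tracer goes
   negative);
4. DOC uptake

       V_DOC = V_DOC^max · clamp((q_C^max − q_C)/(q_C^max − q_C^min), 0, 1)
                         · DOC/(DOC + K_DOC^sat)
       f_PS  = P_S/(P_S + V_DOC)   (1 when both vanish)
       V_DOC = 0  when  f_PS < f_PS^min = 1%

   so mixotrophs remain obligate photosynthesizers: a cell that cannot
   photosynthesize at least 1% of its carbon intake takes no DOC (in
   particular, no DOC uptake at night). The gate is re-evaluated every
   step from instantaneous rates, with no hysteresis;
5. biosynthesis at `μ_syn^max · min(fill_C, fill_N, fill_P)` (linear
   reserve-fill factors), moving quota into structure, plus maintenance
   respiration `K_R` on structural carbon (reserve floor acts as
   dormancy — starving cells stop dividing but persist until grazed);
   the identity of the minimum fill factor is the limitation diagnostic;
6. division with probability `Δt · r_max · logistic((s − 2)/0.15)` —
   effectively when size approaches twice the post-division reference —
   halving size and quotas and spawning a twin agent;
7. quadratic grazing: per-cell mortality probability proportional to the
   local cell concentration; grazed N and P remineralize to DIN and PO₄
   in place and grazed carbon joins the DOC pool, closing the budgets;
8. vertical random walk consistent with a two-layer eddy-diffusivity
   profile (10⁻² m² s⁻¹ in a 50 m mixed layer, 10⁻⁵ m² s⁻¹ below, smooth
   5 m transition, with the deterministic `∂K/∂z` drift correction and
   reflecting boundaries);
9. implicit (backward-Euler, tridiagonal) tracer diffusion with no-flux
   boundaries; DIN/PO₄ restored toward their deep profiles below 150 m
   (10-day timescale); DOC restored toward its background profile.

Random draws are consumed in a fixed documented order (division,
grazing, random-walk) from a single per-member generator, so identical
configuration and seed reproduce the trajectory bit-for-bit. When
divisions push the super-agent count past 3× its initial value,
depth-adjacent pairs are merged with multiplicity-weighted averaging,
which conserves cell, N and P totals exactly.

With restoring disabled the column is closed: total N and P (tracer +
agent quotas + structural biomass) are conserved to better than 10⁻⁹
relative per step and 10⁻⁶ over a full run, and this is asserted in
tests. Population extinction flags the result rather than raising.

### The DOC-like substrate

The DOC pool is the model's intentionally least-constrained component:
it stands for the labile fraction of a chemically complex mixture whose
nutritional value cannot be measured directly. It is represented as a
tracer restored (0.7-day timescale) toward a surface-anchored
exponential background — 4.6 mmol C m⁻³ at the surface, e-folding over
55 m — reflecting that labile DOC is produced by the photosynthetic
community above and turns over quickly. The restoring flux, not the
instantaneous concentration, is what limits deep mixotrophic growth, so
the background profile and timescale jointly set how deep DOC-supported
division extends; they are the right knobs for sensitivity studies. A
uniform background (settable via `doc_depth_scale → ∞`) makes
DOC-supported growth nearly depth-independent down to the 1% gate, which
is qualitatively wrong for the structure this model is meant to capture.

### Desk-scale configuration and calibration

The published structure this model reproduces came from a 2-D turbulent
simulator; this package replaces the flow with the 1-D column above,
since the quantities of interest are horizontally averaged profiles. The
default configuration is desk-scale: 0–200 m on a 2 m grid, 10-minute
timestep, 120 simulated days with the final 30 days averaged, ~2000
super-agents and 5-member ensembles (distinct seeds derived from the
config seed), running in roughly three minutes for a paired
autotroph/mixotroph comparison on one core. The cluster-scale setting
(1-minute timestep, 360 days, 10 members) is a configuration choice
away.

Because the source simulation's parameter table is not reproduced here,
the IBM defaults were calibrated against its published summary
quantities: mixed-layer division ~0.3 day⁻¹ in both scenarios, autotroph
division ceasing near 90 m, mixotroph division ~0.2 day⁻¹ at 125 m, DOC
contributing ~12% of vertically integrated production and ~43% below the
nutrient-to-carbon limitation transition, and a nutricline ~20 m deeper
in the mixotroph scenario. The calibration lives in a handful of
parameters: the fixed chl:C (2.4·10⁻³) and P–I initial slope (10⁻³,
light-saturation ~30 µmol photons m⁻² s⁻¹) set where photosynthesis
saturates and fails; maintenance respiration (0.3 day⁻¹) sharpens the
autotroph light floor; `V_DOC^max` (3.5·10⁻¹⁹ mol C cell⁻¹ s⁻¹ per unit
size) bounds mixotrophic supplementation; the grazing coefficient
(2.2·10⁻¹² m³ cell⁻¹ day⁻¹) with the initial mixed-layer stock sets the
recycling equilibrium there. The reported "contribution of DOC uptake"
is the occupancy-weighted time mean of `(1 − f_PS)` computed from the
gross photosynthesis rate and the realized (gated, tracer-limited) DOC
uptake rate — zero at night when both rates vanish — and integrals over
depth weight it by total carbon acquisition.

### Output diagnostics

Profiles are binned at 5 m over the recording window: cell density
(occupancy per bin), division rate (logged division events per
cell-day; empty bins are missing, not zero — and in a mortality-free
test run the logged rate matches `ln(N₁/N₀)/Δt`), tracer means, DOC
contribution, and the carbon-limited occupancy fraction whose ½-crossing
defines the limitation transition depth. The nutricline depth is the
linearly interpolated threshold crossing of a nutrient profile (default
threshold: half the deep phosphate value). The autotroph viability
depth is the bottom edge of the contiguous actively-dividing region from
the surface (cutoff 0.02 day⁻¹), which is robust to isolated deep bins
with rare division events. Ensemble bands are per-depth min/max across
members.

## Single-cell isotope rates

For a cell incubated with ¹³C-bicarbonate and ¹⁵N-ammonium for time `t`
(days), the biomass-specific uptake rate is the linear isotope-dilution
estimate `μ = ((x − x_nat)/(x_src − x_nat))/t` applied separately to C
and N; small negative estimates are clamped to zero, and enrichments
outside `[x_nat, x_src]` are flagged, not dropped. Population-
representative rates are medians, robust to the long right tails of
single-cell distributions. The heterotrophic fraction is
`1 − μ_C/μ_N` on the median rates: the share of the carbon demand
implied by the N-based growth rate that photosynthesis does not supply.

Doubling time is reported in two conventions, with the reciprocal
`1/μ_N` as the headline: it is the convention under which a rate of
0.16 day⁻¹ reads as ~6 days (6.25), consistent with equating "replicate
every 4–7 days" with 0.14–0.25 day⁻¹; `ln 2/μ_N` is also emitted.

## Ecotype light thresholds

Laboratory light thresholds for active growth (defaults: 10 µmol photons
m⁻² s⁻¹ for HL-adapted strains, 2.8 for LL-adapted) are interpreted as
instantaneous noon-scaled values applied to exponentially attenuated
noon PAR, giving the closed-form photic depth `ln(I₀/I_th)/K_d` (zero
when the surface is already below threshold). The threshold source
experiments used integrated illumination over a 14 h:10 h cycle and the
conversion is not uniquely defined; applying the thresholds to
daily-mean PAR instead simply rescales `I₀` and is available to callers.

Below-photic cell fractions are column-trapezoid integrals with a linear
split of the straddling layer. Time-series averages are taken over
stratified dates only — mixed layer shallower than the photic depth —
because deeper mixing can carry below-photic cells back into the light;
dates are weighted equally (not by interval length, a documented
choice). The mean and the maximum are both reported.

## Synthetic data

Every fixture is a pure function of a parameter spec and a seed, with
ground truth returned alongside (and written as a sidecar JSON by the
CLI) so tests recover rather than re-derive it. The generators emulate:
exponentially attenuated PAR (600 µmol photons m⁻² s⁻¹ noon surface,
K_d = 0.045 m⁻¹); sigmoidal nutriclines near 110 m; observed growth
declining from ~0.5 day⁻¹ at the surface to a plateau ≥0.1 day⁻¹ down to
150 m, sampled sparsely with seeded gaps; a sinusoidal mixed-layer cycle
(30–180 m) crossing the photic depth twice a year; Gaussian ecotype
depth niches ordered HL above LL with HL clades numerically dominant
(analytic truncated-Gaussian integrals provide the ground-truth
below-photic fractions); and single-cell enrichments generated by
inverting the isotope-dilution formula at true rates
(μ_C = 0.024, μ_N = 0.16 day⁻¹, 3.5 h incubation) with median-1
log-normal noise.

What the generators do not emulate: real HOT/BATS/JGOFS covariance
structure, measurement error in nutrients or PAR, seasonal ecotype
succession, or instrument-level isotope artefacts. Tests passing on
these fixtures therefore demonstrate that the algorithms are correct and
internally consistent under realistic magnitudes — not that the field
estimates would be recovered from real observational noise. Pipelines
accept real profiles in the documented CSV layouts when users have them.

## Numerical choices and degenerate inputs

- Growth fixed point: under-relaxation 0.5, |Δμ| < 10⁻⁶ day⁻¹, ≤200
  iterations; acclimation irradiance floored at 10⁻⁶ µmol photons m⁻²
  s⁻¹ in dark water.
- IBM timestep must satisfy the uptake-depletion stability constraint
  (≤10 min at the default grid); tracer diffusion is implicit and
  unconditionally stable; per-grid-cell uptake is capped at 99% of the
  standing tracer per step.
- Interpolations (observed growth, onset depths, nutricline, photic
  splits) are linear; integrals are trapezoidal on native grids.
- Degenerate inputs have defined behaviour: polar night → flagged zero
  factors; empty profiles, missing observations, zero-cell columns,
  empty stratified masks → errors or NaN ("missing"), never silent
  zeros; extinct IBM populations → flagged results.

## Known limitations

- The contracted acclimation and allocation forms are calibrated
  stand-ins; absolute growth magnitudes inherit their uncertainty even
  though the limitation structure is robust.
- The 1-D column cannot represent lateral stirring or submesoscale
  light-history effects; ensemble spread only reflects demographic and
  random-walk stochasticity.
- The DOC pool is a single idealized substrate; its background profile
  and turnover are the model's least-constrained inputs, chosen to
  reproduce the published summary structure.
- Grazers are implicit (a quadratic closure), so no predator dynamics,
  diel vertical migration, or selective grazing.
- Surface DOC exudation is not modelled, so surface heterotrophic
  inferences from profile comparisons are lower bounds.
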