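# Methods

## The model chain

`thermacclim` analyses leaf gas-exchange measurements from a
regression-based warming × elevated-CO2 field experiment: five warming
offsets (+0, +2.25, +4.5, +6.75, +9 °C above ambient) crossed with two
atmospheric CO2 levels (ambient ≈400 ppm and elevated ≈800 ppm) across
10 plots, with 1–4 trees per plot of two boreal conifers (tamarack, a
deciduous conifer, and black spruce, an evergreen) measured in two
monthly campaigns. Each tree contributes A–Ci response curves (net
assimilation *A* versus intercellular CO2 *Ci*) at five leaf
temperatures (15, 25, 32.5, 40, 45 °C), each stepping chamber CO2
through the 11-step sequence 400, 300, 200, 50, 400, 500, 600, 800,
1200, 1600, 2000 µmol mol⁻¹.

### Forward model (`fvcb`)

Steady-state C3 photosynthesis follows the Farquhar–von
Caemmerer–Berry model: *A* = min(*A*c, *A*j, *A*TPU) with

- *A*c = *V*cmax·(*C*i − Γ\*)/(*C*i + *K*c(1 + O/*K*o)) − *R*day
  (Rubisco-limited),
- *A*j = (*J*max/4)·(*C*i − Γ\*)/(*C*i + 2Γ\*) − *R*day
  (RuBP-regeneration-limited at saturating light), and
- *A*TPU = 3·TPU (triose-phosphate-use-limited; printed as a gross
  rate, so no *R*day subtraction by default — `tpu_net=True` subtracts
  it for users who want all three states on a net basis).

Γ\*, *K*c and *K*o take the standard Bernacchi in-vivo values at 25 °C
(42.75 µmol mol⁻¹, 404.9 µmol mol⁻¹, 278.4 mmol mol⁻¹) with simple
Arrhenius scalings (activation energies 37 830, 79 430, 36 380
J mol⁻¹) and intercellular O2 = 210 mmol mol⁻¹; all overridable via
`KineticConstants`. Capacities are "apparent" (Ci-based); mesophyll
conductance is out of scope.

Temperature responses use two functions. Biochemical capacities follow
the peaked (modified) Arrhenius function

f(*T*k) = *k*opt · *H*d·exp[*E*a(*T*k−*T*opt)/(*T*k·R·*T*opt)] /
(*H*d − *E*a(1 − exp[*H*d(*T*k−*T*opt)/(*T*k·R·*T*opt)]))

evaluated in Kelvin with *E*a, *H*d carried in kJ mol⁻¹ (converted to
J internally; R = 8.314 J mol⁻¹ K⁻¹) and reported optima converted to
°C at the boundary. Net photosynthesis near its optimum follows the
quadratic *A*(T) = *A*opt − *b*·(T − *T*optA)², where *b*
(µmol m⁻² s⁻¹ °C⁻²) is the curvature: larger *b* means a narrower,
more temperature-sensitive response.

### A–Ci fitting (`aci`)

The bilinear method exploits the linearity of both limitation states
in transformed Ci. For every contiguous split of the Ci-sorted points
with at least 3 points per side: the low-Ci segment is regressed on
x₁ = (Ci−Γ\*)/(Ci+*K*m) giving *V*cmax (slope) and *R*day (negative
intercept, clamped at 0 with a warning when nonphysical); holding that
*R*day, the high-Ci segment is regressed through the origin on
x₂ = (Ci−Γ\*)/(Ci+2Γ\*) giving *J*max/4. The split minimizing the SSE
of the reconstructed piecewise model wins; the transition Ci is the
midpoint of the bounding points. TPU is reported only when the two
highest-Ci steps fall more than one standard error below the Aj line.

One numerical convention matters at the 50-ppm step (Ci = 35
µmol mol⁻¹, below Γ\* ≈ 43): the extrapolated RuBP-regeneration
hyperbola dips beneath the Rubisco branch there. That inversion is an
artifact of extrapolating the Aj hyperbola below the compensation
point, not a limitation change, so both the synthetic generator and
the fitter's SSE reconstruction use the two-segment convention
(Rubisco limitation below Γ\*). Without it, noiseless round-trips are
biased ~3 % by that single point.

The growth-CO2 net photosynthesis of a curve is the mean measured *A*
over all steps within 25 ppm of the tree's growth Ca (400 or 800 ppm;
the protocol visits 400 twice and both visits are averaged).

### Thermal fitting (`thermal`)

Per tree × month: the quadratic is fitted to the five growth-CO2 *A*
values by exact polynomial least squares (monomial basis, then
*b* = −c₂, *T*optA = −c₁/2c₂, *A*opt = c₀ − c₁²/4c₂); a non-negative
c₂ means no interior optimum and the tree is flagged and excluded
downstream. *V*cmax(T) and *J*max(T) series are fitted with the peaked
Arrhenius function with *H*d fixed at 200 kJ mol⁻¹ (for both
capacities) to avoid over-parameterization; *k*opt is profiled out
linearly, leaving a 2-parameter problem multistarted from
*T*opt ∈ {25, 30, 35} °C × *E*a ∈ {40, 60} kJ mol⁻¹ — the peaked
function has local minima on 5-point series.

Derived quantities: *A*g = *A*(mean growth temperature) via the
quadratic fit, where the growth temperature is the mean daytime
(09:00–15:00, half-open) air temperature over the 10 full days
preceding the campaign's measurement date; ΔMeanTg = mean growth
temperature − *T*optA (positive when the air is warmer than the
optimum); and the A70 decomposition — *A* recomputed at a fixed
Ci/Ca of 0.7 (Ci = 280/560 ppm for ambient/elevated growth CO2) from
the per-temperature fitted *V*cmax, *J*max, *R*day and TPU, with the
quadratic refitted to the A70 series (`arrhenius_smoothed` switches
the capacities to the Arrhenius fits instead of the raw
per-temperature estimates).

### Treatment inference (`inference`)

All tests run on plot means (arithmetic mean over the 1–4 trees per
plot × month), per species. Warming enters as a continuous covariate;
CO2 as a two-level factor; the campaign month is the candidate random
intercept. Model selection is two-step: (1) random structure (none vs
month intercept) by REML AIC under the richest fixed structure;
(2) fixed structure (main effects vs warming × CO2 interaction) by ML
AIC under the chosen random structure; AICc = AIC + 2k(k+1)/(n−k−1)
is reported alongside because the design is small; ties go to the
simpler model. With only two month levels the random variance is
profiled on the boundary-truncated scale — when it collapses to zero
the candidate is evaluated as the OLS model with the boundary variance
parameter still counted in k, and the closed-form restricted
likelihood of OLS uses the same convention as the mixed model so REML
AICs are comparable. Directional hypotheses (warming/CO2 increase
ToptA, Aopt, Ag) use one-sided t probabilities; other responses are
two-sided; no multiple-testing correction is applied across responses
(flagged in output metadata). ΔMeanTg is additionally tested by a
two-factor fixed-effects ANOVA (warming as a 5-level factor × CO2)
with type-II sums of squares so unbalanced cells degrade gracefully.

## The synthetic generator (`synthetic`)

The generator emulates the statistical structure the analysis assumes,
so every stage is testable with known truth. Design: 10 plots
(5 warming × 2 CO2), configurable trees/plot (default 3) and both
campaign months. Climate: half-hourly air temperature as an ambient
diurnal cosine (daily mean 19 °C — chosen so the 4:00–20:30 daytime
mean matches the ≈19 °C June value reported for the emulated site —
half-range 6 °C peaking at 15:00) plus weather noise shared across
plots (one site) plus each plot's exact warming offset; sharing the
weather term makes pairwise daytime-mean differences equal the
offsets exactly.

Per-tree truths follow linear acclimation relations (per species:
intercept, slope per °C warming, CO2 offset, optional CO2-specific
slope, multiplicative CO2 factor for *b*) plus noise: additive
plot-level (σ = 0.5 °C) and tree-level (σ = 0.3 °C) Gaussian noise on
thermal optima, multiplicative lognormal noise (CV = 0.10 tree-level,
half that plot-level) on *A*opt and *b*, and a +0.5 °C August shift on
optima so random-structure selection is non-degenerate. The default
relations embed: ToptA = 23.2 + 0.26·W (+3 °C under eCO2) for
tamarack and 23.3 + 0.35·W for spruce; ToptV/ToptJ intercepts derived
from the optimum–optimum relations at W = 0; Aopt = 7.9 + 0.26·W
(+3 offset) for tamarack and a CO2 × warming interaction
(slopes 0.10/0.54) for spruce; *b* = 0.020 with an 86 % elevation
under eCO2 in tamarack. The *b* baseline was set so the quadratic
truth keeps *A* positive at the coldest measurement temperature for
every treatment combination — a narrower (larger-*b*) truth would
imply negative assimilation at 15 °C for the warmest elevated-CO2
trees and force unphysical activation energies in the calibration
below.

Curves are then generated mechanistically: *V*cmax(T), *J*max(T) from
the peaked Arrhenius truth, *R*day scaling from 25 °C with Q10 = 2,
a constant Ci/Ca of 0.7 (so stomatal behaviour is
temperature-invariant and the thermal optimum is under purely
biochemical control — which is also why the fitted A70 optimum must
agree with the growth-CO2 optimum, a property the tests check), and
additive Gaussian noise σ_A = 0.5 µmol m⁻² s⁻¹ per point. TPU
limitation is off by default and enabled via config to exercise the
ATPU branch.

Because ToptA is an emergent property of the biochemistry, the
generator solves an inverse problem per tree: find Arrhenius
parameters whose noiseless A(T) at growth Ci, fitted with the same
five-temperature quadratic the analysis uses, lands exactly on the
tree's (ToptA, Aopt, b) truth. Three knobs are used — a common shift
of the Vcmax/Jmax optima, a common scale on their activation energies
(bounded so Ea < Hd), and the 25 °C respiratory fraction
Rday25/Vcmax25 (bounded to 0.5–15 %; higher respiration steepens the
supra-optimal decline and widens the reachable curvature range). The
solve is a batched damped-Newton iteration on all trees at once
(grid-presolved optimum shift, backtracking line search), polished by
a batched Levenberg–Marquardt pass over all three knobs (the min(Ac,
Aj) surface has branch-switch kinks), with a scalar trust-region
fallback for rare stragglers; a final closed-form rescale of Vcmax,
Jmax and Rday jointly (which scales A(T) exactly linearly) pins Aopt
and b. Residuals are driven below 1e-8, so noiseless round-trips
through the analysis recover the configured truths to numerical
precision. One consequence: the generated ToptV/ToptJ values absorb
the calibration shift and do not themselves follow their configured
warming relations tightly; the biochemical-optimum recovery analyses
therefore generate Vcmax/Jmax series (or paired plot-level optima)
directly from the peaked Arrhenius function, which is also how those
quantities enter the fitting stage they test.

### What the generator does not emulate

Real stomatal behaviour varies with temperature and VPD (the constant
Ci/Ca makes the A70 check an internal-consistency property, not a test
of stomatal decoupling on real data); mesophyll conductance is absent;
weather is white noise rather than autocorrelated synoptic variation;
instrument drift, leaf-area error and curve-quality filtering are not
simulated; and the quadratic is the exact functional form of the truth
near the optimum, so passing recovery says nothing about
quadratic-vs-peaked model misfit on real temperature-response data.

## Validation strategy and problem sizes

The study-level quantities (warming slopes, CO2 shifts, curvature
ratios, optimum–optimum slopes) are validated by parameter recovery:
200 seeded replicates of the full chain (generate → growth-CO2
extraction → quadratic fits → plot means → mixed regression), with
the mean recovered estimate compared to the embedded truth (±0.05 on
slopes, ±0.5 °C on intercept shifts, ±10 percentage points on the
curvature ratio). Each replicate is a 10-plot, 3-trees/plot, 2-month
experiment — 60 tree-months, 300 curves, 3 300 points. The
biochemical-optimum protocols use 30 Jmax series per replicate (ToptJ
slope through the Arrhenius stage) and 20 plot-equivalents × 2 months
of paired optima (relationship slopes, σ = 0.7 °C on the response).
Deterministic layers are validated against independent oracles:
literal transcriptions of the five forward equations (1e-10 relative),
exhaustive partition enumeration for the bilinear fitter, closed-form
polynomial least squares for the quadratic, a 0.1-resolution profile
grid for the peaked Arrhenius fit, and discrete/analytic window
averages for the climate summaries.

## Numerical choices and limitations

- Minimum bilinear segment size 3; growth-Ca matching tolerance
  25 ppm; both configurable.
- Jmax is identifiable only while the Ac/Aj crossover stays below the
  1200-ppm step; above Jmax/Vcmax ≈ 2.4 fewer than three purely
  Aj-limited steps remain and Jmax recovery degrades to ~1 % even
  without noise — a limit of the measurement protocol, not the fitter.
- Curves that cannot be fitted at 45 °C (the noisiest temperature) are
  dropped with a warning rather than aborting the tree; failures at
  other temperatures propagate.
- The quadratic fit flags optima outside the measured range ±10 °C;
  the Arrhenius fit flags optima outside 5–50 °C.
- Uncertainty is not propagated from the A–Ci fits into the thermal
  optima (point estimates throughout, matching the plot-mean analysis
  design); seasonal Ag applies the nearest campaign's quadratic fit.
- All generator outputs are pure functions of (config, seed); the
  pipeline manifest records the config hash and seed for bit-identical
  reruns.
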