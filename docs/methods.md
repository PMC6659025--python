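# Methods

## Scope and intent

`fishthermal` implements a deliberately minimalist ecophysiological model:
two coupled budgets (energy and oxygen), one behavioural decision (the
activity fraction τ), and one life-history schedule (a logistic maturation
reaction norm). Temperature acts only on enzymatically driven rates
(standard and active metabolism, maximum consumption) through a shared
Arrhenius factor, and on the oxygen side through the supply dome and the
decline of dissolved oxygen with warming. Ecological rates (realized
feeding, mortality) respond to temperature only *via* the behavioural
re-optimization — there is no direct temperature dependence of attack
rates. The model is deterministic throughout.

## Symbols and renames

Two symbol collisions in the conventional notation are resolved as follows:

| concept                         | conventional | here          |
|---------------------------------|--------------|---------------|
| egestion + excretion fraction   | φ            | `phi_e`       |
| allocation to reproduction      | φ(w, w*)     | `psi` / `allocation` |
| reaction-norm steepness         | c            | `c_mrn`       |
| Arrhenius factor                | c(T)         | `arrhenius_factor` |

Units are grams wet weight, years, °C (Kelvin only inside the Arrhenius
evaluation), mg O₂ L⁻¹ for ambient oxygen, eV for the activation energy.

## Parameters that matter

* `k, n` — standard metabolism `k w^n` (g^(1−n) y⁻¹; slow 1/0.88, fast
  1.5/0.75). The fast strategy's 50% higher `k` reflects the assumption
  that about half of maintenance supports the feeding machinery, so doubled
  maximum intake (`h` 30 → 60 g^(1−q) y⁻¹) costs 50% more maintenance.
* `k_a` — cost of activity at τ = 1, isometric in weight (slow 4, fast
  2 g y⁻¹). The linear-in-`w` cost is what ultimately closes the energy
  budget at large size.
* `γΘ` — encountered food, 60 g^(1−p) y⁻¹ at baseline; food scenarios use
  multipliers 2/3, 1, 4/3 (i.e. 40/60/80).
* `ρ, μ` — baseline and activity mortality: slow (0.1, 6), fast (1, 1),
  both scaled by `w^{q−1}`. These encode refuge use versus exposure.
* `E_a = 0.52 eV`, `T0 = 15 °C` — Arrhenius scaling, `c(T0) = 1`.
* `T_max = 26 °C`, `T_opt`, `η`, `ζ` — the maximum-oxygen-supply (MOS)
  curve: dome regime (η = 3, T_opt = 20) versus continually rising regime
  (η = 0.1, T_opt = 25). `ζ` (slow 0.5, fast 1 g y⁻¹ per w^n) sets its
  height.
* `C_crit = 2`, `C_50 = 4 mg L⁻¹` — ambient-oxygen saturation of supply;
  ambient oxygen is `l·e^{−0.01851 (T−5)}` with `l = 10 mg L⁻¹` at 5 °C
  (approximate seawater saturation at 35 PSU; configurable — the anchor
  value is not part of the published parameter table).
* `ω` — oxygen cost per unit mass metabolized, default 0.005. No published
  value exists for this coefficient; only the ratio ω/ζ is identified (a
  joint rescaling leaves the feasibility constraint unchanged). The default
  is fixed from the scenario definitions: presets must retain aerobic scope
  at full activity (τ = 1) over mid-range temperatures, with oxygen
  limiting activity only near the thermal extremes of 5–26 °C in the dome
  regimes and never below `T_max` in the rising regimes. With ω = 0.005, at
  w = 10 g the dome presets are limited only at T ≤ 5 °C (fast) and
  T ≥ 25 °C (both); raising ω to ~0.01 already violates the mid-range
  window, an order of magnitude lower makes oxygen irrelevant everywhere.
* `w*`, `c_mrn = 0.5 g⁻¹`, `slope = 0` — the maturation reaction norm. The
  intercept `w*` is not a free dial: it is calibrated once per scenario by
  maximizing lifetime reproductive output R₀ at 15 °C and baseline food,
  then held fixed across temperatures and food levels (an evolved trait on
  the timescales modelled). A linearly age-sloped norm
  (`w* + slope·t`) is provided as an option; the original sloped
  formulation it stands in for is not available, so the linear offset is a
  synthetic, clearly-labelled substitute and defaults to off.

## Formula-level decisions

* **MOS dome exponential.** The dome is implemented as
  `λ(T) = ζ x^η e^{η(1−x)}`, `x = (T_max − T)/(T_max − T_opt)`, whose
  stationary point is exactly at `T_opt` — required by the definition of
  `T_opt` as the temperature of maximum supply. A variant with the
  exponential coefficient replaced by the metabolic exponent `n` (which
  shifts the maximum off `T_opt` and is dimensionally anomalous, the two
  symbols being unrelated) is available via `literal_n` for comparison.
* **Normalization.** `λ(T_opt) = ζ` exactly (`normalize_mos=True` default),
  so ζ is literally the "height" of the supply curve. The un-normalized
  form `ζ x^η e^{−ηx}` differs only by the constant factor `e^η`; every
  relative-to-maximum quantity is invariant to the choice.
* **Activity in the oxygen demand.** Demand uses `τ k_a w`, so the
  feasibility constraint `P_O2(τ) ≥ 0` responds to the realized activity;
  the maximal-demand form `k_a w` (the two coincide at τ = 1) is available
  with `strict_paper=True`.
* **Survival.** `S(t) = exp(−∫₀ᵗ M ds)` — the standard cumulative-hazard
  form consistent with "survival to age t".
* **SDA oxygen demand** uses the realized feeding level f and the
  un-scaled `h w^q` inside the parenthesis, with the global `ω c(T)`
  prefactor applied to the whole demand.

## Behavioural optimization

`τ*` maximizes `P/M` on [0, 1] by a 2001-point grid scan refined by bounded
golden-section search (tolerance 1e−8), so results are bit-reproducible; a
flat objective resolves to the smallest τ (risk-averse tie-break). The
oxygen cap `τ_max` is the unique root of the strictly decreasing
`P_O2(τ)` (Brent bracketing, xtol 1e−10), 1 if scope remains at full
activity, and 0 with an `infeasible` flag when even resting metabolism
cannot be sustained (resting feasibility is weight-independent because
supply and resting demand both scale as `w^n`). The realized activity is
`min(τ*, τ_max)`. When no feasible activity yields `P > 0`, the fish
minimizes losses by maximizing `P` itself — maximizing the negative ratio
`P/M` would perversely reward high mortality; the loss-minimizing rule is
continuous with the `P > 0` regime. The original description does not
specify the optimizer or the all-losses case; both choices are this
package's own.

## Growth, fitness and calibration

Growth integrates `dw/dt = (1 − ψ)P` from `w0 = 0.1 g` (initial weight is
not part of the published design; 0.1 g is a post-larval size consistent
with the "even initial activity levels" discussion and is configurable)
with SciPy's adaptive RK45 at rtol 1e−8, jointly with the cumulative hazard
and the fitness integrand as additional states. Because re-optimizing τ
inside the right-hand side dominates the cost, `τ*(w)` is precomputed on
200 log-spaced weights spanning the floor to 10% above the energetic bound
(the root of `max_τ P(w,τ) = 0`) and interpolated monotone-cubically in
log-weight. Weight may shrink but is floored at 0.01 g; negative
contributions are clipped to zero in the R₀ integrand (starving fish do
not produce negative offspring). R₀ is in survival-weighted grams allocated
to reproduction — no egg-size normalization, so only relative fitness
across conditions is meaningful. The default 100-year horizon is
conservative: the integrand decays with survival, and halving the horizon
changes R₀ by < 0.1% in the preset scenarios.

Calibration of `w*` scans 25 log-spaced intercepts on [1 g, energetic
bound] and refines the best bracket by golden-section to 0.1% relative
tolerance; the procedure is deterministic and idempotent.

## Performance metrics and sweeps

Production efficiency `P/(f h c(T) w^q)` (undefined at f = 0, algebraically
bounded by the assimilation fraction `1 − β − φ_e = 0.6`), the Gilliam
ratio `P/(Mw)`, growth trajectories, and R₀ are assembled over the
factorial design (strategy × MOS regime × temperature × food × size) by
`run_sweep`, with relative-to-maximum normalizations computed within
(strategy, regime, food) groups. Diagnostic sizes default to 1.25, 10 and
80 g (5, 10, 20 cm under the condition factor 0.01 g cm⁻³, which is fixed
by the stated length–weight pairs). Infeasible cells are flagged, never
dropped. The default temperature grid spacing is 0.25 °C (the original
spacing is unstated); tests and the acceptance script use coarser grids —
1–3 °C steps and the three-temperature low-food contrast — which resolve
every monotonicity and unimodality property the model exhibits at far lower
cost.

## What the presets do and do not emulate

The presets reproduce the *structure* of the study design: trait contrasts
at equal assumed adult size, two oxygen-supply regimes, three food levels,
a 5–26 °C range. They are not fitted to any species' data; absolute rates
(g y⁻¹) are only meaningful relative to each other. Passing tests therefore
demonstrate internal consistency and the qualitative thermal responses
(activity rising with warming, oxygen limitation confined to extremes,
temperature-size rule at low food, fitness declining with warming and
peaking below the juvenile-growth optimum) — not quantitative agreement
with any particular fish.

## Known limitations

* No anaerobic metabolism or oxygen debt; the aerobic-scope constraint is
  hard on the modelled timescales.
* The behavioural rule is short-sighted (no dynamic programming over future
  states, no thermoregulatory habitat choice).
* No density dependence beyond the assumption that R₀ is the right fitness
  measure; no evolutionary dynamics of traits or of the reaction norm.
* One caveat discovered during development: under the tabulated fast-strategy
  traits, lifetime fitness keeps increasing with the maturation intercept
  far beyond the nominal ~270 g adult size (the marginal condition
  `P′(w*) ≈ M(w*)` is only met at tens of kilograms, because the fast
  energy budget closes only near ~380 kg), so the calibrated fast scenario
  matures far larger than the slow one. The slow strategy calibrates to
  w* ≈ 74 g (plateau ≈ 93 g, ≈ 21 cm). Both calibrations are reported as
  computed; see the repository's acceptance output.
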