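# fishthermal

A size- and trait-based bioenergetic model of fish thermal performance,
coupling an energy budget and an oxygen budget through behavioural
optimization of foraging activity. It is aimed at theoretical and
physiological ecologists who want a mechanistic null model for how
temperature shapes growth, production efficiency, mortality and fitness in
ectotherms — e.g. for contrasting oxygen-limitation (OCLTT-style)
explanations of thermal performance against purely metabolic/behavioural
ones, or for exploring the temperature-size rule.

## The model

Net energy gain at weight `w` (g), temperature `T` (°C) and activity
fraction `τ ∈ [0, 1]`:

    P(w,T,τ) = (1 − β − φ_e) f h c(T) w^q − c(T) k w^n − τ c(T) k_a w

with a Holling type-II feeding level

    f(w,T,τ) = τγΘw^p / (τγΘw^p + h c(T) w^q)

and Arrhenius scaling `c(T) = exp(E_a (T − T0)/(b T T0))` (Kelvin inside,
`c(15 °C) = 1`). The oxygen budget (aerobic scope) is

    P_O2 = S_O2(T) w^n − ω c(T) (β f h w^q + k w^n + τ k_a w)

where the maximum oxygen supply `S_O2(T)` is a flexible dome in temperature
(zero at the lethal limit `T_max`, maximal at `T_opt`) scaled by a
saturating function of ambient dissolved oxygen, which itself declines with
warming. Fish choose activity by Gilliam's rule, `τ* = argmax P/M` with
mortality `M = (ρ + μτ) w^{q−1}`, subject to `P_O2(τ*) ≥ 0` (no sustained
oxygen debt). Surplus energy is split between growth and reproduction by a
logistic maturation reaction norm `ψ(w) = 1/(1 + e^{−c(w−w*)})`; growth
follows `dw/dt = (1 − ψ)P`, survival `S(t) = exp(−∫M dt)`, and lifetime
fitness is `R0 = ∫ ψ P S dt`, with the intercept `w*` calibrated by
maximizing `R0` at the 15 °C reference temperature.

Four presets span the study design: a **slow** (low metabolism,
refuge-seeking: low `ρ`, high `μ`, high activity cost) versus a **fast**
(doubled maximum intake, 50% higher standard metabolism, exposed: high `ρ`,
low `μ`) life-history strategy, each under a **dome**-shaped versus a
continually **rising** (nodome) maximum-oxygen-supply regime:
`slow_dome`, `slow_nodome`, `fast_dome`, `fast_nodome`.

## Worked example

```python
>>> import fishthermal as ft
>>> bundle = ft.preset("slow_dome")
>>> sol = ft.optimal_activity(10.0, 15.0, bundle)   # 10 g fish at 15 °C
>>> round(sol.tau_star, 4), round(sol.P, 2), round(sol.M, 3), round(sol.P_O2, 3)
(0.1941, 16.41, 0.798, 1.587)
```

The slow strategist forages ~19% of the time: its high activity mortality
(μ = 6 y⁻¹) and activity cost pin the Gilliam optimum low. It nets
16.4 g y⁻¹ against a mortality of 0.80 y⁻¹, with 1.59 units of aerobic
scope to spare — oxygen is not limiting here. The same call on
`fast_dome` gives `tau_star ≈ 0.90`: the fast strategist, with doubled
intake capacity and low activity mortality, forages almost continuously.

The same numbers from the shell, as one CSV row:

```sh
fishthermal activity --preset slow_dome --w 10 --t 15
```

Scenario sweeps, growth trajectories and fitness curves:

```sh
fishthermal sweep --t-grid 5:26:1 --out sweep.csv
fishthermal growth --preset slow_dome --t 15 --out growth.csv
fishthermal fitness --preset fast_dome --t-grid 5:25:2 --out fitness.csv
```

Outputs are tidy CSV with a `# params {...}` header row recording the fully
resolved parameter bundle, so every table is reproducible from its own
header. Custom parametrizations go through YAML configs
(`--config my.yaml`, top-level keys `preset`, `traits`, `thermal_oxygen`,
`mrn`, `simulation`).

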