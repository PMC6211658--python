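# bindkin

Non-equilibrium drug-target binding dynamics: dynamic occupancy of
binding sites that themselves build and decay.

## The problem

Pharmacology usually treats receptor occupancy as an equilibrium
quantity — the Hill value `L0/(L0 + Kd)` — as if the binding site were
permanently available.  Real binding sites are not: proteins are
synthesized and degraded (PCSK9 turns over with a ~5 min half-life),
and binding-competent conformational states open and close (the hERG
channel's open/inactivated states live ~350 ms).  When site turnover is
fast compared with binding, occupancy must *rebuild within every
buildup/decay cycle of the site*, and equilibrium reasoning fails.

`bindkin` solves the binding rate equation under time-dependent site
availability,

    dC/dt = kon (B_total(t) − C) L0 − koff′ C,        C(0) = 0,

where `B_total(t)` rises with rate constant `k_i` to a plateau and,
after settling (95% of the plateau, at t ≈ 3/k_i), decays with rate
constant `k_−i` — either as a saturating exponential (species turnover,
scenario 1) or as a logistic pulse (state gating, scenario 2).  Because
a complex cannot outlive its site, dissociation is *hijacked* by site
decay: `koff′ = max(koff, k_−i)`, raising the effective affinity to
`Kd′ = koff′/kon ≥ Kd`.

In the dimensionless groups `α = kon·L0/k_i`, `β = koff′/k_−i`,
`γ = k_−i/k_i`, `τ = k_i·t`, the equation has closed-form solutions
(elementary exponentials for scenario 1; Gauss-hypergeometric ₂F₁ terms
for scenario 2), backed by an adaptive ODE integrator that doubles as
an independent oracle.  The resulting fractional-occupancy profiles are
classified as:

* **SSO** (steady-state occupancy) — `c(τ)/B_total(τ)` constant at
  `c∞ = α/(α+β)`; requires `kon ≥ kon_ss = 10·k_i/L0`,
* **qSSO** — the plateau reached only by saturating dose
  (`n = L0/Kd′ ≫ 1`),
* **nSSO** — occupancy lags the site and peaks below `c∞`.

The practical message encoded in the `tuning_report` advisor: speed
`kon` to `kon_ss` *first*; then slow `koff` — but only down to `k_−i`,
because residence time below the site's own decay rate adds nothing.

## Worked example

Gain-of-function D374Y PCSK9 binding the LDL receptor at endosomal pH,
at the top of the circulating concentration range (40.5 nM), with the
~5 min site turnover (`k_i = k_−i = 1e-2 s⁻¹`) and measured kinetics
(`kon = 6.74e5 M⁻¹s⁻¹`, effective `koff′ = 2.3e-3 s⁻¹`):

```
$ bindkin case pcsk9 --variant D374Y --ph 5.3 --ligand 40.5e-9
{
  "Kd_prime": 3.4124629080118693e-09,
  "L0": 4.05e-08,
  "c_at_site_peak": 0.8530056972970878,
  "c_peak": 0.8598673044882325,
  "kon_ss": 2469135.802469136,
  "ph": 5.3,
  "profile": "qSSO",
  "tau_peak": 3.0700000000000003,
  "variant": "D374Y"
}
```

Reading this: the effective affinity is 3.4 nM (hijack-corrected from
the measured 0.54 nM), so 40.5 nM is an ~12-fold saturating dose.
Occupancy reaches 85% of the site maximum when site availability peaks
(`c_at_site_peak`, τ = 3), with the true maximum 86% shortly after
(`tau_peak ≈ 3.07`) — a quasi-steady-state profile reached through
concentration, since `kon` is ~4-fold below the `kon_ss` for this dose.
Wild-type under the same conditions peaks at 82%/83%: the disease
mutation buys only a few points of dynamic occupancy at high exposure.

The generic driver works the same way for hypothetical parameters:

```
$ bindkin simulate --scenario 1 --kon 1e6 --koff 1e-3 \
    --ki 1e-4 --k-decay 1e-4 --ligand 1e-9
{
  ...
  "c_inf": 0.5,
  "functional_window": "8.333 hr",
  "kon_ss": 1000000.0,
  "profile": "SSO",
  ...
}
```

Here `kon` exactly meets `kon_ss = 10·k_i/L0 = 1e6`, so a 1 nM dose
(`L0 = Kd`) holds a constant 50% of the available site throughout its
8.3 hr functional window.  Other subcommands: `sweep` (kon ladders),
`classify`, `case herg`, `drugs summarize` (kinetic-regime percentages
over the packaged 32-drug table), `fixtures validate`.  Everything is
also available as a plain Python API (`bindkin.solve_numeric`,
`bindkin.c_closed_scenario1`, `bindkin.classify_profile`, ...).

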