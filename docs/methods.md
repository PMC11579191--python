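# Methods

## Model and assumptions

All three models are one-compartment, linear, time-invariant within dosing
cycles; doses are the only discrete events.

**Oral (Bateman) multi-dose.** Between doses the state follows
`y' = -κa y`, `x' = κa γ y - κe x`, where `y` is the amount still awaiting
absorption and `x` the plasma concentration. At each dose instant
`t_{n-1}` the depot jumps (`y += d_n`) and `x` is continuous — oral intake
cannot raise systemic concentration instantaneously. With the dose-history
sums `S_α(n), S_β(n)` (forward recursion `S(n+1) = factor_n S(n) + d_{n+1}`,
factors `α_n = e^{-κa τ_n}`, `β_n = e^{-κe τ_n}`), the within-cycle solution
is `x = k S_β(n) e^{-κe Δ} - k S_α(n) e^{-κa Δ}`, `y = S_α(n) e^{-κa Δ}`,
`k = κa γ/(κa-κe)`. The equi-dose case closes the recursion geometrically:
`S_α(n) = d (1-α^n)/(1-α)`.

`C₁(n)` is computed as `k·S_β(n)`; the equivalent three-term expression
(`k S_α + k[(S_β - d_n) - (S_α - d_n)]`) is retained in the test suite and
checked for equality to machine precision. The literal O(N²) double-sum
definition of the product sums is likewise kept in tests as the reference
implementation of the recursion.

**IV bolus.** Doses are *concentration increments* δₙ (mass/volume) — note
the unit change from the oral model, whose doses are amounts. `x` jumps by
δₙ at each dose and decays mono-exponentially in between:
`x = S_β(n) e^{-κe Δ}`. By linearity this equals the plain superposition of
decayed past doses, which serves as an independent closed-form cross-check.

**Finite absorption time (F.A.T.).** Each cycle splits at the cutoff
`s_n = t_{n-1} + σ_n` into an assimilation phase (absorption + elimination)
and a clearance phase (elimination only, depot exactly zero). The dose
condition is a *reset* (`y(t_{n-1}) = d_n`): any unabsorbed remainder of
earlier doses is discarded, which coincides with the additive oral
condition because `y` vanishes on the preceding clearance phase (asserted
by a test, not assumed). Ground truth is the per-cycle recursion

    x_assim(Δ) = k d_n (e^{-κe Δ} - e^{-κa Δ}) + r_n e^{-κe Δ}
    x_clear(t) = x(s_n) e^{-κe (t - s_n)},    r_{n+1} = x(t_n),  r_1 = 0

valid for arbitrary schedules including `σ_n = τ_n` (empty clearance
phase). The equi-dose closed form is a secondary path, cross-checked
against the recursion for 20 cycles.

*Index note.* In the equi-dose closed form the clearance coefficient is
`C₃(n) = k (B - A) Σ_{i=1}^{n} β^{n-i} d_i` (`A = e^{-κa σ}`,
`B = e^{-κe σ}`). A variant with the sum stopping at `i = n-1` circulates;
it makes `C₃(1) = 0`, i.e. a zero clearance concentration after the very
first dose, contradicting continuity at the cutoff. The carryover identity
`C₁(n) - C₂(n) = (β/B)·C₃(n-1) = r_n` — which the recursion satisfies by
construction — pins the sum's upper limit at `i = n`; the package
implements that form and tests the identity rather than silently patching
either convention.

## Schedule bookkeeping

Schedules are finite truncations of conceptually infinite plans; evaluation
past the last cycle is a domain error, never extrapolation (append a
zero-dose washout cycle via `DoseRegimen.with_washout` to observe decay).
Cycles are half-open `[t_{n-1}, t_n)`: a dose instant opens its cycle, so
`y` (oral), `x` (bolus) and the F.A.T. phase label are right-continuous at
events; `t = t_N` maps to cycle `N`. Zero doses are legal, making "skipped
dose" encodable either as a longer interval or an explicit zero — both give
identical trajectories (tested).

`κa = κe` within 1e-9 relative is a hard error: every closed form divides
by `κa - κe`, the confluent limit is rare in practice, and no
`t·e^{-kt}` fallback is provided. Flip-flop ordering (`κa < κe`) is fully
supported; the prefactor `k` changes sign but all concentrations remain
positive. Units are documented (hours, mg, mL⁻¹ in the examples) but not
enforced; the CLI labels outputs with the config's declared units.

## Metrics and asymptotics (equi-dose)

Closed forms in `α, β, k`: per-cycle AUC
`k d [(1-β^n)/κe - (1-α^n)/κa]`; peak offset
`ln(κa C₂/(κe C₁))/(κa-κe)` with the peak value in power form; trough
(remainder) `x(nτ)`. The asymptotic envelope is
`ss_lower = k d [β/(1-β) - α/(1-α)]` (limiting trough) and `ss_upper` the
limiting peak. The limiting per-cycle AUC equals the single-dose
`AUC_[0,∞) = γ d / κe` exactly (algebraic cancellation; asserted at 1e-12
and cross-checked by quadrature in tests).

For extreme parameters the printed peak-offset formula can leave `[0, τ]`;
the implementation then returns the true boundary argmax and emits a
`RuntimeWarning` rather than reporting an out-of-cycle time.

The periodicity gap `sup_{s∈[0,τ]} |ΔC₁ e^{-κe s} - ΔC₂ e^{-κa s}|`
(`ΔCᵢ` between consecutive cycles) is located in closed form from the two
endpoints and the unique interior critical point. Because
`ΔC₁ = k d β^{n-1}` and `ΔC₂ = k d α^{n-1}`, the gap decays geometrically
with ratio `max(α, β)`. The ε-steady-state index `N_ε` requires the gap to
stay below ε *for all* later cycles; that infinite quantifier is certified
by the envelope `gap(m) ≤ (|ΔC₁(n)|+|ΔC₂(n)|)·max(α,β)^{m-n}` — a finite,
provable stopping rule that does not assume the gap is monotone from the
start. Metrics are equi-dose only; general-regimen per-cycle AUC is
available through the oracle's quadrature.

"Therapeutic range" here means the asymptotic concentration envelope
`[S̲S̲, S̄S̄]` — a property of the schedule — not the externally prescribed
clinical MIC/TC window; the design module relates the two.

## Regimen design

Both envelope bounds are linear in `d`, so matching a target envelope
reduces to a scalar problem: `ss_upper/ss_lower` is dose-free, > 1
everywhere, → 1⁺ as τ → 0 and unbounded as τ → ∞. The solver root-finds
the ratio in `log τ` (Brent, relative tolerance 1e-12, bracket expanded
geometrically within τ ∈ [1e-6, 1e6]) and scales `d` linearly. The assumed
monotonicity of the ratio is *verified on the search bracket* (17-point
scan) before root-finding; violation aborts with a diagnostic. Default
exact targets when only a (MIC, TC) window is given are the widest
admissible envelope — the window edges themselves. Because that puts the
designed schedule exactly on the boundary of the effective set (a closed
condition), the membership predicate allows 1e-9 relative slack.

## Numerical oracle

The oracle integrates the raw ODE systems with `scipy`'s DOP853, restarted
at every event with the prescribed jump applied to the state, at default
relative tolerance 1e-12 (accepted range 1e-13..1e-6). It deliberately
shares no algebra with the closed forms: no matrix exponentials, no
superposition. AUCs are checked with adaptive quadrature (`scipy` QUADPACK).
Closed-form-vs-oracle comparisons use 1e-6..1e-8 relative slack to absorb
error accumulation over many cycles; observed deviations sit at
1e-12..1e-10.

## Test corpus and problem sizes

Randomized property tests draw `κa, κe` log-uniform in [0.05, 2] /h
(separation > 1%, flip-flop arising naturally in about half the draws),
`γ` log-uniform in [1e-4, 1e-2] /mL, 1-20 doses, intervals uniform in
[1, 24] h, doses uniform in [0, 1000] mg — the realistic once-hourly-to-
once-daily oral dosing regime. Oracle sweeps use 100 random regimens per
model (40 in the acceptance script) sampled at 20 grid points per cycle;
steady-state checks simulate 300 cycles; monotonicity scans use 20×20
(d, τ) grids. The generator emulates schedules and kinetics only: it does
not model measurement noise, between-subject variability, nonlinear
elimination or lag times, so passing tests certify the mathematics of the
dosing models, not fit to clinical data.

## Known limitations

- No parameter estimation from observed concentrations, no lag-time or
  transit-compartment models, no multi-compartment kinetics, no infusions.
- `κa = κe` is rejected rather than handled by a confluent limit.
- Metrics/asymptotics/design cover equi-dose schedules; arbitrary-schedule
  trajectories are exact but their asymptotics are not summarized.
- Strict-monotonicity claims (accumulating troughs, growing peaks) hold
  until increments fall below double-precision resolution (~cycle 18 for
  the example kinetics); tests assert strictness only where resolvable.
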