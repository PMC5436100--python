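# Methods

## Scope and assumptions

`redoxkin` treats H₂O₂ signaling in the *eustress* regime: moderate,
transient or localized H₂O₂ elevations that do not overload the antioxidant
systems.  Three simplifications follow and bound every result the package
produces:

1. **First-order removal.**  Antioxidant consumption and switch oxidation
   are pseudo-first-order in H₂O₂ (`v = k·[H₂O₂]`).  No Michaelis–Menten
   saturation: outside eustress (high bolus doses) the steady-state and
   competition formulas overestimate removal.
2. **Sustained local H₂O₂ for switch kinetics.**  The master equation
   assumes the H₂O₂ level near the switch is constant on the time scale of
   switch relaxation.  Coupling a time-varying H₂O₂ trajectory into the
   switch ODE is supported numerically (chain `scenario_sim` output into
   `integrate_time_course`) but has no closed form here.
3. **Minimal two-state switch.**  One oxidation step, one lumped enzymatic
   reduction step.  Redox relays (peroxiredoxin → target transfer),
   peroxiredoxin hyperoxidation and cooperative/ultrasensitive responses
   are out of scope; where relays operate, real response times are slower
   than the two-state prediction because the relay adds a delay.

## Parameters

All internal computation is in SI (M, s); µM appears only at interfaces.

Built-in registry (`builtin_registry()`), second-order oxidation constants
`k_ox` in M⁻¹s⁻¹: Prx2 1×10⁷, Prx5 3×10⁵, Keap1 140, cdc25B 140, PTP1B 24,
PTP1B+CO₂ 396 (bicarbonate/peroxymonocarbonate chemistry, 37 °C), SHP-2 20,
SHP-2+CO₂ 167.  Reduction constants `k_switchoff`: 2×10⁻³ s⁻¹ for the
phosphatases, Keap1 and cdc25B (slow thioredoxin-family reduction of
phosphatases) and 2 s⁻¹ for the peroxiredoxins (fast thioredoxin
recycling) — a ~1000-fold difference that makes phosphatase and
peroxiredoxin dynamic ranges overlap despite a ~10⁴-fold reactivity gap.
The SHP-2+CO₂ constant is carried in the registry on the same footing as
PTP1B+CO₂, as tabulated in the source kinetic data.

Competition entries: Prx `k2` 10⁵–10⁷ at 10 µM, GPx 6×10⁷ at 0.2–10 µM,
catalase 10⁷ at 10³ µM (the concentration refers to the peroxisome;
compartment volumes are not modelled, the value is stored with its
provenance note).  Interval-valued constants are kept as `[low, high]`
pairs and propagated endpoint-wise; point queries use the midpoint unless
an endpoint is requested.

Threshold policy (`ThresholdPolicy`): dynamic range edges at 10% and 90%
oxidation (below 10% the response is too weak to transmit, above 90% it is
near saturated), response time reported at 50% oxidation, and 600 s (10
min) as the longest response time still useful for signaling.  All four
are configurable; the 10–90% window fixes the dynamic-range span at
(0.9/0.1)·(0.9/0.1) = 81-fold regardless of the switch.

## Response time definition

The response time is the half-time of the exponential relaxation toward
the new oxidation steady state, `t½ = ln 2/(k_ox·H + k_switchoff)`.  The
intuitive phrase "time to oxidize half of the initially present target" is
subtly different and ill-defined at exactly 50% steady-state oxidation
(the half-way point is approached only asymptotically); the relaxation
half-time is finite for every input, reproduces the tabulated 173 s and
0.2 s values, and exhibits the sum dependence on the two rates.  The
literal variant is available as `time_to_half_reduced`, raising a
`ValueError` whenever the steady state never crosses half the initial
reduced pool.

## Quasi-steady-state validation (scenario_sim)

The full balance `d[H₂O₂]/dt = v(t) − k_cons·[H₂O₂]` is integrated with
LSODA (rtol 10⁻⁸, atol 10⁻¹⁴ M — k_cons up to ~10³–10⁴ s⁻¹ makes the
system stiff on minute windows), restarted at the profile's slope
discontinuities so the solver never steps across a corner.  The default
formation profile is triangular: rise 0 → v_peak over 0–300 s, decay to 0
at 1200 s, zero after — the simplest shape matching a burst that peaks at
5 min and ends at 20 min; tabulated profiles are supported for fidelity to
any measured shape.  v_peak defaults to 1.2×10⁻⁵ M·s⁻¹ (QSSA peak of 1 µM
at the k_cons lower bound 12 s⁻¹); because the system is linear the QSSA
deviation metric is invariant to the amplitude.  The initial condition is
QSSA-consistent (`v(0)/k_cons`) so that `max_rel_dev` measures
transient-tracking error, not initialization error; `cold_start=True`
starts from zero.  `max_rel_dev` is taken over grid points with positive
QSSA level on a default 1-s grid; near the profile's start and end the
relative deviation scales as `1/k_cons` (QSSA boundary layers), which is
what limits the metric at high k_cons.  The QSSA verdict rule: removal
half-time `ln 2/k_cons` must be ≤ signal_timescale/100 (ratio
configurable); minute-scale signaling with k_cons ≥ 12 s⁻¹ passes by about
two orders of magnitude.

## Fitting (inference)

`fit_rate_constants` minimizes the unweighted sum of squared residuals
between the closed-form oxidized fraction and observations, jointly over
all courses (per-point weights optional; the error structure of
densitometry data is generally unknown, so none is assumed).  The
optimizer (`scipy.optimize.least_squares`) works on log₁₀-transformed
constants — enforcing positivity across the ~10-decade plausible range —
from a heuristic start (plateau ratios give `k_switchoff/k_ox`; the rise
time of the fastest course gives λ) plus 4 seeded uniform ±1-decade
perturbations; the best of the 5 starts is kept.  With a single distinct
dose, (k_ox, k_switchoff) are structurally unidentifiable — the data
determine only λ = k_ox·H + k_switchoff and the plateau — so the fit is
reparameterized in (log₁₀ λ, logit plateau) and reported with
`identifiable=False` and the composites.

## Synthetic data

`generate_synthetic_course` evaluates the closed-form trajectory and adds
independent Gaussian noise (default study condition σ = 0.02 on oxidized
fractions, an additive truncated-Gaussian stand-in for densitometry error)
clipped to [0, 1], with a recorded seed.  The recovery study conditions
are: truth (396 M⁻¹s⁻¹, 2×10⁻³ s⁻¹), doses {1, 5, 25} µM, 20 time points
spanning 180–3600 s (several relaxation times at every dose), 10
replicates.  What the generator does *not* emulate: correlated errors
within a gel, dose uncertainty, baseline oxidation offsets, relay-delayed
kinetics and probe-calibration error — so passing recovery tests show the
estimator is correct under its own model, not that real densitometry data
will reach the same accuracy.

## Numerical choices

- Closed-form switch trajectories are cross-validated against an
  independent Radau integration of the same ODE (rtol 10⁻¹⁰, atol 10⁻¹²);
  agreement is required to 10⁻⁶ absolute over k_ox ∈ [10, 10⁸],
  k_switchoff ∈ [10⁻⁴, 10], H ∈ [10⁻⁹, 10⁻³] M.
- Inversion `h2o2_for_ox` requires 0 < ox < 1 and raises otherwise:
  saturation is not invertible, and returning infinities would silently
  poison downstream arithmetic.
- Flux fractions are defined on rate constants, `k/(k_cons+k_sign)`, which
  coincide with flux fractions at steady state but remain well defined
  transiently; computing fluxes as `fraction × v_formation` makes flux
  conservation exact in floating point.
- Published-value comparison uses half-away-from-zero rounding
  (`round_sig`), 2 significant figures by default; report tables print
  response times to the nearest second (a tenth of a second below 1 s).
- Oxidized fractions within ~10⁻⁷ of 1 carry an irreducible relative error
  of order eps/(1−ox) in double precision; round-trip identities are exact
  to 10⁻¹⁰ outside that saturation sliver.

## Limitations

Single well-mixed compartment (no membrane transport or localized-pool
geometry beyond a scalar gradient factor); the gradient regime
(peroxiredoxins active: factor 650–1000; inhibited: under 10) must be
chosen by the user — no rule infers it from the dose; rate constants are
taken at face value with no temperature/pH correction; hyperoxidation and
multi-step relays are not modelled.
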