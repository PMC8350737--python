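# Methods

`zymoflux` models glucose/xylose co-utilization by an engineered,
2,3-butanediol (2,3-BDO) producing *Zymomonas mobilis* Δpdc strain at three
levels: transporter kinetics, pathway thermodynamics/enzyme cost, and a
core-network dynamic flux balance simulation. This note records the models,
the defaults and why they were chosen, and what the synthetic data do and do
not establish.

## 1. Transporter uptake kinetics

Glucose and xylose enter through the same facilitator (glf) and inhibit
each other competitively:

    v_glc = Vmax_glc [glc] / ( Km_glc (1 + [xyl]/Ki_xyl) + [glc] )
    v_xyl = Vmax_xyl [xyl] / ( Km_xyl (1 + [glc]/Ki_glc) + [xyl] )

with extracellular balances d[glc]/dt = −v_glc·[X], d[xyl]/dt = −v_xyl·[X].
Biomass [X] is data, interpolated linearly between measured points; growth
is deliberately not modeled at this layer so the transporter fit does not
inherit growth-model error.

**Estimation.** The six constants are fit in log10 space by multi-restart
trust-region least squares (`scipy.optimize.least_squares`, bounds
Vmax ∈ [10⁻³, 10³] mmol gDCW⁻¹ h⁻¹, Km ∈ [10⁻², 10⁴] mM, Ki ∈ [1, 10⁴] mM).
The first start is a finite-difference heuristic (peak observed specific
rates, quartile concentrations); the rest are log-uniform draws seeded by
the user. The default loss divides each residual by the observed
concentration (floored at 2% of the initial value). This is the maximum
likelihood weighting when measurement error is proportional to
concentration, which is how HPLC error behaves and how the synthetic
generator injects noise; unweighted mM² residuals are available via
`weighting="absolute"`. The ODE is integrated with LSODA; the
finite-difference Jacobian uses a relative step of 10⁻⁴ so that parameter
perturbations move the residuals well above the integrator noise floor.

**Identifiability.** A single batch course pins Vmax_glc, Vmax_xyl and
Km_xyl tightly, but Km_glc trades off against Ki_xyl along a nearly flat
likelihood ridge: during the glucose phase only the lumped quantity
Km_glc·(1 + [xyl]/Ki_xyl) is strongly constrained, and [xyl] varies too
little before glucose runs out to separate the two factors. A linearized
(Cramér–Rao) analysis at the default synthetic conditions (2% noise, 27
samples) gives relative standard deviations of roughly 4% (Vmax_glc),
~90% (Km_glc), 2–3% (Vmax_xyl, Km_xyl), and >100% for both Ki. Noiseless
data recover all six constants essentially exactly; with noise, point
estimates of Km_glc and the Ki's from one course should be treated as
order-of-magnitude. The tests therefore check a pooled median error over
the Vmax/Km estimates rather than per-parameter medians.

## 2. Synthetic fermentation generator

`generate_fermentation` emulates a 65 h batch with initial glucose 443 mM,
xylose 245 mM and inoculum 0.277 gDCW L⁻¹ (OD 0.84 × 0.33 g L⁻¹ per OD).
Biomass follows a logistic curve (defaults r = 0.12 h⁻¹, K = 5 gDCW L⁻¹,
chosen so glucose falls below 3 mM near 25 h and both sugars are spent by
65 h, matching the fermentation the defaults emulate). The sugars are
integrated against the *linear interpolation* of the logistic sampled at
the measurement times — the same biomass treatment the estimator uses — so
the true parameters lie exactly in the fitting model's class and noiseless
recovery is a meaningful test. Measurement noise is multiplicative
Gaussian, value × (1 + cv·ε) clamped at zero, applied to sugars and
biomass. Ground-truth kinetics default to the fitted point estimates with
Ki_xyl = 200 mM and Ki_glc = 600 mM as configurable stand-ins (only the
ordering Ki_glc ≫ Ki_xyl is empirically supported).

What passing tests show: the estimator is consistent and well-behaved under
the stated noise model. What they do not show: robustness to structured
HPLC artifacts, sampling irregularity, biomass measurement bias, or model
misspecification of the rate law itself.

## 3. Pathway thermodynamics (MDF)

A pathway is an ordered reaction list with signed stoichiometry, ΔG°′
(kJ mol⁻¹), and a relative flux per mol of 2,3-BDO. The max–min driving
force is the LP

    max B  s.t.  −(ΔG°′_j + RT S_jᵀ x) ≥ B,   ln lb ≤ x ≤ ln ub,

over x = ln(c/1 M), solved with HiGHS. Defaults: free intracellular
metabolites in [1 μM, 10 mM]; extracellular sugars pinned at measured
concentrations; T = 298.15 K (the reference state of standard
eQuilibrator-sourced ΔG°′ values) even though fermentations run at 30 °C —
configurable, and flagged here because it is a provenance choice, not a
physical claim. Water and protons never appear in the concentration vector
(their contribution is absorbed into ΔG°′). Reactions flagged irreversible
(the glf transport step, ΔG°′ = 0 by construction, and the two
decarboxylations als/aldc) are excluded from the maximin objective — their
ΔG′ is still reported — because transport is treated kinetically and gas
release makes the decarboxylations effectively one-way.

Cumulative profiles are unweighted partial sums of per-reaction ΔG′ in
pathway order, evaluated either at the MDF-optimal concentrations or at a
1 mM reference ("standard" profile); the bottleneck report lists reactions
with ΔG′ > 0 at 1 mM. Time-course scans re-pin the substrate at each of a
series of concentrations, floored at 10⁻³ mM to keep logarithms finite near
depletion. Cofactor-ratio scans add the equality x_num − x_den = ln r and
re-solve.

**Flux split of the xylose route.** Per mol BDO: 1.2 xylose through
isomerase/xylulokinase; 0.4 each through rpe (written X5P→Ru5P, the net
carbon-flow direction), rpi, tkt₁, tal, tkt₂; 0.8 through pgi and the ED
reactions; 1.2 through lower glycolysis; 1 through als/aldc/bdh. This is
the unique split that satisfies carbon balance (1.2 × C5 = C4 + 2 × CO₂)
and intermediate steady state, and it yields +1.2 ATP, +0.8 NADPH and
+0.2 NADH per BDO; the glucose route yields +1 ATP, +1 NADPH, +2 CO₂.

## 4. Enzyme protein cost

The enzyme demand of a reaction carrying flux v (mol s⁻¹) is factorized as

    E = MW · v / (kcat⁺ · η_rev · η_sat),
    η_rev = 1 − exp(ΔG′/RT),
    η_sat = Π_S (s/Km)^|ν| / ( Π_S (1+s/Km)^|ν| + Π_P (1+p/Km)^|ν| − 1 ),

the common modular rate law written as capacity × thermodynamic ×
saturation efficiency. For irreversible steps η_rev ≡ 1 and the product
terms are dropped from η_sat. Reverse turnover numbers, where needed,
follow the Haldane relationship kcat⁻ = kcat⁺ Π_P Km^|ν| / (K_eq Π_S Km^|ν|)
with Km in M.

Total pathway cost Σ_j E_j (g per mol s⁻¹ of pathway flux) is minimized
over ln-concentrations with the same bounds/pins as the MDF problem,
subject to ΔG′_j ≤ −ε (ε = 10⁻³ kJ mol⁻¹) for reversible steps — linear
constraints in x. Because the objective spans many decades (a reaction
pushed to equilibrium has η_rev → 0), the optimizer minimizes log(total
cost) with SLSQP; this preserves the argmin and conditions the search. Ten
seeded restarts by default: one from the MDF optimum (requires MDF > 0,
otherwise the bottleneck reaction is named in the error), the rest
Gaussian jitters of it; the returned solution is never worse than the cost
at the MDF optimum. Time-course scans warm-start each point from the
previous optimum and report infeasible timepoints explicitly.

## 5. Core network and dynamic FBA

The shipped core network is hand-built from the strain's central carbon
map: glf transport for both sugars, the ED pathway, an incomplete EMP
(no phosphofructokinase), the engineered pentose phosphate reactions, a
truncated TCA arm (no α-ketoglutarate dehydrogenase, no malate
dehydrogenase), the acetolactate→acetoin→2,3-BDO branch, glycerol
formation as an NADH sink, pyruvate decarboxylase present but bounded to
zero (the Δpdc knockout), respiration as a coupled oxidase
(2 NADH + O₂ + ADP + Pi → 2 NAD + ATP, i.e. P/O = 0.5, reflecting the
notoriously inefficient *Z. mobilis* chain) plus an uncoupled oxidase, a
transhydrogenase (NADPH→NADH), NGAM with lower bound 0, and exchanges for
glc/xyl/O₂/acetoin/BDO/glycerol/CO₂/Pi/water. Every internal reaction is
carbon-balanced (checked at build time), so FBA conserves carbon exactly.
The biomass reaction uses classic precursor demands (g6p, f6p, r5p, e4p,
gap, 3pg, pep, pyr, accoa, oaa, akg, 13 mmol NADPH) with a lumped ATP
requirement of 100 mmol gDCW⁻¹ — deliberately high, encoding the low
ATP-biomass yield of *Z. mobilis* (≈10 g DCW per mol ATP); the implied
biomass carbon is ≈42.6 mmol C gDCW⁻¹. The shipped network has 58
reactions and 54 metabolites; it is a faithful reduced reconstruction, not
a replica of any particular genome-scale reconstruction, and exact reaction counts
are only asserted against user-supplied model files.

**Simulation (static optimization approach).** Each step: (1) kinetic
exchange bounds from the current state — sugar uptake from the
competitive-inhibition law, acetoin/BDO reuptake by plain MM
(Vmax 10 mmol gDCW⁻¹ h⁻¹, Km 5 mM), O₂ by MM (Vmax 15, Km 1.24 μM) — with
availability caps so no pool can be drawn below zero within a step;
(2) lexicographic FBA: max biomass → max BDO export → max acetoin → max
glycerol → min glucose uptake → min xylose uptake → min O₂ uptake, each
optimum fixed within 10⁻⁵ relative before the next (the product order puts
the target molecule first; the three minimizations are order-insensitive
since all products are already fixed); (3) state integration with fluxes
frozen: biomass exactly exponential, species balances use the exact
integral of X(t), and dissolved O₂ — stiff, Km ≈ 1 μM against mM dynamics
— advances by the closed-form solution of its linear ODE, never
overshooting negative. The O₂ uptake bound is evaluated at the
quasi-steady dissolved concentration where MM uptake equals kLa transfer
(solving the resulting quadratic), plus drawdown of the current stock;
without this, the bound flip-flops between saturation and zero at
alternating steps. Defaults kLa = 30 h⁻¹, O₂* = 0.21 mM; a single constant
kLa is used even where a real run changes agitation mid-batch.

Infeasible steps (possible only through numerics — NGAM's zero lower bound
makes the zero vector feasible) advance the state with zero biological
fluxes, abiotic O₂ transfer still applied, and are flagged. GLPK solves
each LP from a cold start (presolve on): warm bases on these
near-degenerate lexicographic problems can cycle. `simulate_batch` runs on
a private copy of the model so identical inputs give bit-identical
trajectories.

Under the default aeration the whole metabolism is O₂-transfer limited:
anaerobically, every glucose through the obligatory g6pdh step strands one
NADPH that no fermentative sink can clear at non-negative ATP balance, so
the Δpdc strain needs (micro)aerobic conditions to run — consistent with
how this strain is actually fermented. Expected behaviors reproduced:
simultaneous (non-diauxic) sugar consumption, acetoin accumulating only
after sugar exhaustion, BDO declining thereafter when reuptake is enabled
(re-oxidation for maintenance), biomass overprediction relative to real
fermentations (no maintenance lower bound, no metabolite leakage).

## 6. Condition scans

`sugar_ratio_scan` varies the initial glucose:xylose *molar* ratio r with
total substrate carbon fixed (6·glc + 5·xyl = 3883 mM C, the validation
loading); `kla_scan` varies the O₂ transfer coefficient. Both report the
maximum productivity max_t [BDO](t)/t (argmax tie → earliest) and the
final titer, which favor different aeration levels: productivity keeps
rising with kLa while the titer peaks at moderate aeration, because strong
aeration diverts late-batch BDO to re-oxidation and acetoin.

## 7. Problem sizes and numerical defaults

Default batch: 65 h at dt = 0.1 h (650 lexicographic solves, ~5 s).
Example scans use dt = 0.25 h. Parameter-recovery checks use 27-sample
courses, 2–3 restarts per fit; MDF/cost toy oracles use 2–3 reaction
chains with grid search refined to ≲0.02 kJ mol⁻¹ resolution. LP fixing
slack: max(|v|·10⁻⁵, 10⁻⁶). ODE tolerances: 10⁻⁷ (fitting), 10⁻⁸
(recovery checks and generation).

## 8. External parameter tables

ΔG°′ (eQuilibrator-style), kcat, Km and molecular weights for the real
enzymes are user-supplied files merged onto the shipped pathway
definitions; missing entries come back as a checklist rather than an
error. Duplicate rows merge by geometric mean for kinetic constants (the
standard convention for multi-source database values) and arithmetic mean
for ΔG°′ (a signed quantity). The shipped `synthetic_params.tsv` is a
clearly-labelled synthetic stand-in with plausible magnitudes so examples
and machinery tests run self-contained; its numbers carry no literature
provenance and no result derived from it should be quoted as a property of
the organism.

## 9. Known limitations

- Km_glc and both Ki are weakly identified from one batch course (§1);
  profile-likelihood or multi-condition designs would be needed for tight
  estimates.
- ΔG°′ values are consumed as given: no pH/ionic-strength transformation,
  no temperature correction from 25 °C.
- The enzyme-cost objective is near-convex in ln-concentrations but not
  certified convex; multi-start SLSQP can in principle return a local
  minimum (grid cross-checks on small instances agree within 1%).
- The core network's biomass composition and OD→gDCW factor (0.33) are
  generic defaults, both configurable; absolute biomass and growth-rate
  predictions inherit their uncertainty directly.
- dFBA ignores intracellular dynamics entirely (pseudo-steady state) and
  uses a single kLa; transient agitation schedules are out of scope.
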