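# Methods

## Model and assumptions

The pathway is modelled as a deterministic, well-mixed ODE system
`dC/dt = N·v(C)` over amount concentrations in nmol/L.  Compartments
(plastid, cytosol, mitochondrion, external) are labels only: the package
does not track volumes, all species share one unit, and inter-compartmental
movement is an ordinary reaction with its own rate law.  Boundary species
(external reservoirs such as the AIR/SAM/NAD/glycine feeds) are clamped at
their initial concentration by zeroing their derivative.

Rate laws are irreversible:

- `MM1` — single-substrate Michaelis–Menten, `v = Vmax·S/(Km+S)`.
- `MM2` — two-substrate random-order ternary-complex double hyperbola,
  `v = Vmax·A·B/((KmA+A)(KmB+B))`.  This is the default bi-substrate form
  (used for the THIC, TH1 and THiM steps); a ping-pong alternative
  `v = Vmax·A·B/(KmB·A + KmA·B + A·B)` is available per reaction as the
  `MM2_ping_pong` law type, since published kinetic data rarely settle the
  mechanism and the two forms differ at sub-saturating co-substrate.
- `mass_action` — `v = k·Π(substrates)`; first-order for transporters.
- `constant_flux` — a state-independent rate, used for feeds and for
  gap-filled steps where no substrate dependence is wanted.

No inhibition, cooperativity, or riboswitch feedback terms are included:
the TDP riboswitch acting on THIC mRNA is a transcript-level control with no
agreed kinetic parameterization, so abundance effects enter only through
Vmax.  Overexpression and knockout are therefore modelled as multiplicative
Vmax scaling (Vmax = kcat·[E]); Km is an active-site property and is left
unchanged.  An enzyme label groups all reactions catalysed by one gene
product, so scaling bifunctional TH1 moves its kinase and synthase Vmax
together — one gene, one abundance change, two active sites.

## Numerical choices

Integration uses LSODA (adaptive stiff/non-stiff switching) with
`rel_tol = 1e-8` and `abs_tol = 1e-12` nmol/L, suited to trajectories
spanning sub-nmol/L intermediates and mmol/L cofactor pools.  The output
grid is uniform (default 1000 points over 10,000 s) and is evaluated from
the solver's dense interpolant, so refining the grid never changes the
integration.  States in `(-1e-9, 0)` nmol/L — ordinary stiff-solver
excursions — are clamped to zero before rate evaluation; anything below
−1e-9 aborts with a diagnostic naming the metabolite, as do NaN/Inf states.
A Vmax scaled to exactly zero (knockout) silences the reaction rather than
tripping the positivity checks on intact parameters.

**Plateau** is not a sharply defined observable, so the package uses a
trailing-window flatness rule: the quasi-steady level is declared reached
when `(max−min)/|mean|` over the last 10 % of the course falls below 1e-3
(both the window and the tolerance are configuration).  The plateau value is
reported as the window mean; for a genuine plateau this coincides with the
terminal value, and both are exposed.  **Peaks** are the global grid maximum
refined by quadratic interpolation through the neighbouring grid points
(exact for a locally parabolic apex; ties break to the earliest time), and
peak times are also rendered as "Xm Ys".

## Flux-balance gap-filling

Reactions without kinetic constants are flagged `needs_fba` in the tables
(they must then have no kinetic parameters, and vice versa).  Their
steady-state flux is predicted by the LP `maximize c·v` subject to
`N·v = 0` over internal (non-clamped) metabolites and per-reaction bounds,
solved with the HiGHS simplex.  Neither the objective nor the bounds are
biochemically given, so both are explicit configuration with documented
defaults: the objective maximizes gross production of the target metabolite
(default TMP), bounds are `[0, 1]` nmol/L/s with unparameterized transports
capped at 0.05 nmol/L/s in the shipped network.  Each predicted flux `J` is
then converted into an MM1 law on the reaction's first consumed substrate
with `Km = km_default` (10 nmol/L) and `Vmax = J·(Km+S₀)/S₀`, so the rate at
the initial state equals `J` exactly while the step stays responsive to
substrate depletion; `constant_flux` conversion is available per reaction,
and zero flux always becomes a zero constant flux.  A nonzero flux through a
reaction whose substrate starts at zero is unsatisfiable and reported as
such.

## Synthetic networks: what they emulate and what they do not

The **reduced thiamin network** (`make_thiamin_toy`) contains the two
biosynthetic branches, both TH1 activities under one label, and a saturable
TMP drain standing in for everything downstream.  Its constants are fixed in
code, chosen so that the canonical overexpression phenotypes hold: the
thiazole branch carries less flux than the pyrimidine branch (so THIC
overexpression is inert and THI1 overexpression gives a bounded sustained
rise), the drain is slow relative to a 100-fold TH1 burst (so TH1
overexpression overshoots transiently and relaxes once the precursor pools
are spent), and only the triple overexpression lifts the input flux itself.
These are qualitative reproductions of the known system behaviour; the toy's
absolute concentrations are not calibrated to any measured rice values.

The **full-size synthetic rice network** (`make_rice_network`, also shipped
as TSV tables under `data/rice_b1_synthetic/`) has the published pathway
topology — de novo synthesis in the plastid, TH2 in cytosol and
mitochondrion, TDPK and THiM salvage in the cytosol, the TDP carrier, and
external exchange — at the full census of 34 reactions and 29 metabolites,
with five transports left unparameterized to exercise gap-filling
end-to-end.  Every numeric parameter is an invented, plausible value chosen
once: feed pools carry first-order consumption so that all relaxation times
fit inside the 10,000 s horizon, and initial concentrations start near the
unperturbed steady state.  Consequently its simulated numbers characterize
the package, not rice; conclusions about real tissue require measured
kinetic constants in the same table schema.

Synthetic **growth curves** are logistic,
`OD(t) = K/(1+((K−x₀)/x₀)e^{−rt})` with K = 1.5, x₀ = 0.05, a reading every
30 min for 3 days, plus i.i.d. Gaussian noise on OD (σ = 0.01, floored at
0).  They emulate plate-reader output in shape and schema but not its real
error structure (autocorrelated drift, evaporation, lag-phase variability),
so passing tests demonstrate estimator correctness under the stated noise
model, not robustness to every instrument artifact.

## Growth-rate estimation

OD series are natural-log transformed and the growth rate is the OLS slope
of ln(OD) against time over the detected exponential window.  Window
detection uses the "easy linear" rule: a window of 10 consecutive readings
slides along the series, and the exponential phase is the window with the
steepest slope among those with `R² ≥ 0.95` and positive slope.  The
flatness-style alternative (longest high-R² run) was evaluated and rejected:
on saturating curves it drifts into the deceleration or stationary phase,
where ln(OD) is almost perfectly linear but no longer exponential, and
under realistic noise a hard `R² ≥ 0.99` gate excludes precisely the early
windows that are genuinely exponential (their R² sits near 0.96–0.98 when
relative noise is highest at low OD).  On a pure exponential every window's
slope equals the true rate, so the estimate is exact and independent of the
sampling interval; on the synthetic logistic benchmark the recovered rate is
within 10 % of the generating rate.  A series with no qualifying window —
flat, or noise-dominated — yields an explicit "no exponential phase" result.
The chosen window bounds and R² are always reported so alternatives can be
audited.  Group comparison is one-way ANOVA followed by Tukey's HSD, with
significance tiers at P < 0.05 and P < 0.01; all-identical degenerate input
is reported as P = 1 rather than a numerical error.

## Problem sizes and determinism

Default runs integrate 10,000 s with 1000 output points; a full-network
simulation takes well under a second, and the complete overexpression scan
a few seconds.  The verification suite integrates toy networks against a
fixed-step RK4 oracle at dt = 1e-3 s over short horizons, enumerates LP
vertices exhaustively on ≤ 5-reaction toys, and uses 30–100 logistic
replicates for growth-rate recovery.  All generators are pure functions of
their arguments and a seed; simulations are deterministic, and the only
stochastic inputs anywhere are the synthetic growth-curve noise draws.

## Known limitations

- Irreversible rate laws only; reversibility must be expressed as paired
  opposing reactions.
- No volumes or concentration conversion between compartments.
- The FBA objective/bounds defaults are modelling assumptions, not data;
  gap-filled kinetics inherit them.
- No parameter estimation from time-course data, and no stochastic (SSA)
  simulation — the dynamics of interest are deterministic plateaus and
  transients at nmol/L scale, where copy-number noise is not represented.
- The SBML layer covers the constructs these models use (compartments,
  species, reactions, MathML kinetic laws with local parameters, plus a
  package annotation recording the law type); arbitrary third-party SBML
  with other constructs (events, rules, function definitions) is out of
  scope and rejected explicitly.
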