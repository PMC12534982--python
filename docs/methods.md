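# Methods

## Network model and curation

A model is a list of metabolites and reactions with signed stoichiometry,
flux bounds in mmol·gDW⁻¹·h⁻¹, optional boolean gene–protein–reaction
(GPR) rules and one biomass objective reaction. Reversibility has a single
source of truth: a reaction is reversible iff its lower bound is negative.
Internal indexing is 0-based declaration order; every exported table is
keyed by reaction/metabolite id so external consumers never depend on
order. COBRA-style JSON is the canonical read/write dialect because
fixtures must be hand-writable; SBML Level-3 FBC is supported read-only
(via libsbml, with the conventional `R_`/`M_`/`G_` id prefixes stripped).

Dead-end detection marks metabolites that cannot both be produced and
consumed; a reversible reaction counts as producer *and* consumer of every
participant, which matches the mass-balance notion of a blocked metabolite.
Detection is purely structural (bounds other than the reversibility sign
are ignored), so a temporarily closed uptake (ub = 0) does not spuriously
condemn its metabolite. `prune_dead_ends` removes dead-end metabolites and
all reactions touching them, iterating to fixpoint because each removal can
orphan upstream metabolites; it is idempotent, order-independent, and
refuses to delete the objective reaction. Sink reactions (stoichiometry
{metabolite: −1}) default to reversible bounds [−1000, 1000] so they can
drain or supply their metabolite. The pipeline exposes both curation
orders; the default is prune-then-sink, so sinks are only spent on
metabolites that survive pruning.

## Expression integration

Raw counts are normalized in two steps: per-sample library-size scaling
(to the mean library size), then per-gene division by the gene's mean
across control samples. Control genes therefore average 1, the control
model approximates the γ-scaled baseline, and treated/control fold changes
are directly interpretable. Genes with zero control mean get value 0 and
are flagged rather than silently dropped.

GPR rules are evaluated numerically: a leaf is the gene's value, AND nodes
combine children with `min` (a complex is limited by its scarcest subunit)
and OR nodes with `max` (the best-expressed isoenzyme carries the flux).
`mean`/`sum` variants are exposed for users who prefer
capacity-pooling semantics. Genes missing from a profile evaluate to 1
(neutral) so incomplete annotation never blocks a reaction; every GPR-less
reaction also gets the neutral value, recorded with provenance
`no-gpr-neutral`.

Bound rescaling is multiplicative exactly as stated above (factor
f = γ·expression, default γ = 2). Because f ≥ 0, signs are preserved,
lb ≤ ub is maintained, irreversible reactions stay irreversible and
expression 0 blocks a reaction. The literal multiplicative form can widen
bounds when γ·expression > 1; an optional `cap_factor` clips f for users
who want bounds that only tighten. Scaling is symmetric in both directions
of a reversible reaction (no directional expression data exists).

## Flux analysis

All LPs are solved with scipy's HiGHS interface at feasibility tolerance
1e-9 with deterministic variable ordering, so repeated runs are
bit-identical on one platform. FBA maximizes the biomass flux subject to
S·v = 0 and bounds. FVA solves the per-reaction min/max problems with
biomass constrained to equal α·f_max (default α = 1); a `biomass_relaxed`
switch turns the equality into ≥, the common practical relaxation (the two
coincide at α = 1, since the optimum cannot be exceeded). The test suite
checks FVA against two independent oracles: naive per-reaction LP
enumeration and cobrapy's FVA running on GLPK.

Differential flux summarizes each condition's FVA interval by its midpoint
(the extremes are exported alongside so users can re-derive alternatives),
averages midpoints across samples within a condition, and reports
fold_change = treated/control with a sign guard ε = 1e-6 × (largest
absolute bound). Entries with |control midpoint| < ε are flagged
`near-zero-denominator`; entries whose ratio would be non-positive (the
flux changes sign between conditions) are flagged `sign-change`; only
`ok` rows carry a log2 fold change and enter rankings.

## Knockout analysis

A gene knockout disables every reaction whose GPR evaluates false with
that gene removed. MOMA predicts the post-knockout flux state as the
feasible point minimizing Σ(v_i − ref_i)² with disabled reactions clamped
to zero; the reference is the source-condition FBA solution. The QP is
solved with SLSQP and then polished by solving the KKT system on the
detected active bound set, which recovers machine-precision optima on the
small models this package targets (an LP-based L1 variant was considered
and rejected: the quadratic objective is what makes the prediction unique).

The transformation score compares source (treated) and target (control)
FVA midpoints. Per reaction, the desired direction is sign(target −
source) with a dead band τ (default 1e-3 × largest absolute bound, so
noise-level changes never count); the achieved change is prediction −
source. Successes add and violations subtract weights |target − source| /
Σ|·|; reactions inside the dead band weigh 1/n and succeed when the
prediction also stays within τ. A knockout reproducing the target exactly
scores 1 on the moving reactions; one moving everything adversely scores
−1. The robust score is the minimum over the MOMA-based and FBA-based
scores — the worst-case principle of robust metabolic transformation
analysis, deliberately simplified (outputs are labelled simplified-rMTA;
the published bTS/wTS weighting is not reproduced). Ranking is by robust
score descending with lexicographic tie-breaks; infeasible knockouts are
reported separately with a −∞ sentinel.

## Kinetics

Dose–response fitting uses V = V_max/(1 + (I/IC50)^h), parameterized in
(V_max, log₁₀ IC50, log h) so positivity is structural, initialized from
the interpolated half-maximal crossing on the log-concentration axis, and
solved by Levenberg–Marquardt least squares. I = 0 rows anchor V_max (the
model evaluates to V_max there) but live off the log grid. The slope h is
free by default. Fits are declared non-converged — never silently wrong —
for flat data (activity span below 5% of the maximum) or when the fitted
IC50 lands more than three decades outside the measured concentration
range.

Mode classification uses the apparent-IC50 trend across substrate levels:
fold shift = IC50(S_high)/IC50(S_low), with a 25% dead band (typical
inter-assay IC50 variability) separating competitive (rising), uncompetitive
(falling) and indeterminate. For a competitive call with K_m supplied, K_i
is the mean of per-point Cheng–Prusoff values IC50/(1 + S/K_m). K_m is
always an explicit input, never defaulted: published K_m values for DHODH
differ between enzyme constructs, and silently picking one would bias K_i.

Melt curves must have ≥ 10 strictly increasing temperatures. The default
Tm method smooths the 350/330 ratio with a Savitzky–Golay filter spanning
about 2.5 °C, takes the first derivative, requires its peak to be interior
and at least 3× the median absolute derivative (a flat or purely linear
curve fails this and raises "no transition detected"), and refines the
peak as the vertex of a local quadratic over ±2 °C. The Boltzmann method
fits a two-state sigmoid with linear pre- and post-transition baselines,
initialized from the derivative estimate. ΔTm = Tm(holo) − Tm(apo), signed
so stabilization is positive.

## Synthetic data

The toy network is hand-specified (18 reactions, 17 metabolites) so every
expectation used in tests has a closed form. Design choices worth noting:

- Biomass consumes UMP directly (plus an ATP proxy, glutathione, and a
  small citrate demand when the corresponding branches are on); the
  nucleotide phosphorylation steps above UMP are lumped away to keep the
  network small, since they carry no independent information at steady
  state.
- UMP synthase (capacity 5) is deliberately tighter than DHODH (capacity
  10), so in the control state the de novo branch overproduces orotate
  into its drain — giving the orotate sink a nonzero control flux whose
  collapse under DHODH knockdown is detectable.
- The built-in orotate sink is drain-only (lb = 0). Generic sinks default
  to reversible, but a supplying orotate sink would bypass DHODH entirely
  and erase both the knockdown signature and the salvage-rescue contrast;
  drain-only keeps de novo (or salvage) flux the sole pyrimidine source.
- The uridine salvage branch (uptake capacity `salvage_ub`, default 0)
  reproduces the rescue logic: with salvage closed a DHODH knockout is
  lethal, with salvage open biomass survives.
- All eleven metabolites of the curated sink list (dihydroorotate,
  orotate, glutamine, pyruvate, citrate, NAD, NADH, aspartate, acetyl-CoA,
  ubiquinol, ubiquinone) are present, so sink-insertion workflows can be
  exercised on the toy.

Expression profiles are lognormal around 1 (control) or around the gene's
multiplicative effect (treated), parameterized so the arithmetic mean hits
the target and the CV equals `noise_cv`. The study conditions emulated by
the defaults are three biological replicates per condition, a 5-fold
DHODH knockdown (effect 0.2) and 10% expression CV. Assay tables come from
the competitive rate law v = V_max·S/(K_m(1 + I/K_i) + S) or its
uncompetitive counterpart v = V_max·S/(K_m + S(1 + I/K_i)) with
multiplicative lognormal noise (2% CV in the simulated assays); the
simulated enzyme uses K_i = 1.5 µM and K_m = 100 µM, a literature-typical
Michaelis constant for DHO. Melt curves are two-state sigmoids with linear
baselines and additive gaussian noise; 0.002 ratio units is used as the
instrument-level noise (nanoDSF ratio traces are very clean), with apo and
holo midpoints 55.7 °C and 59.2 °C (ΔTm 3.5 °C). Default seed 20250233;
every generator is a pure function of configuration and seed.

What the generators do *not* emulate — and hence what passing tests do not
show: transcriptome-wide covariance structure, mapping/quantification
noise in real RNA-seq, genome-scale model degeneracy (alternate optima are
far more prevalent in 10,000-reaction models), tight-binding inhibition
(where IC50 ≈ enzyme concentration and Cheng–Prusoff is biased), and
aggregation artefacts in melt curves.

A separate random-model generator produces small feasible stoichiometries
(every reaction admits zero flux, so v = 0 is always feasible) purely for
oracle fuzz tests of FVA and MOMA.

## Pipeline

Differential flux executes curate → constrain → per-sample FVA →
within-condition aggregation → fold change; the knockout screen builds
condition-representative models by averaging per-sample bounds, uses the
treated model as the source state and control as the target. Problem sizes
throughout the tests and the acceptance script (18-reaction toy, 100
random ≤ 8-reaction models, 100 kinetics fits) were chosen so the full
suite completes in well under a minute while still exercising every code
path; all stages are deterministic given config and seed, and each run
directory carries a metadata JSON with the config hash, seed, version and
the simplified-rMTA label.

## Known limitations

- FVA midpoints are a summary statistic; two conditions with identical
  midpoints but different range widths fold-change to 1.
- The equality biomass constraint at α = 1 can make FVA infeasible on
  models with numerically marginal optima; use the relaxed form there.
- MOMA via SLSQP targets small/medium models; genome-scale MOMA would
  need a dedicated sparse QP solver.
- The robust score is a two-engine worst case, not the published rMTA
  statistic; rankings agree qualitatively on transparent cases but are
  not numerically comparable to rMTA outputs.
- Condition aggregation averages bounds (knockout screen) or FVA ranges
  (differential flux) across replicates; heteroscedastic replicates are
  not down-weighted.
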