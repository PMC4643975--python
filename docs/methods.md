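# Methods

## The problem

Genome-scale metabolic models of the same organism differ in two
conceptually distinct ways: in the underlying *reconstruction* (which
reactions, metabolites and gene associations are believed to exist) and
in the *model parameters* chosen to make that reconstruction simulable
(medium composition, biomass objective, reference phenotype lists).
When two models disagree, naive benchmarking cannot say which layer is
responsible. `gemscreen` standardizes the parameter layer so that
differences in predictive behaviour can be attributed to the
reconstruction: the same medium is imposed on every model, a common
biomass objective is substituted where the model's metabolites allow
it, and the same reference gene lists are used for scoring.

## Flux balance analysis

Every simulation is a linear program over the flux vector v:

    maximize    v_biomass
    subject to  S v = 0          (steady state, non-boundary metabolites)
                lb <= v <= ub    (reaction bounds; uptake = negative
                                  lower bound on an exchange reaction)

Boundary metabolites (the `_b` species closing exchange reactions in
COBRA-convention files) are excluded from the steady-state constraint;
this is exactly what allows exchanges to carry net flux. All LPs are
solved with HiGHS through `scipy.optimize.linprog`, which is
deterministic for a fixed problem. Genome-scale LPs have alternate
optima; only objective values and one-norm-minimal norms are treated as
contractual, never the fluxes of a particular optimal vertex.

One-norm-minimised FBA re-solves with the biomass flux pinned to its
optimum and minimises the total absolute flux via split
positive/negative variables. Internal loops that carry no benefit to
the objective are driven to zero, which is what makes the high-|flux|
ranking of `diagnose_high_flux_reactions` a usable loop detector: a
reaction that still carries an enormous flux in the one-norm-minimal
solution is being *forced* to, typically by a thermodynamically
implausible shortcut that inflates the biomass optimum.

## Deletion screens and scoring

Gene deletions act through boolean gene-protein-reaction (GPR) rules:
`and` joins complex subunits, `or` joins isozymes, `and` binds tighter
than `or`. A reaction whose rule evaluates False under a deletion set
gets bounds (0, 0). A gene is predicted **essential** when the mutant's
maximum biomass flux falls below `essentiality_threshold` (default
1e-6 flux units; infeasible LPs score as zero flux and hence
essential — a model that cannot balance at all certainly cannot grow).

A pair of individually dispensable genes is predicted **synthetic
lethal** when the double mutant's flux is at or below
`sl_wildtype_fraction` (default 0.10) of the wild-type flux; the
boundary is assigned to lethal, i.e. "non-lethal" means strictly more
than 10% of wild type. Double screens run on the model's own default
medium and biomass: pairwise interaction benchmarks are conventionally
reported on models as distributed, and the quadratic cost discourages a
full grid. Pair records stream to a TSV checkpoint and a rerun resumes
after the last finished pair.

Agreement with a reference list is summarised by the Matthews
Correlation Coefficient,

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with the **positive class = non-essential (viable)**: a true positive
is a gene predicted viable and annotated viable; a gene correctly
predicted essential is a true negative. When any marginal sum is zero
the MCC is undefined and this package returns 0 (logged). Cross-
condition aggregation pools the counts first and takes the MCC of the
summed matrix — the mean of per-condition MCCs is a different statistic
and is deliberately not reported. Counts are combined in exact integer
arithmetic up to the final square root.

For double screens, a reference pair whose genes are not both
individually-dispensable in the screen is an "other error" (the single
screen already made the mistake) and is excluded from the MCC; reference
pairs naming genes outside the model are tallied `out_of_scope`.

## Structural statistics

**Blocked reactions** are those whose flux-variability range is within
`BLOCKED_TOL` (1e-6) of zero when *all* exchange reactions are opened to
±1000 — blockage due to network structure, not medium. FVA imposes no
objective-fraction constraint (the biomass reaction is present but not
fixed); an optional fraction parameter exists for users who want
optimum-conditioned ranges.

**Dead-end metabolites** are purely structural, independent of exchange
bounds and biomass: a metabolite is a dead end if it participates in
exactly one reaction, or if, considering reaction reversibility, it can
only ever be produced or only ever be consumed. Both clauses are
implemented and `dead_end_details` reports which clause fired per
metabolite, because published phrasings of the definition differ subtly
and consumers may want to distinguish them.

## Scope comparison

Each model is reduced to a binary vector over the union of gene
identifiers (or of ChEBI metabolite identifiers, taking the FIRST
identifier when a metabolite carries several; unannotated metabolites
are excluded, so the metabolite comparison is inherently less
comprehensive). Pairwise distances between vectors (euclidean default;
hamming and jaccard available) feed average-linkage agglomerative
clustering (single/complete available) and classical Torgerson MDS
(double-centred squared-distance matrix, eigendecomposition,
coordinates by decreasing eigenvalue; non-positive eigenvalues are
truncated with a warning). Euclidean-on-binary with average linkage
matches the defaults of the MATLAB pdist/clustergram stack this kind of
analysis is traditionally run on; both are exposed as parameters since
neither choice is canonical. Cluster *counts* at a given cut height are
treated as observations, not contracts — they are cut-dependent.

## Standardization parameters

- **Medium** (`MediumDefinition`, YAML): component key -> (lb, ub) on
  the matching exchange; keys resolve by exchange reaction id, then
  exchanged-metabolite id, then ChEBI id. Applying a medium first
  closes every exchange uptake, then opens exactly the listed
  components; per-model `supplements` reopen extra exchanges for models
  that otherwise cannot grow. "Unconstrained" is magnitude 1000 (COBRA
  convention); the default constrained glucose uptake is 10 mmol/gDW/h,
  a conventional magnitude echoed in report headers — published
  descriptions of such media typically say "constrained" without a
  number, so the value is a config field, not a constant.
- **Biomass** (`BiomassDefinition`, YAML): metabolite key -> signed
  coefficient (negative = consumed). Substitution closes the old
  objective reaction (so it cannot act as a free drain) and installs a
  new one; any unresolvable component aborts with the full missing
  list. A model that cannot express the common biomass is *excluded*
  from common-biomass comparisons, never silently approximated.

Media application and biomass substitution commute, and both are
idempotent; these are asserted properties, not assumptions.

## The synthetic-data generator

Real model collections cannot ship with this package, so every analysis
stage is validated on generated toy models whose correct answers are
wired into the topology (never computed by the LP machinery under
test):

- `n_linear_pathways` chains of `pathway_length` irreversible steps
  each feed one required biomass precursor; a chain step's sole gene is
  essential by construction.
- complex steps (AND over two genes) plant essential gene pairs;
- isozyme steps (OR over two genes) plant synthetic-lethal pairs whose
  members are individually dispensable;
- bypassed steps gain a gene-free duplicate reaction, making their gene
  dispensable without creating new lethal pairs;
- a dead-end unit `M -> D` plants one dead-end metabolite and one
  blocked reaction; a blocked unit `M -> Z -> W` plants two blocked
  reactions whose inner metabolite is *not* a dead end. Any strictly
  terminal construct must end in a dead end — steady state forces its
  producing chain to zero flux — so the truth sets record the actual
  planted ids rather than pretending the counts are independent.

Default scale is ~58 genes / ~65 reactions: every rule type is
exercised and a full double screen (~1.6k LPs) finishes in seconds.
Generation is a pure function of the spec; the same seed yields
byte-identical files.

What the toys do **not** emulate: real network topology (hub
metabolites, cofactor coupling, compartment transport chains),
realistic GPR depth, degenerate alternate-optima structure at scale, or
annotation noise in identifiers. Passing the toy-based suite therefore
demonstrates correctness of the decision rules, scoring arithmetic and
LP mechanics — not predictive performance on real reconstructions,
which requires the published model files as inputs.

Noisy reference lists flip each truth label independently at
`flip_rate`; the expected MCC of a perfect predictor against such a
list has the closed form

    n_v n_e (1-2p) / sqrt(n_v n_e (n_v(1-p)+n_e p)(n_e(1-p)+n_v p))

(n_v viable, n_e essential truth genes), which reduces to 1-2p for a
balanced truth. The simulation-vs-closed-form agreement (200 seeds,
3-standard-error band) is part of the acceptance checks; it calibrates
how much measured-MCC degradation is attributable to reference-list
noise alone.

Growth observations are emulated as the FBA optimum under a constraint
grid scaled by truncated Gaussian noise N(1, noise_sd). At 5% noise
and 20 grid points the mean Pearson correlation stays above 0.99 —
which is exactly why high single-constraint correlations on real data
should not be over-interpreted: in the single-limiting-nutrient regime
the response is linear and almost any stoichiometry fits.

## Numerical choices

- `FEAS_TOL` = 1e-9 (solver feasibility scale); `BLOCKED_TOL` = 1e-6,
  on the same scale as the essentiality threshold, so "cannot carry
  flux" and "cannot grow" are judged comparably.
- One-norm minimisation first tries exact equality to the FBA optimum
  and falls back to a 10*FEAS_TOL relaxation if the equality-constrained
  problem is numerically infeasible.
- Unbounded FBA is reported as a status, never clamped; growth scans
  refuse to compute a correlation over scan points with unbounded
  optima (an artificial large value would fabricate a correlation).
- Ties in the high-flux ranking break lexicographically by reaction id;
  pair enumeration is lexicographic with `gene_a < gene_b`.
- Exchange detection is recomputed, never trusted from input: a
  reaction touching exactly one non-boundary metabolite, or with an
  `EX_`/`R_EX_` id prefix. Consequence: a biomass drain consuming a
  single metabolite is structurally an exchange and is excluded from
  "internal reaction" rankings.

## Known limitations

- No quadratic objectives, loopless-FBA MILP, or thermodynamic
  constraints; the one-norm heuristic suppresses only loops that carry
  no objective benefit.
- No gap-filling, no annotation lookups, no nomenclature translation:
  gene ids are opaque case-sensitive strings, so models using
  incompatible gene naming cannot be screened against ORF-based
  reference lists (they can still be compared structurally).
- Compartment labels are carried but not canonicalized; models that
  name compartments differently will not be reconciled.
- `.mat` model files are out of scope; convert to SBML or the flat TSV
  dialect first.
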