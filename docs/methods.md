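# Methods

## Object model

A `Model` holds id-keyed, insertion-ordered collections of `Reaction`,
`Metabolite` and `Gene` records with explicit mutual awareness: every
metabolite carries the set of reactions whose stoichiometry mentions it,
every gene the set of reactions whose GPR rule mentions it. These
backreferences are maintained by the registration operations
(`add_reactions`, `remove_reaction`) and verified exhaustively by
`validate_model`, which cross-scans all reaction records.

Design choices where the design was genuinely open:

- **Reversibility is derived, never stored.** A reaction is reversible iff
  `lower_bound < 0`. The Toolbox `rev` flag is emitted as `lb < 0` on write
  and ignored on read, keeping a single source of truth.
- **Default bounds** follow the COBRA convention: irreversible
  `[0, 1000]`, reversible `[−1000, 1000]`, in mmol·gDW⁻¹·h⁻¹. The
  magnitude 1000 is conventional, not infinite, and is never promoted to a
  solver infinity — an unbounded LP status can only arise from explicitly
  infinite bounds.
- **Boundary reactions are defined structurally**: exactly one metabolite
  in the stoichiometry. Medium application refuses ids that do not satisfy
  this.
- **Insertion order is canonical** everywhere (matrix rows/columns, report
  rows), making all outputs deterministic.
- **The objective lives per reaction** (`objective_coefficient`), not as a
  model-level expression.
- Ids are case-sensitive opaque strings; the compartment is a separate
  metabolite field (formats encode it in ids; see I/O below).

## GPR rules

Grammar: identifiers (letters, digits, `._-`, covering locus tags such as
`STM1234` or `b0008`), case-insensitive `and`/`or` (with `&`/`|` accepted
as Toolbox-dialect synonyms), parentheses; `and` binds tighter than `or`.
Identifiers equal to keywords are disallowed. Same-kind operators are
flattened into n-ary nodes, so structural equality is insensitive to
redundant parenthesization and `parse(format(expr))` is the identity on
trees. The empty rule denotes a spontaneous reaction and always evaluates
true — no deletion can close it. Because the grammar has no negation,
evaluation is monotone: enlarging the deleted set can only flip rules from
true to false, which makes deletion objectives monotonically non-increasing
and the screens well-defined. The Toolbox index dialect (`x(1) & x(2)`) is
translated to id form against the model's gene list on read and emitted
alongside `grRules` on write.

## Linear programming

`build_lp` emits one variable per reaction with its bounds, one equality
row per metabolite (right-hand side 0; the constraint matrix is exactly the
model's stoichiometric matrix in insertion order) and the per-reaction
objective. Backends normalize status to
{optimal, infeasible, unbounded, failed}. Two are registered: HiGHS through
`scipy.optimize.linprog` (default) and GLPK simplex through swiglpk; any
adapter implementing `available()`/`solve()` can be registered by name, and
priority order is configurable (`tolerance` and `solver_priority` via a
YAML or key=value file).

The contract across backends covers the optimal objective value and
feasibility only — flux vectors are vertices of a generally underdetermined
polytope (alternate optima) and are not comparable. The feasibility and
agreement tolerance is 1e−6 throughout; optimal solutions are verified to
satisfy bounds and `|S·v| ≤ 1e−6` per metabolite.

## Flux analysis

- **FBA** (`optimize`): maximize the objective; errors if no reaction
  carries a nonzero objective coefficient.
- **Media** (`apply_medium`): listed exchanges get the given bounds, every
  other boundary reaction's lower bound is closed to 0, internal reactions
  are untouched; returns a modified copy.
- **FVA** (`flux_variability`): with the added constraint `c·v ≥ f·z*`
  (an inequality, not a pin, so ranges at smaller `f` are supersets),
  minimize and maximize each requested reaction's flux. Default `f = 1.0`;
  an infeasible baseline or `f` outside (0, 1] errors. Unbounded
  subproblems report ±∞.
- **Deletions**: reactions whose GPR evaluates false under the deleted set
  are closed (`lb = ub = 0`) in a copied LP — never removed, so indices are
  stable and the input model's bounds are untouched (pure-function
  contract, covered by tests). The double screen computes each unordered
  pair once; the diagonal equals the single screen. When no reaction
  closes, the baseline solve is reused.
- **Essentiality**: a deletion is essential when its objective falls below
  `threshold_fraction × baseline` (default 0.01) or no optimal solution
  exists; classification requires a positive baseline.
- **Parallelism** (`parallel_map`): process-based (fork) with chunk size
  `ceil(tasks/workers)`; results are returned in task order and are
  identical to sequential execution for any worker count. A failing task
  records its error without poisoning the rest. `n_workers=1` is exactly
  the sequential path.

## Reporter metabolites

Gene p-values are clamped to `[1e−15, 1 − 1e−15]` and transformed by
`z = Φ⁻¹(1 − p)` (upper-tail convention: small p → large positive z). A
metabolite with k scored neighborhood genes (the union of genes over its
reactions; unscored genes are ignored, k counts scored genes only) gets
`z_raw = Σ z_g / √k`. For each occurring k, `n_background` size-k gene sets
are drawn **without replacement** from the scored genes present in the
model — the same sampling frame the neighborhoods live in — with a seeded
`numpy` generator; `z_corrected = (z_raw − μ_k)/σ_k` (σ with ddof 0) and
`p_corrected = 1 − Φ(z_corrected)`. Output is sorted by `z_corrected`
descending, ties broken by metabolite id; metabolites with k = 0 are
listed as unscored. A degenerate background (σ_k = 0, e.g. all scores
equal) yields `z_corrected = 0` with a warning. Fixed seed and inputs give
bit-identical results.

Note that on a fixed network the corrected scores are correlated across
metabolites (neighborhoods share genes), so a single score draw estimates
the null mean of `z_corrected` noisily even over many metabolites; the
calibration checks pool the empirical distribution over independent score
replicates on one network before asserting mean ≈ 0 and sd ≈ 1.

## Model I/O

- **SBML**: Level 2 Version 4 in the legacy COBRA notes dialect of the
  pre-FBC repositories (Model SEED / BioModels era): bounds and objective
  in kinetic-law parameters `LOWER_BOUND`/`UPPER_BOUND`/
  `OBJECTIVE_COEFFICIENT`, gene rules in a `GENE_ASSOCIATION:` notes line,
  `SUBSYSTEM:` and `FORMULA:` likewise. The FBC package is out of scope.
  Species ids embed the compartment as a `_<compartment>` suffix, stripped
  on read when it matches a declared compartment; metabolites with no
  compartment are written into a default compartment `c` (and read back
  with compartment `c` — packaged fixtures therefore carry `c` so round
  trips are exact). Species flagged `boundaryCondition="true"` or suffixed
  `_b` are external boundary metabolites: they are dropped from
  stoichiometry, which turns two-sided `A ↔ A_b` exchange notation into the
  one-sided boundary reactions of the object model. Reactions without
  bound parameters default from the `reversible` attribute.
- **COBRA struct (MAT v5)**: the Toolbox parallel-array layout
  (`rxns`, `mets`, `S`, `lb`, `ub`, `c`, `b`, `rev`, `genes`, `grRules`,
  `rules`, plus name/formula/subsystem annotations). Compartments use the
  `id[compartment]` met-id convention; an optional `metCharges` vector
  carries charges so the round trip is loss-free. Missing optional fields
  are tolerated; missing mandatory fields and dimension mismatches raise
  errors naming the field. The MATLAB variable name carries the model id
  (sanitized to a valid identifier).
- **JSON**: loss-free serialization of every model field including media
  definitions; required keys are validated with JSON-path error messages,
  unknown keys are ignored with a logged warning.

All formats round-trip every packaged fixture with bit-exact bounds and
stoichiometric coefficients (all fixture values are exactly representable),
and SBML/struct exports of the same model produce identical matrices.

## Fixtures and synthetic data

The packaged toys keep optima hand-derivable (coefficients ±1, source
bound 10): the **diamond** (two parallel branches, optimum 10, every gene
individually dispensable, branch pairs synthetically lethal), **chain(n)**
(single path, optimum 10, every gene essential, all FVA intervals pinned),
and a **coefficient-2 chain** (A → 2 B, optimum 20) exercising non-unit
stoichiometry. The diamond also exists in exchange convention
(uptake-negative `EX_A`, bounds [−10, 1000]) with a stored `minimal` medium.

`random_model(n_mets, n_rxns, seed)` guarantees feasibility with positive
optimum by construction: a spanning source → chain → sink pathway carries
flux 10, remaining reactions connect random metabolite pairs (30%
reversible) with random GPRs of AND/OR depth ≤ 2 over a gene pool of
`max(3, n_rxns/2)` genes (20% spontaneous). `random_scores` draws uniform
p-values, optionally planting p = 0.001 on one metabolite's neighborhood.

What the generator emulates: sparse connectivity, parallel/looping routes,
isozymes and complexes, exchange-bounded growth. What it does not: realistic
metabolite/reaction degree distributions, mass-unbalanced biomass
compositions, multi-compartment transport, thermodynamic directionality.
Passing tests therefore demonstrate algorithmic correctness at desk scale,
not biological fidelity on genome-scale reconstructions — those are read
through the same I/O paths but their content is external to this package.

## Problem sizes and numerical choices

The verification suite runs at desk scale by choice: random models of ≤ 20
reactions for the FVA/deletion oracle sweeps (25 and 10 seeded models
respectively), 1000-tree GPR round-trip sampling, a 120-metabolite network
with 24 pooled score replicates for reporter null calibration and 20
replicates for planted-signal power (`n_background = 1000`). Tolerances:
1e−6 for all LP-derived comparisons, bit-exactness for I/O and
determinism contracts. Tie-breaks: insertion order for matrices and
reports, lexicographic metabolite id for equal reporter scores.

## Known limitations

Quadratic rerouting objectives (MoMA-style), MILP formulations, SBML FBC,
thermodynamic/crowding constraints, gene-expression coupling and strain
design are out of scope. FVA's retention constraint assumes a positive
optimum (with a negative baseline objective the `≥ f·z*` constraint is the
natural but untested reading). Reaction-deletion (as opposed to
gene-deletion) screens are not provided, though closing bounds by hand and
re-optimizing achieves the same in two lines.
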