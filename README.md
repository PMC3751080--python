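# cobracore

Constraint-based reconstruction and analysis of genome-scale metabolic
networks in Python: an object model for reactions, metabolites and genes;
flux balance analysis (FBA) and flux variability analysis (FVA) over
pluggable linear-programming backends; single and double gene-deletion
screens driven by Boolean gene–protein–reaction (GPR) rules; reporter-
metabolite topology analysis; and model exchange via SBML (legacy COBRA
dialect), COBRA-Toolbox MATLAB structs and JSON.

It is written for systems-biology researchers who work with stoichiometric
reconstructions — predicting growth phenotypes, screening for essential
genes and synthetic lethal pairs, mapping omics signals onto network
topology — and who want those analyses scriptable from Python.

## The model

A metabolic network with *m* metabolites and *n* reactions is a
stoichiometric matrix **S** (m × n). Constraint-based analysis assumes
steady state and bounds each flux:

```
maximize    c · v
subject to  S · v = 0
            lb ≤ v ≤ ub
```

where **v** is the flux vector (mmol·gDW⁻¹·h⁻¹) and **c** selects the
objective, typically a biomass pseudo-reaction whose flux approximates
growth rate. On top of this LP:

- **FVA** re-solves min/max of each reaction's flux subject to
  `c·v ≥ f·z*` (retaining a fraction *f* of the optimum *z**) — the honest
  summary when alternate optima make a single flux vector arbitrary.
- **Gene deletions** evaluate each reaction's GPR rule (`and` = complex
  subunits, `or` = isozymes) under a deleted gene set, close the reactions
  whose rule turns false, and recompute the optimum. The grammar has no
  negation, so deleting more genes can never raise the optimum.
- **Reporter metabolites** aggregate per-gene significance scores over each
  metabolite's reaction neighborhood, `z_raw = Σ z_g / √k`, and correct
  against sampled same-size random gene sets:
  `z_corrected = (z_raw − μ_k)/σ_k`.

Exchange reactions — reactions touching exactly one metabolite — encode the
growth medium through their bounds; a `Medium` maps exchange ids to bounds
and applying it closes every unlisted uptake.

## Worked example

The diamond fixture routes up to 10 units of substrate A through two
parallel gene-catalyzed branches into a sink on D that carries the
objective (`examples/01_build_and_fba.py` builds it from scratch):

```python
>>> from cobracore.fixtures import make_diamond
>>> from cobracore import optimize, flux_variability, double_gene_deletion
>>> model = make_diamond()
>>> sol = optimize(model)
>>> sol.status, sol.objective_value
('optimal', 10.0)
>>> flux_variability(model).ranges["R1"]
(0.0, 10.0)
>>> double_gene_deletion(model).objective(("g1", "g2"))
-0.0
```

The optimum (10.0) equals the source bound: everything taken up reaches the
sink. The FVA range `[0, 10]` for branch reaction R1 shows the two routes
trade off freely at the optimum (alternate optima). Deleting the two branch
genes `g1` and `g2` together drops growth to 0 although each single
deletion is harmless — a synthetic lethal pair.

Each script in `examples/` demonstrates one capability (model building and
FBA, growth media, FVA, deletion screens, reporter metabolites, I/O) and
prints a short interpretation. A thin CLI mirrors the library:

```bash
cobracore fba model.xml --medium medium.tsv
cobracore fva model.xml --fraction 0.9
cobracore deletions model.xml --double --workers 4
cobracore reporters model.xml scores.tsv --seed 0
cobracore convert model.xml model.json
```

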