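"""Build a small metabolic network by hand and run flux balance analysis.

The diamond network routes up to 10 mmol/gDW/h of substrate A through two
parallel branches (A->B->D and A->C->D) to a sink on D that carries the
objective.  FBA maximizes the sink flux subject to steady-state mass balance
and the flux bounds.
"""

from cobracore import Metabolite, Model, Reaction, add_reactions, optimize, validate_model

model = Model(id="diamond", description="two parallel routes from A to D")
mets = [Metabolite(m, compartment="c") for m in "ABCD"]
add_reactions(
    model,
    [
        Reaction("EX_A", {"A": 1.0}, lower_bound=0.0, upper_bound=10.0),
        Reaction("R1", {"A": -1.0, "B": 1.0}, gpr_text="g1"),
        Reaction("R2", {"A": -1.0, "C": 1.0}, gpr_text="g2"),
        Reaction("R3", {"B": -1.0, "D": 1.0}, gpr_text="g3"),
        Reaction("R4", {"C": -1.0, "D": 1.0}, gpr_text="g4"),
        Reaction("EX_D", {"D": -1.0}, objective_coefficient=1.0),
    ],
    metabolites=mets,
)
assert validate_model(model) == []

solution = optimize(model)
print(f"status            : {solution.status}")
print(f"objective (EX_D)  : {solution.objective_value:.4f} mmol/gDW/h")
for rid, flux in solution.fluxes.items():
    print(f"  flux {rid:<6} = {flux:8.4f}")
print()
print("The optimum equals the source bound (10): every unit of A taken up")
print("reaches D, split arbitrarily between the two branches (alternate optima).")
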