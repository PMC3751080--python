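"""Apply a growth-medium definition to a model's exchange reactions.

Exchange (boundary) reactions touch exactly one metabolite; in the usual
convention a negative flux is uptake.  A medium maps exchange-reaction ids
to bounds; applying it closes the lower bound of every unlisted exchange,
so only the listed nutrients can be consumed.
"""

from cobracore import apply_medium, optimize
from cobracore.fixtures import make_diamond

model = make_diamond(convention="exchange")
print("stored media:", list(model.media))

fed = apply_medium(model, model.media["minimal"])
print(f"growth on minimal medium : {optimize(fed).objective_value:.4f}")

starved = apply_medium(model, {})
print(f"growth on empty medium   : {optimize(starved).objective_value:.4f}")

limited = apply_medium(model, {"EX_A": (-2.5, 1000.0)})
print(f"growth with uptake <= 2.5: {optimize(limited).objective_value:.4f}")
print()
print("Growth tracks the allowed substrate uptake: 10 on the stored minimal")
print("medium, 0 with all uptakes closed, 2.5 when uptake is capped at 2.5.")
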