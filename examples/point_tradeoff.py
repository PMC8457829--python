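"""Point-measurement trade-off at the Bicoid configuration.

Builds the SDD model with the boundary at 40% of the system length and a
decay length of 20% (the Bicoid geometry), evaluates cost, positional
error and their product, and compares the gradient's decay length with
the cost-precision optimum.
"""

from morphocost import (
    CostParams,
    SddParams,
    optimal_lambda_point,
    threshold_fraction,
    tradeoff_point,
)

params = SddParams.from_lambda(L=1.0, lam=0.2, jin=1.0)
result = tradeoff_point(params, CostParams(), xb=0.4)

print(f"cost C(xb)                 = {result.cost:.4f} alpha_o (nm = {params.nm:.2f})")
print(f"squared positional error   = {result.precision_sq:.4f}")
print(f"trade-off product (norm.)  = {result.product_normalized:.4f}  "
      "[units alpha_o L/lcell; ~0.6 after rounding]")
lam_min, product_min = optimal_lambda_point(0.4, 1.0)
print(f"optimal decay length       = {lam_min:.4f} L  "
      f"(lambda/lambda_min = {params.lam / lam_min:.3f})")
print(f"product at the optimum     = {product_min:.4f} alpha_o L/lcell")
print(f"threshold fraction         = {threshold_fraction(0.4, lam_min):.3f}  "
      "(boundary forms near 10% of the source concentration)")
print()
print("Reading: with lambda = 0.2 L the Bicoid-like gradient pays only "
      f"{result.product_normalized / product_min:.2f}x the minimal "
      "cost-precision product at its boundary - nearly optimal.")
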