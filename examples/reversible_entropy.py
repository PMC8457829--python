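"""Entropy production of a reversible morphogen gradient.

With every elementary step made bidirectional, the dissipation of the
gradient is a well-defined entropy production rate.  This script computes
the three-way trade-off product S_dot * tau * eps^2 for a driven gradient,
shows that detailed balance gives exactly zero dissipation (and no
gradient), and locates the hop rate (decay length) minimizing the product.
"""

import math

from morphocost import (
    ReversibleRates,
    optimal_hop_reversible,
    tradeoff_reversible,
)
from morphocost.thermo import detailed_balance_rates

rates = ReversibleRates(synth_fwd=100.0, synth_rev=0.2, deg_fwd=1.0,
                        deg_rev=0.05, hop_fwd=9.0, hop_rev=9.0, n_cells=30)
xb = 10.5
r = tradeoff_reversible(rates, xb)
print(f"entropy production rate    = {r.entropy_rate:.2f} k_B/time")
print(f"relaxation time tau(xb)    = {r.tau_rev:.3f} /kd")
print(f"positional error eps^2(xb) = {r.epsilon_rev_sq:.4f}")
print(f"triple product             = {r.product:.2f} k_B")

hop_min, product_min = optimal_hop_reversible(rates, xb)
print(f"optimal hop rate           = {hop_min:.2f}  "
      f"(lambda_min ~ {math.sqrt(hop_min / rates.deg_fwd):.2f} cells, "
      f"lambda_min/xb = {math.sqrt(hop_min / rates.deg_fwd) / xb:.2f})")
print(f"product at the optimum     = {product_min:.2f} k_B")

eq = tradeoff_reversible(detailed_balance_rates(30), xb)
print(f"\ndetailed balance: product = {eq.product}, degenerate = {eq.degenerate}")
print()
print("Reading: a dissipationless (equilibrium) system carries no gradient; "
      "a driven one pays entropy at a rate that, together with speed and "
      "precision, is minimized by a decay length just under half the "
      "boundary distance.")
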