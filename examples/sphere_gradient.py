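"""Morphogen gradient on a spherical surface (fish-embryo-like geometry).

Solves diffusion-depletion on a sphere with a polar source cap, checks
production/degradation balance, and evaluates the generalized trade-off at
a boundary a few decay lengths beyond the cap edge.
"""

import math

import numpy as np

from morphocost import (
    CostParams,
    SphereSpec,
    sphere_conservation_residual,
    steady_state_sphere,
    tradeoff_geometry,
)

spec = SphereSpec(R=30.0, theta0=math.pi / 3, D=4.0, kd=1.0, source_rate=10.0,
                  n_theta=2000)
profile = steady_state_sphere(spec)
print(f"decay length lambda = {spec.lam:.1f}, sphere radius R = {spec.R:.0f}")
print(f"conservation residual (production vs degradation): "
      f"{sphere_conservation_residual(spec):.2e}")

for arc in (0.0, 2.0, 6.0, 12.0):
    theta = spec.theta0 + arc / spec.R
    rho = float(np.interp(theta, profile.x, profile.rho))
    print(f"  arc {arc:>4.1f} past the cap edge: rho = {rho:8.4f}")

theta_b = spec.theta0 + 6.0 / spec.R
r = tradeoff_geometry(spec, CostParams(), theta_b)
print(f"\ntrade-off at arc 6 (theta_b = {theta_b:.3f} rad):")
print(f"  product          = {r.product:.3g} alpha_o")
print(f"  lambda_min       = {r.lambda_min:.2f}  (lambda/lambda_min = "
      f"{spec.lam / r.lambda_min:.2f})")
print(f"  product/minimum  = {r.product / r.product_min:.2f}")
print()
print("Reading: the profile decays exponentially past the cap on arcs short "
      "compared with R; a decay length well above lambda_min marks a "
      "gradient that spends more than the minimal dissipation for its "
      "positional precision.")
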