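"""Use a trichome stalk as a force sensor for insect-triggered ruptures.

The stalk is a truncated-cone cantilever (length L, radii R1 at top and R2
at base) of bending modulus E. An observed tip deflection Δx just before a
thrips-triggered rupture converts to the in-plane force component
F⊥ = 3πE·R1³R2/(4L³)·Δx, and to the full applied force via the contact
angle. Uncertainties on E and L propagate first-order.
"""

import math

from trichomech import (TrichomeGeometry, BendingModulus, cone_stiffness,
                        insect_force)

geom = TrichomeGeometry(L=100.0, R1=5.0, R2=10.0)
modulus = BendingModulus(E=55.0, sigma_E=64.0, n=19)

k_beam = cone_stiffness(geom, modulus.E)
print(f"stalk tip stiffness: {k_beam:.4f} uN/um")

est = insect_force(dx_um=3.70, geom=geom, modulus=modulus,
                   theta_axis_rad=math.radians(20.0))
lo, hi = est.interval
print(f"in-plane component F_perp: {est.F_perp:.3f} uN")
print(f"full insect force F_ins  : {est.F_ins:.3f} +/- {est.sigma_F:.3f} uN")
print(f"1-sigma interval         : [{lo:.2f}, {hi:.2f}] uN")
print()
print("The interval's lower edge clips at zero: the spread of measured")
print("bending moduli (55 +/- 64 MPa over n=19 stalks) dominates the")
print("uncertainty, yet the estimate agrees in order of magnitude with the")
print("directly measured micropipette rupture forces (a few uN).")
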