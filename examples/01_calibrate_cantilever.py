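"""Calibrate a cantilever: thickness from the thermal spring constant,
InvOLS from a synthetic contact curve, and the effective lateral spring
constant k_e that converts lateral photodiode volts into newtons."""

import numpy as np

from fibremech import Cantilever, ContactCurve, calibrate, effective_spring_constant

# geometry of a soft rectangular silicon lever (typical fibre-pulling probe)
lever = Cantilever(width=32.5e-6, length=350e-6, tip_height=15e-6, kn=0.03)

# a synthetic contact curve: flat approach, then a linear in-contact ramp
# whose slope encodes InvOLS = 50 nm/V
dist = np.concatenate([np.linspace(-2e-6, 0, 100), np.linspace(0, 1e-6, 200)[1:]])
defl = np.where(dist > 0, dist / 5.0e-8, 0.0)
contact = ContactCurve(dist, defl, contact_window=(100, len(dist)))

lever = calibrate(lever, contact)
print(f"beam thickness t   = {lever.thickness * 1e6:.3f} um  (from kn = {lever.kn} N/m)")
print(f"InvOLS             = {lever.invols * 1e9:.1f} nm/V (from the contact slope)")
print(f"k_e                = {lever.ke:.3e} N/V")

# the shear modulus of silicon cancels out of k_e: changing G leaves it fixed
doubled_G = calibrate(
    Cantilever(width=32.5e-6, length=350e-6, tip_height=15e-6, kn=0.03,
               G_si=2 * lever.G_si, thickness=lever.thickness, invols=lever.invols)
)
print(f"k_e with G doubled = {effective_spring_constant(doubled_G):.3e} N/V (identical)")

# k_e is what turns a lateral signal into force: at sin(alpha) = 0.5,
# a 1 V deflection means F = 1 V * k_e / (2 * 0.5)
print(f"\n1 V of lateral signal at sin(alpha)=0.5 -> F = {1.0 * lever.ke:.3e} N")
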