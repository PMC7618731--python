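# fibremech

Analysis of single-fibre lateral-pulling force spectroscopy, built for
AFM experiments on fibrin fibres suspended across micro-striated
substrates. The package turns raw instrument traces — time, cantilever
Y-position and lateral photodiode signal — into force, engineering
stress–strain curves and the fibre-level mechanical parameters used to
compare fibrinogen variants, and ships a synthetic fibre + instrument
simulator so every analysis stage can be validated against known ground
truth.

## Who it is for

Researchers doing single-fibre biomechanics with lateral AFM pulling:
continuous pulls to rupture, incremental pulls with stress-relaxation
holds, and cyclic loading protocols. The library is meant to be used
from Python; `examples/` contains one short narrative script per
capability.

## The model

**Calibration.** A rectangular cantilever's thickness follows from its
thermal normal spring constant, `t = (4·k_n·l³/(E·w))^{1/3}`, and the
effective lateral spring constant that converts lateral volts to newtons
is

    k_e = E·w·t³·InvOLS / (6·l²)    [N/V]

where InvOLS is the contact-curve slope inverted. The silicon shear
modulus cancels out of `k_e` exactly.

**Mechanics.** A fibre spanning a well of half-width *a* = 5 μm pulled
laterally by *d* has half-length `L' = √(a² + d²)`, engineering strain
`ε = (L' − a)/a`, and carries the force `F = L_v·k_e/(2·sin α)` with
`sin α = d/L'`. Engineering stress divides by the elliptical
cross-section `A = π·h·w/4` measured on the ruptured ends.

**Continuous pulls.** Each stress–strain curve yields rupture stress,
extensibility (strain at rupture), toughness (∫σ dε), a low-strain
modulus (fit on ε ∈ [0.1, 1.5]), a pre-rupture modulus (final 0.3
strain), and a smoothed tangent-modulus curve.

**Stress relaxation.** Hold-phase decays are decomposed as

    σ(t) = σ₀ + σ₁·e^{−t/τ₁} + σ₂·e^{−t/τ₂},   τ₁ < τ₂

the generalized Kelvin picture (spring in parallel with two Maxwell
arms, viscous moduli μᵢ = Eᵢ·τᵢ). The elastic proportion `E₀/E_max` and
the fast-relaxation contribution `E₁/(E₁+E₂)` are ratio metrics that are
independent of the spring-constant and cross-section calibration.

**Cyclic loading.** After drift correction anchored on zero-strain
dwells, each pull/release cycle yields a characteristic strain (first
crossing of 0.05 MPa — a permanent-elongation proxy), Loss%
(work lost relative to the step's first pull) and hysteresis area%.

## Worked example

```sh
python examples/02_pull_to_rupture.py
```

prints, for a simulated fibre with a 2 MPa low-strain modulus stiffening
to 8 MPa and rupturing at strain 2.65 (1 % lateral noise):

```
rupture stress   = 9.24 MPa   (stress at the break)
extensibility    = 2.650      (strain at rupture; imposed 2.65)
toughness        = 8.38 MPa    (area under the curve = energy/volume)
modulus 1        = 2.00 MPa    (low-strain slope; imposed 2.0)
modulus 2        = 8.03 MPa    (pre-rupture slope; imposed 8.0)
stiffening ratio = 4.01       (modulus2 / modulus1)
```

The analysis recovers the imposed constitutive parameters; the ratio of
the two moduli quantifies strain stiffening. The other examples cover
calibration (`01`), stress-relaxation decomposition (`03`), cyclic
metrics (`04`) and cohort-level variant comparison with the
normality-gated ANOVA / Kruskal–Wallis policy and ratio-over-WT tables
(`05`).

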