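"""Analyse a single continuous pull to rupture: build the stress-strain
curve, detect rupture, and extract the five headline fibre parameters
(rupture stress, extensibility, toughness, modulus 1, modulus 2)."""

from fibremech import (
    FibreModel,
    Instrument,
    detect_rupture,
    extract_pull_parameters,
    generate_pull_trace,
    tangent_modulus,
    trace_to_curve,
)

instrument = Instrument()  # 10 um wells, 0.1 um/s pull, 10 samples/s
model = FibreModel()       # 2 MPa low-strain modulus, stiffening to 8 MPa near strain 2

trace = generate_pull_trace(model, instrument, seed=11, rupture_strain=2.65)
print(f"trace: {len(trace)} samples, {trace.time[-1]:.0f} s of pulling")

curve = trace_to_curve(trace.y_um, trace.lateral_V, instrument.ke,
                       instrument.cross_section, instrument.well)
curve.rupture_index = detect_rupture(curve)
p = extract_pull_parameters(curve)

print(f"rupture stress   = {p.rupture_stress / 1e6:.2f} MPa   (stress at the break)")
print(f"extensibility    = {p.extensibility:.3f}      (strain at rupture; imposed 2.65)")
print(f"toughness        = {p.toughness / 1e6:.2f} MPa    (area under the curve = energy/volume)")
print(f"modulus 1        = {p.modulus1 / 1e6:.2f} MPa    (low-strain slope; imposed 2.0)")
print(f"modulus 2        = {p.modulus2 / 1e6:.2f} MPa    (pre-rupture slope; imposed 8.0)")
print(f"stiffening ratio = {p.stiffening_ratio:.2f}       (modulus2 / modulus1)")

tm = tangent_modulus(curve)
mid = len(tm.strain) // 2
print(f"\ntangent modulus at strain {tm.strain[10]:.2f}: {tm.tangent[10] / 1e6:.2f} MPa"
      f" | at {tm.strain[mid]:.2f}: {tm.tangent[mid] / 1e6:.2f} MPa"
      f" | at {tm.strain[-1]:.2f}: {tm.tangent[-1] / 1e6:.2f} MPa")
print("(the rise of the tangent modulus along the pull is the strain stiffening)")
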