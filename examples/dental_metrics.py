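"""Dental topographic metrics on a parametric crown family.

Generates synthetic molar crowns with increasing cusp count / relief /
sharpness and prints the three metrics, showing which surface feature each
one responds to: OPCR counts distinct "tools", RFI measures relief, ariaDNE
measures bending (cusp sharpness).
"""

from paleodiv import generate_tooth_mesh
from paleodiv.dtm import compute_ariadne, compute_opcr, compute_rfi

print(f"{'n_cusps':>8} {'relief':>7} {'sharp':>6} | {'OPCR':>7} {'RFI':>7} {'ariaDNE':>8}")
for n_cusps, relief, sharp in [
    (2, 1.0, 1.0),
    (4, 1.0, 1.0),
    (6, 1.0, 1.0),
    (4, 0.4, 1.0),
    (4, 1.8, 1.0),
    (4, 1.0, 0.7),
    (4, 1.0, 1.8),
]:
    mesh = generate_tooth_mesh(n_cusps=n_cusps, relief=relief, sharpness=sharp, face_count=2000)
    opcr = compute_opcr(mesh)
    rfi = compute_rfi(mesh)
    dne = compute_ariadne(mesh, epsilon=0.1)
    print(f"{n_cusps:>8} {relief:>7.1f} {sharp:>6.1f} | {opcr:>7.2f} {rfi:>7.3f} {dne:>8.4f}")

print("\nOPCR rises with cusp count, RFI with relief, ariaDNE with sharpness;")
print("all three are invariant to the crown's absolute size.")
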