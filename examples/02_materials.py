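"""Inspect the soft-tissue material models.

Prints the component material table (Neo-Hookean moduli, the adipose
five-parameter Mooney-Rivlin coefficients, densities), the derived shear
modulus / incompressibility parameters, and the effective small-strain
stiffness of the adipose law with its ratio to the glandular tissue.
"""

import breastfem as bf

table = bf.material_table()
print(f"{'component':12s} {'kind':16s} {'E or C10+C01':>12s} "
      f"{'mu (kPa)':>9s} {'d (1/kPa)':>10s} {'rho (kg/m3)':>12s}")
for comp, m in table.items():
    stiff = m.E if m.kind == "neo_hookean" else \
        m.coefficients["C10"] + m.coefficients["C01"]
    print(f"{comp:12s} {m.kind:16s} {stiff:12.3f} {m.mu:9.3f} "
          f"{m.d_incomp:10.4f} {m.density * 1e9:12.0f}")

e_adipose = bf.small_strain_modulus(table["adipose"])
print(f"\nadipose effective small-strain modulus: {e_adipose:.4f} kPa "
      f"(~{round(e_adipose, 1)} kPa)")
print(f"gland / adipose stiffness ratio: {10.0 / e_adipose:.2f} "
      "(the literature band for normal tissue is 1 to 6.7)")

mu, d = bf.convert_E_nu(10.0, 0.49)
print(f"\nE = 10 kPa, v = 0.49  ->  mu = {mu:.4f} kPa, d = {d:.4f} 1/kPa")
print("mu is the initial shear modulus and d the volumetric penalty "
      "coefficient of the nearly incompressible (v = 0.49) tissue laws.")
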