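"""Can the Na+/H+ exchanger reverse the pH gradient of a tumour?

Estimates the intracellular sodium concentration of cancer tissue from the
2-3 fold total-sodium elevation, then asks whether the inward sodium
gradient yields enough free energy to pump protons out against a reversed
pH gradient (pH_i 7.4, pH_e 6.6).
"""

from fentonflux import (
    SodiumModel,
    TransportSpec,
    coupled_exchange_deltaG,
    feasibility,
    solve_cancer_isc,
)

model = SodiumModel()  # ESC 140, normal ISC 12, volumes 20:80
print(f"normal tissue total sodium: {model.tsc_normal:.1f} mmol/l")

for k in (2.0, 3.0):
    isc_c = solve_cancer_isc(SodiumModel(k=k))
    print(f"k={k:.0f}: cancer ISC = {isc_c:.0f} mmol/l "
          f"({isc_c / 12:.2f}-fold of normal)")

h_out = TransportSpec(1, 0.07, 10.0**-7.4, 10.0**-6.6)  # H+ exported
for label, na_in in (("cancer", 59.0), ("normal", 12.0)):
    na_leg = TransportSpec(1, -0.07, 140.0, na_in)  # Na+ imported
    dg = coupled_exchange_deltaG(na_leg, h_out)
    print(f"{label} (Na+ 140 -> {na_in:.0f}): dG = {dg:+.0f} J/mol "
          f"-> pH reversal {feasibility(dg)}")

# A positive total free energy means the sodium gradient cannot drive the
# proton export, so the exchanger cannot explain the pH reversal in cancer.
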