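"""Net acid production of the reprogrammed metabolisms.

Prints the bundled per-pathway H+/CO2 yields and the proton balance of the
two ATP production routes: fermentation plus hydrolysis acidifies, full
respiration plus hydrolysis is neutral.
"""

from fentonflux import atp_pathway_balance, proton_ledger

for entry in proton_ledger().values():
    h = (f"0 or +{entry.h_plus_alt} H+" if entry.conditional
         else f"{entry.h_plus:+d} H+")
    co2 = f" and {entry.co2:+d} CO2" if entry.co2 else ""
    print(f"  {entry.rm:<36s} {h}{co2} per {entry.per_unit}")

print()
print("ATP cycle proton balance:")
print(f"  Warburg production + 1 hydrolysis:     "
      f"{atp_pathway_balance('warburg', 1):+d} H+")
print(f"  respiration production + 1 hydrolysis: "
      f"{atp_pathway_balance('respiration', 1):+d} H+")
# Only fermentative ATP turnover is a net proton source; this is why the
# Warburg effect can serve as an acidifier while respiration cannot.
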