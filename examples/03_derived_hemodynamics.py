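"""Derived hemodynamic and oxygen-transport indices from raw monitor values.

One animal in deep hemorrhagic shock: low cardiac output, low arterial
pressure, high extraction.  All derived values follow the conventional
formulae documented in ``shockhrv.hemo``.
"""

import shockhrv as sh

rec = sh.HemodynamicRecord(
    hr=140, co=1.8, bw=25.0,          # tachycardic, low output
    map=45.0, cvp=4.0, mpap=22.0, pawp=6.0,
    hb=8.5, sao2=0.97, svo2=0.35,     # low mixed-venous saturation
    pao2=95.0, pvo2=28.0, paco2=38.0, pvco2=49.0,
)
der = sh.derive_all(rec)
flow, ox = der.flow, der.oxygen

print(f"BSA   {flow.bsa:6.3f} m²        (0.09 · 25^(2/3))")
print(f"CI    {flow.ci:6.2f} L/min/m²   SVI {flow.svi:5.1f} mL/beat/m²")
print(f"SVRI  {flow.svri:6.0f} dyn·s·cm⁻⁵·m²   PVRI {flow.pvri:5.0f}")
print(f"CaO₂  {ox.cao2:6.2f} mL/dL      CvO₂ {ox.cvo2:5.2f} mL/dL")
print(f"DO₂I  {ox.do2i:6.0f} mL/min/m²  VO₂I {ox.vo2i:5.0f} mL/min/m²")
print(f"O₂ER  {ox.o2er:6.2f}            CO₂ gap {ox.co2gap:.0f} mmHg")

pp = [38.0, 41.0, 44.0, 41.0, 38.0, 35.0, 38.0, 41.0, 44.0, 41.0, 38.0, 35.0]
ppv = sh.pulse_pressure_variation(pp, [0, 6, 12])
print(f"PPV   {ppv:6.1f} %            (fluid-responsive when elevated)")
print("The high O₂ER, wide CO₂ gap and elevated PPV together read as "
      "hypovolemic circulatory failure.")
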