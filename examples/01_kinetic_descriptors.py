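"""Derive the five mass-transfer descriptors from one weighed sample.

A 20 g apple piece at 20% dry matter is osmotically dehydrated to 18 g
at 25% dry matter.  The descriptors translate that weighing into
dry-matter-basis quantities.
"""

from odkinetics import cr_ratio, solid_gain, true_water_loss, water_content, water_loss

m0, s0 = 20.0, 0.20   # initial mass (g) and dry-matter fraction
m, s = 18.0, 0.25     # after immersion

wc = water_content(s)
sg = solid_gain(s, m, m0, s0)
wl = water_loss(s, m, m0, s0)
wlt = true_water_loss(wl, sg)
cr = cr_ratio(wlt, wl)

print(f"WC   = {wc:.4f} g H2O / g d.m.   (water still held per g dry matter)")
print(f"SG   = {sg:.4f} g / g i.d.m.     (osmotic solute taken up)")
print(f"WL   = {wl:.4f} g / g i.d.m.     (water removed, initial-dry-matter basis)")
print(f"WL_T = {wlt:.4f} g / g d.m.      (water removed per g dry matter actually present)")
print(f"CR   = {cr:.4f}                  (WL_T/WL; near 1 = dehydration with little uptake)")
# The gap between WL and WL_T is exactly the solid uptake: CR*(1+SG) = 1.
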