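"""Theoretical isotope-envelope brackets across the fragment mass range.

The composition of a fragment ion is unknown, so its isotope pattern is
bracketed by three extreme composition models (all-phenylalanine,
averagine, all-aspartate).  The monoisotopic fraction shrinks with mass,
which is why heavier fragments need the +1/+2 peaks to be scored.
"""

from deisograph import envelope_bounds

print(f"{'mass (Da)':>10}  {'mono':^22}  {'+1':^22}  {'+2':^22}")
for mass in (300, 600, 1000, 1500, 2000, 3000, 4000):
    b = envelope_bounds(float(mass))
    cells = [f"{lo:.3f} <= {mid:.3f} <= {hi:.3f}"
             for lo, mid, hi in zip(b.t_min, b.t_mean, b.t_max)]
    print(f"{mass:>10}  {cells[0]}  {cells[1]}  {cells[2]}")

print("\neach cell is min <= mean <= max relative intensity; the mean is the")
print("averagine prediction and the extremes come from the carbon-rich and")
print("oxygen-rich composition models.")
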