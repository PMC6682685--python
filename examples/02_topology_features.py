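"""Persistence barcodes of phantoms with known topology.

A sublevel-set filtration of the masked image grows the pixel set with an
intensity threshold; H0 bars track connected components, H1 bars track
loops.  The annulus phantom has one hole, the double annulus two, so the
H1 bar counts below are the Betti numbers of the figures.
"""

from radiorobust.synthetic import make_tda_phantom
from radiorobust.tda import barcode_polynomial, barcode_stats, cubical_persistence

for shape in ("disk", "annulus", "double_annulus"):
    sp = make_tda_phantom(shape, levels=[0.0, 1.0])
    h0, h1 = cubical_persistence(sp.channels["T1"], sp.mask)
    print(f"{shape:15s} H0 bars={h0.n_bars}  H1 bars={h1.n_bars}  "
          f"H1 intervals={h1.intervals.tolist()}")

sp = make_tda_phantom("double_annulus", levels=[0.0, 1.0])
_, h1 = cubical_persistence(sp.channels["T1"], sp.mask)
print("polynomial features P1..P4:", barcode_polynomial(h1).round(3))
print("statistics (n, births, deaths, lengths):",
      barcode_stats(h1).round(3))
# Two holes filled at intensity 1 give two H1 bars (0, 1): each hole is
# born when its ring completes at threshold 0 and dies when the interior
# fills at threshold 1.
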