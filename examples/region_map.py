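"""ASCII (k, h) region map for a mutation pair.

Regions are labelled by the sign pattern of S_D - theta over the pair's
diagnostic novel genotypes; boundaries are the sign-change contours.
"""

import numpy as np

from sdnetevo import get_pair, region_scan

pair = get_pair("mm+/aA")
k_grid = np.linspace(0.05, 2.95, 60)
h_grid = np.linspace(4.5, 1.7, 12)  # high h on top
labels = region_scan(pair, k_grid, h_grid)

sym = {"I": "1", "II": "2", "III": "3", "IV": "4"}
print(f"regions for {pair.id} (rows: h={h_grid[0]:.1f} down to {h_grid[-1]:.1f}; "
      f"cols: k=0..3)")
for row in labels:
    print("".join(sym[x] for x in row))
print(
    "\nRegion I (lowest k): up-regulation by A is strong enough to feminize\n"
    "every m+ genotype; II: the m+ homozygote alone can be female (the zone of\n"
    "transitions for this pair); III: m+ feminizes only next to f; IV (high\n"
    "k): regulation is too weak to change any genotype's sex - recruitment only."
)
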