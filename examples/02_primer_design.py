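"""Design a PCR primer pair on a polymorphic SSR candidate.

Builds a candidate template (flanks around an (AC)n tract), picks the best
primer pair, and shows that the predicted product length differs between the
two lines by (repeat-count difference) x (motif length) — the length
difference an electrophoretic screen detects.
"""

import numpy as np

from silicomap.primerdesign import design_primers

rng = np.random.default_rng(7)
left = "".join(rng.choice(list("ACGT"), 150))
right = "".join(rng.choice(list("ACGT"), 150))

for count in (10, 12):   # repeat counts of the two lines
    tract = "AC" * count
    template = left + tract + right
    pairs = design_primers(template, (150, 150 + len(tract)))
    best = pairs[0]
    print(f"(AC){count}: left {best.left} (Tm {best.left_tm:.1f} C)  "
          f"right {best.right} (Tm {best.right_tm:.1f} C)  "
          f"product {best.product_length} bp  penalty {best.penalty:.2f}")
# Same flanks -> same primer pair; the 2-repeat difference shifts the product
# by 4 bp, which is what makes the locus scorable as a codominant marker.
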