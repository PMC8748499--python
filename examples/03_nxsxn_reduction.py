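"""Collapse a full penta-nucleotide catalog onto the 96 NxSxN classes.

The NxSxN context keeps the bases two positions up- and downstream of a
substitution and marginalises the immediate neighbours, reducing 1536
penta classes (6x4x4x4x4) to 96 (6x4x4) while widening the motif
footprint.
"""

import numpy as np

from sigdriver.contexts import context_classes_96, reduce_penta_to_nxsxn

rng = np.random.default_rng(0)
penta_counts = rng.poisson(5.0, size=1536)

nxsxn = reduce_penta_to_nxsxn(penta_counts)
print(f"penta classes: {len(penta_counts)}, total mutations {penta_counts.sum()}")
print(f"NxSxN classes: {len(nxsxn)}, total mutations {nxsxn.sum()} (conserved)")

labels = context_classes_96()
top = np.argsort(nxsxn)[-3:][::-1]
for k in top:
    print(f"  {labels[k]}: {nxsxn[k]}")
# Each NxSxN class aggregates exactly 16 penta classes (4 x 4 omitted
# neighbour combinations); totals are conserved by construction.
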