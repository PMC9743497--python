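"""Encode a DNA window as the four feature families the classifier uses.

Shows the genomic-signal-processing encodings on a short sequence, then
the full fixed-shape feature bundle for a 600 bp window.
"""

import numpy as np

from cagetss import (
    dna_walk,
    featurize_peak,
    one_hot,
    paired_numeric,
    tetrahedron,
    zcurve,
)
from cagetss.io_formats import ConservationTrack

s = "ACGTACGTGC"
x, y, z = zcurve(s)
print(f"sequence        {s}")
print(f"Z-curve x (purine-pyrimidine) {x}")
print(f"Z-curve y (amino-keto)        {y}")
print(f"Z-curve z (weak-strong H)     {z}")
print(f"DNA walk                      {dna_walk(s)}")
print(f"paired numeric                {paired_numeric(s)}")
print(f"tetrahedron (first base A)    {np.round(tetrahedron(s)[:, 0], 3)}")

# full bundle around a peak representative on a random genome
rng = np.random.default_rng(0)
genome = {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])}
bundle = featurize_peak(genome, ConservationTrack.empty(), "chr1", 1000, "+")
print("\nfeature bundle shapes for a 600 bp window:")
for name in ("onehot", "gsp", "structural", "conservation"):
    print(f"  {name:12s} {getattr(bundle, name).shape}")

# The cumulative Z-curve/walk signals expose base-composition structure;
# the structural block holds bendability (598 values) and propeller twist
# (599 values) zero-padded to the shared 600 bp spatial length.
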