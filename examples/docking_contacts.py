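"""Count docking models contacting a receptor motif.

Builds a synthetic receptor whose residues 376-382 sit near the origin and
ten synthetic single-chain 'docking models' at planted distances, then
counts how many come strictly closer than 10 Angstrom to the motif.
"""

import numpy as np

from eduscan import AtomSet, ContactParams, ResidueInterval, count_contact_models
from eduscan.docking import model_distances

rng = np.random.default_rng(0)


def atomset(coords, start_res=1):
    coords = np.asarray(coords, float).reshape(-1, 3)
    n = len(coords)
    return AtomSet(np.arange(start_res, start_res + n),
                   np.array(["GLY"] * n, dtype=object),
                   np.array(["CA"] * n, dtype=object), coords)


# receptor: residues 370..430 along a line; the motif 376-382 is near x ~ 6-12
receptor = atomset([[i - 370.0, 0.0, 0.0] for i in range(370, 431)], start_res=370)
reference = receptor.restrict(ResidueInterval(376, 382, "motif"))

# ten models at increasing planted distances from the motif
models = [atomset(rng.normal([9.0, d, 0.0], 0.5, (20, 3))) for d in
          [3, 5, 7, 8, 9, 11, 14, 20, 30, 50]]

d = model_distances(models, reference)
n = count_contact_models(models, reference, ContactParams(cutoff=10.0))
print(d.round(2).to_string(index=False))
print(f"models with min distance < 10 A to the motif: {n} of {len(models)}")
# Clustering of many models below the cutoff marks the motif as a preferred
# interaction site.
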