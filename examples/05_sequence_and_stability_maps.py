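"""Map gait sequence and stability over the fore-aft asymmetry plane.

eps_k is the fore-hind asymmetry of leg stiffness, eps_mu that of body
inertia.  Sequence 5 (fore leg first down, last up) fills the region below
the line eps_mu = a eps_k, Sequence 9 (hind leg first down, last up) the
region above it, and Sequence 1 (simultaneous pair touchdown) survives
only on the line.  A coarse grid is enough to see the structure; use
`quadtrot sweep --map sequence --preset dog --grid 0 0.3 31` for a
publication-resolution map.
"""

import numpy as np

from quadtrot import sequence_map, stability_map
from quadtrot.params import ModelParams

base = ModelParams(mu0=0.62, k0=1.5, kappa=0.2)  # dog base, symmetric
axis = np.linspace(0.0, 0.3, 4)

seq = sequence_map(base, 0.06, axis, axis)
print("sequence id on the (eps_k, eps_mu) grid (rows: eps_mu bottom-up):")
print(seq.pivot(index="eps_mu", columns="eps_k", values="sequence_id")
      .iloc[::-1].to_string())

stab = stability_map(base, 0.06, axis, axis)
print("\nmax Floquet modulus Lambda (dog base is stable everywhere):")
print(stab.pivot(index="eps_mu", columns="eps_k", values="Lambda")
      .iloc[::-1].round(4).to_string())
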