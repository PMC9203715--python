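"""Compute the locomotion-characteristics table for both animal presets.

Everything is dimensionless (lengths in units of the hip half-width D,
time in units of sqrt(D/g), forces in units of total body weight) except
the roll amplitudes, which are reported in degrees.
"""

import pandas as pd

from quadtrot import compute_characteristics, find_periodic, preset

columns = {}
for name in ("dog", "horse"):
    params, z_star = preset(name)
    sym = find_periodic(params.replace(eps_mu=0.0, eps_k=0.0), z_star)
    sol = find_periodic(params, z_star, x_guess=sym.x_star)
    columns[name] = compute_characteristics(sol).to_series()

table = pd.DataFrame(columns)
print(table.round(3).to_string())
print()
print("The fore duty factor exceeds the hind one and the fore leg carries")
print("the larger peak ground reaction force: the stiffer fore legs keep")
print("the heavier front of the body supported longer and harder.")
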