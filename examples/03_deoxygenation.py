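"""Adaptation to a normoxia -> hypoxia switch at t_s = 2 days.

At the switch the ambient oxygen drops 21% -> 2%: the quasi-steady necrotic
radius R_n+ jumps above the actual core, and the shell in between dies at an
accelerating rate while every bulk parameter relaxes to its hypoxia
endpoint.  The outer radius barely moves while the internal structure
reorganises — the signature behaviour of these experiments.
"""

import numpy as np

from spheroidox import solve_deoxygenation
from spheroidox.synthetic import ground_truth_bundle

params, _ = ground_truth_bundle("deoxy_like")
t = np.linspace(0.0, 8.0, 161)
tr = solve_deoxygenation(params, t)

i = np.searchsorted(t, params.t_s)
print(f"at the switch (t = {params.t_s} d): R_o = {tr.R_o[i]:.1f} um, "
      f"R_n = {tr.R_n[i]:.1f} um, predicted R_n+ = {tr.R_n_plus[i]:.1f} um")
print("  -> R_n+ > R_n: the core must grow to catch up with the new oxygen field")

print("\n day   R_o     R_n    R_n+   xi_n   xi_i")
for d in (2.0, 3.0, 4.0, 6.0, 8.0):
    k = np.searchsorted(t, d)
    print(f"  {d:3.0f} {tr.R_o[k]:7.1f} {tr.R_n[k]:6.1f} {tr.R_n_plus[k]:6.1f} "
          f"{tr.xi_n[k]:6.2f} {tr.xi_i[k]:6.2f}")

change = (tr.R_o[-1] - tr.R_o[i]) / tr.R_o[i]
print(f"\nouter radius changes only {100 * change:.0f}% over the six days after "
      f"the switch, while the necrotic fraction climbs to {tr.xi_n[-1]:.2f} — "
      "adaptation is internal, not in overall size.")
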