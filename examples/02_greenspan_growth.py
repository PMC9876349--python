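"""Three-phase spheroid growth in a constant environment.

Solves the Greenspan model with the normoxia-like regression parameters and
prints the trajectory at the experimental sampling days, together with the
closed-form time at which the inhibited region forms.
"""

import numpy as np

from spheroidox import inhibited_onset_time, solve_greenspan
from spheroidox.synthetic import ground_truth_bundle

params, design = ground_truth_bundle("normoxia_like")
print(f"parameters: R_o(0)={params.R_o0} um, s={params.s}/day, "
      f"R_c={params.R_c} um, gamma={params.gamma}, Q={params.Q}")

traj = solve_greenspan(params, np.linspace(0.0, 8.0, 81))
print(f"inhibited region forms at t = {traj.t_inhibited_forms:.3f} d "
      f"(closed form {inhibited_onset_time(params):.3f} d)")
print(f"necrotic core forms at   t = {traj.t_necrotic_forms:.3f} d")

print("\n day   R_o      R_i      R_n    phase")
for d in design.days:
    i = np.searchsorted(traj.t, d)
    print(f"  {d:3.0f} {traj.R_o[i]:7.1f} {traj.R_i[i]:8.1f} "
          f"{traj.R_n[i]:8.1f}   {traj.phase[i].value}")
print("\nradii in um; the phase column shows the i -> ii -> iii progression "
      "as the spheroid outgrows first the waste and then the oxygen supply.")
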