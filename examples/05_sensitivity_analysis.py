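"""Reduced costs and constraint sensitivities along the chemostat curve.

At each growth rate the glucose-limited condition is defined by S_min; a
scaled reduced cost R = (dmu/dq)(q/mu) measures how much growth would gain
from relaxing each amino-acid uptake bound, and a sensitivity score
S = (dmu/dc)(c/mu) does the same for the transporter cap and proteome
budget.
"""

from pcfba import make_toy_pcmodel
from pcfba.analyses import Condition, scaled_reduced_cost, sensitivity_score
from pcfba.simulation import min_glucose_concentration

pc = make_toy_pcmodel()

print(f"{'mu':>5} {'R(arg)':>8} {'R(ala)':>8} {'R(ser)':>8} "
      f"{'S(transporter)':>14} {'S(proteome)':>12}")
for mu in (0.25, 0.5, 0.75, 1.0):
    S, _ = min_glucose_concentration(pc, mu)
    cond = Condition(S=S, label=f"mu={mu}")
    costs = {aa: scaled_reduced_cost(pc, cond, aa).R for aa in ("arg", "ala", "ser")}
    s_t = sensitivity_score(pc, cond, "glucose_transporter").score
    s_p = sensitivity_score(pc, cond, "proteome").score
    print(f"{mu:5.2f} {costs['arg']:8.3f} {costs['ala']:8.3f} "
          f"{costs['ser']:8.3f} {s_t:14.3f} {s_p:12.3f}")

# Arginine carries the only positive reduced cost at low growth rates (its
# bound is the active amino-acid constraint) and loses it once the proteome
# limits growth; alanine and serine track protein demand with slack bounds.
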