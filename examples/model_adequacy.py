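"""Posterior-predictive adequacy check on tip-state proportions.

Simulates trees under a 2-state model and asks whether an 'empirical'
tip-state proportion (here generated by the same process) falls inside the
95% envelope of the simulated proportions.
"""

import trophodiv as td
from trophodiv.simulate import tip_state_proportions

p = td.MusseParameters([0.3, 0.2], [0.05, 0.08], [[0, 0.05], [0.05, 0]])
_, states = td.simulate_musse_tree(
    td.SimulationConfig(p, n_tips=120, root_state=0, seed=8))
empirical = tip_state_proportions(states)
print("empirical proportions:", empirical.round(3))

result = td.adequacy_test(p, n_trees=300, empirical_proportions=empirical,
                          n_tips=120, root_state=0, seed=9)
for i in range(2):
    print(f"state {i}: envelope [{result.envelope_low[i]:.3f}, "
          f"{result.envelope_high[i]:.3f}]  inside={bool(result.inside[i])}")

# Proportions generated by the fitted process should fall inside the
# envelope about 95% of the time; a proportion outside it flags a model
# that cannot reproduce the observed state frequencies.
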