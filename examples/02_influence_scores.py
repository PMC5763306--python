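"""Compute per-sample regulator influence scores.

The influence of a regulator in a sample is a Welch statistic comparing
its activated against its repressed targets: strongly positive means the
activated program is on, strongly negative that it is off.
"""

import coregflux as cf

net = cf.make_planted_network(n_regs=4, n_targets=40, edges_per_target=2,
                              seed=1, p_repressor=0.5)
expr = cf.make_expression(net, n_samples=5, noise_sd=0.2, seed=1)

infl = cf.compute_influence(net, expr)
print("influence matrix (regulators x samples):")
print(infl.round(2))
# Each column condenses the ~40-gene sample into 4 activity scores; the
# regulator rows track the (hidden) regulator states that generated the
# data.  NaN would mark a regulator with too few targets in one class.
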