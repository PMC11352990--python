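"""Build a functional brain network from regional time series.

Simulates a handful of correlated regional signals, computes the Pearson
correlation network and applies Fisher's r-to-z transform.
"""

import numpy as np

from cdonbd import RegionalTimeSeries, fisher_z, pearson_network

rng = np.random.default_rng(0)
shared = rng.normal(size=200)
data = np.stack(
    [
        shared + 0.6 * rng.normal(size=200),  # regions 0 and 1 co-fluctuate
        shared + 0.6 * rng.normal(size=200),
        rng.normal(size=200),  # region 2 is independent
    ]
)
ts = RegionalTimeSeries("demo", data, ["visual", "motor", "frontal"])

r_net = pearson_network(ts)
z_net = fisher_z(r_net)

print("Pearson r (regions 0,1):", round(r_net.values[0, 1], 3))
print("Pearson r (regions 0,2):", round(r_net.values[0, 2], 3))
print("Fisher z  (regions 0,1):", round(z_net.values[0, 1], 3))
print(
    "The co-fluctuating pair shows a strong edge (r ~ 0.7, z ~ 0.9); the\n"
    "independent region stays near zero. Diagonals are fixed at 0."
)
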