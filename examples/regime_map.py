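"""A coarse 2D map of firing regimes over coupling conductance and field.

A miniature version of the study's F-gc-Ve maps: every (gc, Ve) cell is an
independent 7 s simulation classified into one of eleven firing regimes.
"""

from prfield import ModelParams, grid_2d

params = ModelParams(Is=0.0, Id=1.0)
result = grid_2d(params,
                 ("gc", [1.0, 1.7, 2.1, 10.0]),
                 ("Ve", [-15.0, -10.0, -5.0, 0.0, 5.0, 10.0]))

table = result.table.pivot(index="gc", columns="Ve", values="regime")
short = table.map(lambda r: r.replace("_", " ")[:18])
print(short.to_string())

rates = result.table.pivot(index="gc", columns="Ve", values="F_hz")
print("\nfiring rate (Hz):")
print(rates.round(1).to_string())

# Weak coupling keeps the neuron responsive over a wide field range; strong
# coupling (gc = 10) equalizes the compartments and narrows the window.
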