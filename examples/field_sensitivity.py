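"""Map the neuron's sensitivity window to a DC induced electric field.

Sweeps the field amplitude Ve in 1 mV steps at weak coupling
(gc = 1 mS/cm^2) and reports the contiguous range that sustains firing.
Outside it the neuron sits in depolarization block (strong negative fields)
or rests (strong positive fields) and is insensitive to the stimulus.
"""

from prfield import ModelParams, sensitivity_interval, sweep_field

params = ModelParams(gc=1.0, VK=-15.0)
scan = sweep_field(params, range(-30, 21))     # forces Is=0, Id=1 weak DC

interval = sensitivity_interval(scan)
print(f"sensitivity range: [{interval.lower:.0f}, {interval.upper:.0f}] mV")

print("\n Ve (mV)   F (Hz)  regime")
for _, row in scan.table.iloc[::5].iterrows():
    print(f" {row['Ve']:7.0f}  {row['F_hz']:7.2f}  {row['regime']}")

# F rises toward the depolarization-block boundary (the field pushes the
# soma toward its firing ceiling) and falls toward the resting boundary.
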