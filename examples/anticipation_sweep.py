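"""Anticipatory firing improves postsynaptic speed coding.

Thalamic HD cells fire ahead of the heading by their anticipatory time
interval (ATI).  Sweeping a fixed ATI across the whole population (shared
trajectory and tuning draws) shows the readout's speed-coding latency
shrinking and its peak correlation growing with anticipation.
"""

import hd2speed as h
from hd2speed.experiments import ExperimentConfig

cfg = ExperimentConfig(seed=11)  # desk scale: 120 s trajectory, 1000 HD cells
df = h.run_ati_sweep(cfg, [0.0, 25.0, 50.0, 75.0])
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# optimal_lag_ms falls as the ATI compensates the synaptic/membrane
# integration delay, and max_corr rises: anticipation improves both the
# latency and the quality of the postsynaptic speed code.
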