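"""Encode a potential trace into Boolean states and evaluate the gates.

Samples above +2 mV set the ``high`` bit, samples below -2 mV the
``low`` bit; seven logic gates are then evaluated row-wise on the
(high, low) pair — the representation used to read computational
structure out of the analog recordings.
"""

import numpy as np

import protospike as ps

t = np.arange(1, 9) * 1e-4           # 10 kHz sampling
v = np.array([0.0, 0.5, 3.1, 2.0, -2.6, -1.0, 4.2, -3.3])  # mV
trace = ps.VoltageTrace(t, v)

table = ps.boolean_pipeline(trace, ps.ThresholdConfig(threshold_high=2.0,
                                                      threshold_low=-2.0))
print(table.to_string(index=False))
# Rows with neither state set (|v| <= 2 mV) give the resting pattern
# AND=OR=XOR=0, NOT=NAND=NOR=XNOR=1; note the value exactly at +2 mV
# does not count as high (the state requires the threshold be exceeded).
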