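"""Build a thalamocortical stimulation waveform and an emulated response.

The Izhikevich neuron (thalamocortical parameters) is driven with a
constant suprathreshold current; its spike train, rescaled to the mV
range of the stimulation channel, is then passed through a first-order
coupling filter standing in for the physical sample.
"""

import numpy as np

import protospike as ps

params = ps.IzhikevichParams()  # a=0.02, b=0.25, c=-65, d=0.05, v_peak=30
result = ps.simulate(params, input_current=5.0, dt=0.1, duration=2000.0)
print(f"{result.n_spikes} spikes in 2 s; emitted peak {result.v.max():.1f} mV "
      f"(clipped at the +30 mV cutoff)")

stimulus = ps.tc_stimulus(params, 5.0, dt=0.1, duration=2000.0, gain=0.1)
print(f"stimulus peak after gain 0.1: {stimulus.potential.max():.2f} mV")

response = ps.response_emulator(stimulus, coupling_tau=5e-3, noise_rms=0.05, seed=2)
lag = np.argmax(np.correlate(response.potential - response.potential.mean(),
                             stimulus.potential - stimulus.potential.mean(), "full")) \
    - (len(stimulus) - 1)
print(f"response tracks the stimulus with ~{lag * stimulus.sample_interval * 1e3:.1f} ms lag")
# The response is a smoothed, noisy copy of the stimulus: the coupling
# time constant controls how much of each spike survives.
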