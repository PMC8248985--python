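"""Spike-LFP synchronization: analytic PPC recovery and peak detection.

Spikes are phase-coupled to a 40 Hz LFP component with a von Mises
distribution of known concentration kappa. The pairwise phase consistency
(PPC) of the measured spike phases should match the analytic value
(I1(kappa)/I0(kappa))^2, and the four-criterion peak detector should find
exactly one peak whose band contains 40 Hz.
"""

import numpy as np
from scipy.special import i0, i1

from etype_sync.spikelfp import ppc, ppc_spectrum, spike_phases
from etype_sync.synthetic import couple_spikes_to_lfp, gen_lfp, gen_spiketrain

kappa = 1.5
lfp = gen_lfp(120.0, components=((40.0, 1.0),), noise_sd=0.3, seed=1)
train = gen_spiketrain(rate=15.0, duration=120.0, seed=2)
coupled = couple_spikes_to_lfp(train, lfp, f_c=40.0, kappa=kappa, seed=3)

sp = spike_phases(coupled.times, lfp, freqs=np.array([40.0]))
measured = ppc(sp.phases[sp.valid[:, 0], 0])
analytic = (i1(kappa) / i0(kappa)) ** 2
print(f"PPC at 40 Hz: measured {measured:.3f}, analytic {analytic:.3f} "
      f"({coupled.n_spikes} spikes)")

spec = ppc_spectrum(spike_phases(coupled.times, lfp))
for pk in spec.peaks:
    print(f"detected peak at {pk.freq:.0f} Hz, band {pk.band[0]:.0f}-"
          f"{pk.band[1]:.0f} Hz, PPC {pk.ppc:.3f}, band mass {pk.mass:.2f}")
print("The band contains the planted 40 Hz carrier; note the ridge extends "
      "above the carrier because the 5-cycle analysis window leaks a strong "
      "locked oscillation upward in frequency (the 25%-of-range criterion "
      "rejects that shoulder as a separate peak).")
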