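"""Spike-triggered multiunit suppression (SMUM) around planted spikes.

A negative SMUM — less multiunit activity on a neighboring electrode in
the 10 ms after a unit's spikes than before — is the signature of a
locally inhibitory (putative interneuron) unit. We plant a -0.3 target
and recover it through the full analysis path (800-3000 Hz bandpass,
rectification, 5 ms sliding median, per-segment z-scoring).
"""

from etype_sync.mua import mua_envelope, population_smum_test, smum
from etype_sync.synthetic import gen_mua, gen_spiketrain

train = gen_spiketrain(rate=10.0, duration=210.0, shape=8.0, seed=1)
wideband = gen_mua(train, smum_target=-0.3, fs_wb=32000.0, seed=2)
envelope, fs_env = mua_envelope(wideband, 32000.0)
res = smum(train, envelope, fs_env)
print(f"planted SMUM target -0.30, recovered {res.SMUM:+.3f} "
      f"from {res.n_spikes} spikes")
print(f"pre-spike mean {res.MUA_pre:+.3f}, post-spike mean {res.MUA_post:+.3f} "
      "(z-units): surrounding activity drops after this unit fires, "
      "as expected for an inhibitory cell")
p = population_smum_test([res.SMUM] * 20)
print(f"Wilcoxon p of 20 such units against zero: {p:.2e}")
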