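"""Generate a synthetic session and write it in the native on-disk layout.

The layout (trials.csv, units.json, float64 spike/waveform/LFP binaries
with a JSON sidecar) is what every downstream stage reads; ground truth
travels alongside for parameter-recovery studies.
"""

import sys
from pathlib import Path

from etype_sync import rl
from etype_sync.session import Session, load_session, write_session
from etype_sync.synthetic import UnitSpec, build_session, gen_session

out = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("scratch/demo_session")

agent = rl.RlParams(0.5, 0.2, 5.0)
trials, _ = gen_session(agent, n_blocks=5, seed=0)
specs = [
    UnitSpec("broad_0", "B", t2p_ms=0.6, rate=6.0, shape=3.0),
    UnitSpec("narrow_0", "N", t2p_ms=0.22, rate=14.0, shape=1.0, burst_mix=0.2),
]
trace = rl.trial_variables(trials, agent)
trains, waveforms, lfp, gt = build_session(specs, trials, variable=trace.p_choice, seed=1)

session = Session(
    trains=trains,
    lfps=[lfp],
    trials=trials,
    waveforms=waveforms,
    ground_truth={"agent": vars(agent), "units": gt.to_dict("records")},
    duration=trains[0].duration,
)
write_session(out, session)
loaded = load_session(out)
print(f"wrote and re-read session at {out}:")
print(f"  {len(loaded.trials)} trials, {len(loaded.trains)} units, "
      f"{len(loaded.lfps)} LFP channel(s), {loaded.duration:.0f} s")
for t in loaded.trains:
    print(f"  unit {t.unit_id}: {t.n_spikes} spikes at {t.rate:.1f} Hz")
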