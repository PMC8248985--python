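"""End-to-end synthetic reproduction: simulate -> classify -> relate.

Generates one session (task behavior from the Rescorla-Wagner agent plus
five planted unit classes, one of them an interneuron-like class that is
gamma-coupled after the cue on low-certainty trials and fires more when
choice certainty is low), then runs every analysis stage and prints the
planted-vs-recovered report. Takes a few minutes.
"""

from etype_sync.pipeline import RunConfig, run_all

config = RunConfig(
    seed=7,
    n_blocks=12,
    units_per_class=6,
    cluster_n_real=30,
    cluster_k_range=(3, 8),
    n_boot=150,
    fit_starts=3,
)
report = run_all(config)
print(report["markdown"])
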