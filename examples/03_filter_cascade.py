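"""The hard-filter cascade for MHC variant sites.

A simulated 15x call set passes through the four site-level stages:
biallelic/exonic selection, QUAL/MQ/rank-sum hard filters, the mean-depth
rule (threshold = min(target/3, 10), so 5 for a 15x target) and the
allelic-balance rule (mean heterozygote read imbalance > 0.9 removes the
site).
"""

import json

from mhcdepth import (
    FilterProfile,
    default_config,
    run_filter_cascade,
    simulate_calls,
    simulate_truth,
)

cfg = default_config(seed=5, n_regions=1, n_individuals_per_region=10)
truth = simulate_truth(cfg)
calls = simulate_calls(truth, depth=15.0, seed=2)

filtered, report = run_filter_cascade(
    calls, truth.regions(), FilterProfile.mhc(), target_depth=15.0
)
print(json.dumps(report, indent=1))
print(
    f"\n{calls.n_sites} discovered sites -> {filtered.n_sites} retained."
    "\nThe 'failed' tallies show which annotation tripped each removed"
    "\nsite; about 5% of simulated sites carry failing annotations by"
    "\nconstruction."
)
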