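"""How reliable are WGS genotypes at each sequencing depth?

Simulates one population of ten koala-like individuals, genotypes them
once with deep target-enrichment (264x) and once with WGS down-sampled to
each rung of the 0.5-30x ladder, filters both call sets, and prints the
concordance table between the two platforms.
"""

from mhcdepth import default_config, run_depth_comparison

cfg = default_config(seed=42, n_regions=1, n_individuals_per_region=10)
report = run_depth_comparison(cfg)

table = report["concordance"].round(3)
print(table.to_string(index=False))
print(
    "\nEach row compares WGS calls at that depth against the 264x"
    "\nenrichment calls over shared variant sites. At 0.5x most genotypes"
    "\nare missing (missing_wgs); concordance climbs with depth and"
    "\nplateaus past 10-15x, the behaviour that motivates sequencing"
    "\nsurveys at ~30x."
)
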