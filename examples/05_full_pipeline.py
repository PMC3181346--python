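"""Run the whole pipeline and inspect the run report.

Equivalent to `pagenet all --outdir scratch/example_run --seed 1`: simulate,
normalize, cluster (per experiment and ortholog-merged), enrich all eight
comparisons, build and export the association network.
"""

from pagenet import PipelineConfig, run_pipeline

config = PipelineConfig(outdir="scratch/example_run", seed=1)
report = run_pipeline(config)

for stage, info in report.stages.items():
    print(f"{stage}: {info}")
# 'enrich' lists significant-set counts per comparison (the 24h and
# postnatal comparisons carry the extra shared-program sets); 'network'
# gives the node/edge counts of the exported SIF/GraphML files.
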