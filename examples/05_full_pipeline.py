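"""Run the whole analysis end to end and print the report.

Equivalent to `ptcore run --seed 42 --outdir scratch/example_run`.
"""

import ptcore as pt
from ptcore.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(simulate=pt.SimConfig(seed=42))
manifest = run_pipeline(cfg, "scratch/example_run")

print(f"completed {len(manifest['stages'])} stages in "
      f"{manifest['wall_time_s']} s; {len(manifest['outputs'])} output files")
print(open("scratch/example_run/report.md").read())
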