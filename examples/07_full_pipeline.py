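"""Run every stage end to end and inspect the summary.

Equivalent to `whiskvr run-all --seed 11 --out scratch/demo` on the shell;
artifacts (TSV tables, windows.json, summary.json, report.txt) land in the
output directory.
"""

import json

import whiskvr as w
from whiskvr.decoding import DecodingConfig
from whiskvr.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="scratch/demo_pipeline",
    session_config=w.SessionConfig(duration=600.0),
    seed=11,
    n_neurons=30,
    decoding=DecodingConfig(bin_width=0.25, step=0.25, folds=4, resamples=5),
    render_tracks=False,
)
summary = run_pipeline(cfg)
print(json.dumps(summary, indent=1, sort_keys=True))
print("\nartifacts in", cfg.out_dir)
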