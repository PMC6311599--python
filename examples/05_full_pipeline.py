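"""Run the whole pipeline (synth -> select -> link -> anchors -> summarize).

Writes every artifact (episode tables, attrition, linkage results, anchors,
utilization summaries, a human-readable report) into ./pipeline_out and
prints the manifest.  The same run is available from the shell as

    ipahes run-all --config run.yaml --seed 5 --out pipeline_out
"""

from pathlib import Path

from ipahes import RunConfig, run_pipeline

manifest = run_pipeline(
    RunConfig(out_dir=Path("pipeline_out"), seed=5, n_cases=60, n_per_violator=10,
              n_validation_cases=80)
)
for name, path in manifest.items():
    print(f"{name:<28s} {path}")
print()
print((Path("pipeline_out") / "report.txt").read_text())
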