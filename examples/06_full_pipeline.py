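"""End-to-end run: survey file in, report bundle out.

Writes nine edge lists, the item-correlation matrix, the measure table,
null-model envelopes for every (layer, measure, model) triple, cross-layer
rank correlations and a manifest that makes every number reproducible.
"""

from pathlib import Path

from trustnet import (
    GeneratorConfig,
    RunConfig,
    generate_survey,
    run,
    write_roster,
    write_survey,
)

out = Path("pipeline_output")
roster, records, _ = generate_survey(GeneratorConfig(seed=42))
write_survey(records, "synthetic_survey.csv")
write_roster(roster, "synthetic_roster.csv")

cfg = RunConfig(
    survey="synthetic_survey.csv",
    roster="synthetic_roster.csv",
    out_dir=str(out),
    seed=7,
    null_iterations=200,   # 1000 reproduces the full analysis; 200 is quick
    log_level="WARNING",
)
artifacts = run(cfg)
print("artifacts written:")
for name, path in sorted(artifacts.items()):
    print(f"  {name:<24} {path}")
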