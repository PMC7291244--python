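"""The whole pipeline on a pocket-sized dataset.

Equivalent to the shell pipeline

    methsplice all -o demo_run --seed 3 --fixture tiny

this drives every stage programmatically: simulate data, build flank pairs,
per-cohort QC / differential tests / PSI / flank regression / EWAS /
differential correlation, then the cross-cohort replication join and the
DEU-DMR co-occurrence report.
"""

import json
from pathlib import Path
from tempfile import mkdtemp

from methsplice import Pipeline, PipelineConfig

outdir = Path(mkdtemp(prefix="methsplice_demo_"))
pipe = Pipeline(outdir, PipelineConfig(seed=3, fixture="tiny"))
summary = pipe.run_all()

print(f"artifacts written under {outdir}\n")
for path in sorted(outdir.rglob("*")):
    if path.is_file():
        print(" ", path.relative_to(outdir))

print("\nreport.json (abridged):")
abridged = {k: v for k, v in summary.items() if k != "config"}
for cohort in ("screening", "replication"):
    abridged.get(cohort, {}).pop("flank_regression", None)
print(json.dumps(abridged, indent=2, default=str))
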