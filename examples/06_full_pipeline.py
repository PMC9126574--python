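"""Run the whole analysis in one call and list its artifacts.

simulate -> screen -> cutoffs -> classify -> encode -> mine -> report,
with a manifest of SHA-256 content hashes; the same config and seed
reproduce every artifact byte for byte.
"""

import json
from pathlib import Path
from tempfile import mkdtemp

from cephalomine import GeneratorConfig, PipelineConfig, run_pipeline

out = run_pipeline(
    PipelineConfig(
        out_dir=Path(mkdtemp()) / "run",
        generator=GeneratorConfig(n_subjects=2508),
        seed=1,
    )
)

manifest = json.loads((out / "manifest.json").read_text())
print(f"artifacts in {out}:")
for name, digest in manifest["artifacts"].items():
    print(f"  {name:24s} sha256:{digest[:12]}...")

report = json.loads((out / "report" / "report.json").read_text())
print(
    f"\n{len(report['rules_size3'])} size-3 and {len(report['rules_size2'])} "
    f"size-2 microcephaly rules; {len(report['comparisons'])} comparisons"
)
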