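"""The whole workflow in one call: table in, reproducible report out.

Writes a synthetic panel to disk in the canonical measurement-table schema,
runs quantify -> fit -> Monte-Carlo -> identifiability -> kcat, and prints
both the machine-readable JSON report and the human summary.  Rerunning
with the same file and seed reproduces the report byte for byte.
"""

import tempfile
from pathlib import Path

from invivokinetics import (
    PipelineConfig,
    generate_strain_panel,
    reference_presets,
    run_pipeline,
    write_records,
)
from invivokinetics.report import human_summary, report_to_json

with tempfile.TemporaryDirectory() as tmp:
    panel_file = Path(tmp) / "panel.csv"
    write_records(generate_strain_panel(reference_presets()["crtB_medium"]), panel_file)
    report = run_pipeline(panel_file, PipelineConfig(n_mc=1000, seed=42))

print(human_summary(report))
print("\n--- JSON report (excerpt) ---")
print("\n".join(report_to_json(report).splitlines()[:20]))
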