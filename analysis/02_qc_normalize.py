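"""Quality control and −ΔΔCt normalization of the raw Ct cohort.

Applies the 60%-present gene/sample filter, reconciles duplicate-chip
technical replicates inside the (0.85, 1.15) agreement band, and
normalizes each organ against the median of its robustly expressed
genes.  Writes normalized.csv (plus per-organ matrices) and
qc_report.json.
"""

import json
from pathlib import Path

from organet.pipeline import PipelineConfig, cmd_run

HERE = Path(__file__).resolve().parent

cfg = PipelineConfig.from_file(HERE / "config.yaml")
manifest = cmd_run(cfg, ("qc",))
info = manifest["results"]["qc"]

report = json.loads((Path(cfg.out_dir) / "qc_report.json").read_text())
print(f"retained {info['genes']} genes x {info['samples']} samples "
      f"(removed {info['removed_genes']} genes, "
      f"{info['removed_samples']} samples)")
print(f"replicate pairs reconciled: {len(report['replicate_merges'])}")
for organ, ref in report["reference_genes"].items():
    print(f"  {organ}: {len(ref)} reference genes for the ΔCt median")
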