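"""Threshold and compare the strain networks; order genes by peak time.

Applies the ±2·SD coefficient filter, counts organ-to-organ edges,
partitions per-organ regulator genes between the strains and sorts the
simulated trajectories by their peak-expression time.  Writes edge
lists (TSV + GraphML), organ-count matrices, regulator_sets.json and
peak_order_<strain>.csv, then summarizes everything.
"""

import json
from pathlib import Path

import pandas as pd

from organet.pipeline import PipelineConfig, cmd_report, cmd_run

HERE = Path(__file__).resolve().parent

cfg = PipelineConfig.from_file(HERE / "config.yaml")
manifest = cmd_run(cfg, ("network",))
summary = cmd_report(cfg)

out = Path(cfg.out_dir)
for strain, info in manifest["results"]["network"].items():
    print(f"{strain}: {info['n_edges']} edges beyond ±{cfg.sd_factor}·SD")

reg_path = out / "regulator_sets.json"
if reg_path.exists():
    reg = json.loads(reg_path.read_text())
    for organ, parts in reg.items():
        counts = {k: len(v) for k, v in parts.items()}
        print(f"  {organ} regulators: {counts}")

for strain in manifest["results"]["network"]:
    peaks = pd.read_csv(out / f"peak_order_{strain}.csv")
    head = ", ".join(f"{r.organ}:{r.gene}@{r.peak_time:g}w"
                     for r in peaks.head(3).itertuples())
    print(f"{strain} earliest peaks: {head}")
print(f"summary -> {out / 'summary.json'}")
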