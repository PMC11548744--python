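"""PCA staging and per-gene age x strain ANOVA of the normalized cohort.

Writes pca_scores.csv / pca_loadings.csv, the per-(organ, gene) ANOVA
table and the p < 0.05 strain-effect gene list.
"""

import json
from pathlib import Path

import pandas as pd

from organet.pipeline import PipelineConfig, cmd_run

HERE = Path(__file__).resolve().parent

cfg = PipelineConfig.from_file(HERE / "config.yaml")
manifest = cmd_run(cfg, ("stats",))
info = manifest["results"]["stats"]

out = Path(cfg.out_dir)
scores = pd.read_csv(out / "pca_scores.csv", index_col=0)
sig = json.loads((out / "significant.json").read_text())

print(f"PCA: {info['n_pca_components']} components over "
      f"{scores.shape[0]} samples")
print(f"strain-differential genes at p<0.05: "
      f"{info['n_significant_strain']}")
for label in sig["significant_strain_genes"][:10]:
    print(f"  {label}")
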