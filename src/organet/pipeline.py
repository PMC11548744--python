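"""Configuration-driven orchestration of the full analysis.

Three entry points mirror the CLI subcommands:

* :func:`cmd_simulate` — generate a synthetic cohort (ground-truth
  network, trajectories, Ct data, metadata) into the output directory;
* :func:`cmd_run` — execute any subset of the stages ``qc``, ``stats``,
  ``fit``, ``network`` on the configured inputs, writing intermediate
  artifacts and a run manifest;
* :func:`cmd_report` — tabulate the artifacts into a JSON + Markdown
  summary.

A single global seed is fanned out to per-stage child seeds via
``numpy.random.SeedSequence.spawn`` (stage order is fixed), so stages
rerun in isolation reproduce their in-pipeline randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, network, qc, stats
from .design import StudyDesign, toy_design
from .hmf import HmfConfig, estimate_network, simulate_fitted_model, summarize_replicates, minmax_scale
from .synthetic import make_synthetic_dataset

log = logging.getLogger(__name__)

STAGES = ("qc", "stats", "fit", "network")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, serializable to YAML/JSON."""

    out_dir: str = "results/pipeline"
    ct_csv: str | None = None            # defaults to the simulate artifacts
    meta_csv: str | None = None
    seed: int = 0
    # synthetic design
    n_organs: int = 3
    n_genes: int = 5
    replicates_per_cell: int = 3
    ages_weeks: tuple[float, ...] = (8.0, 10.0, 12.0, 16.0, 24.0)
    density: float = 0.05
    coeff_scale: float = 0.2
    stability_bound: float = -0.05
    noise_sd: float = 0.25
    missing_rate: float = 0.02
    chip_replicate_fraction: float = 0.0
    # QC
    min_present: float = 0.6
    replicate_band: tuple[float, float] = (0.85, 1.15)
    # HMF
    hmf_M: int = 8
    hmf_N: int = 3
    n_grid: int = 257
    l1_ratio: float = 0.5
    penalty_grid: tuple[float, ...] = ()
    sim_span: tuple[float, float] = (8.0, 24.0)
    sim_n_out: int = 161
    # network
    sd_factor: float = 2.0
    max_fraction: float = 0.75

    def design(self) -> StudyDesign:
        return toy_design(n_organs=self.n_organs, n_genes=self.n_genes,
                          ages=self.ages_weeks,
                          replicates_per_cell=self.replicates_per_cell)

    def hmf(self) -> HmfConfig:
        kw = dict(M=self.hmf_M, N=self.hmf_N, n_grid=self.n_grid,
                  l1_ratio=self.l1_ratio)
        if self.penalty_grid:
            kw["penalty_grid"] = tuple(self.penalty_grid)
        return HmfConfig(**kw)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("ages_weeks", "replicate_band", "penalty_grid", "sim_span"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            json.loads(json.dumps(self.to_dict())), sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    order = ("simulate",) + STAGES
    children = np.random.SeedSequence(seed).spawn(len(order))
    return int(children[order.index(stage)].generate_state(1)[0] % 2**31)


def _manifest(cfg: PipelineConfig, extra: dict) -> dict:
    return {"config_hash": cfg.content_hash(), "seed": cfg.seed,
            "config": cfg.to_dict(), **extra}


def cmd_simulate(cfg: PipelineConfig) -> dict:
    """Generate the synthetic cohort and write its files."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = make_synthetic_dataset(
        cfg.design(), density=cfg.density, coeff_scale=cfg.coeff_scale,
        stability_bound=cfg.stability_bound, noise_sd=cfg.noise_sd,
        missing_rate=cfg.missing_rate,
        chip_replicate_fraction=cfg.chip_replicate_fraction,
        seed=stage_seed(cfg.seed, "simulate"))
    io.write_ct_long(ds.ct, out / "ct.csv")
    io.write_meta(ds.meta, out / "meta.csv")
    io.write_node_matrix(ds.truth.as_frame(), out / "truth_K.csv")
    truth_edges = network.threshold_by_max_fraction(ds.truth.as_frame(), 1e-12)
    network.export_network(truth_edges, out / "truth_edges.tsv", "tsv")
    manifest = _manifest(cfg, {
        "stage": "simulate",
        "n_samples": int(ds.ct.shape[1]),
        "n_genes": int(ds.ct.shape[0]),
        "n_measurements": int(ds.ct.size),
        "design": {"organs": list(cfg.design().organs),
                   "strains": list(cfg.design().strains),
                   "ages_weeks": list(cfg.design().ages_weeks),
                   "replicates_per_cell": cfg.design().replicates_per_cell,
                   "n_genes": len(cfg.design().genes)},
        "truth_spectral_abscissa": ds.truth.spectral_abscissa,
    })
    io.write_json(manifest, out / "simulate_manifest.json")
    return manifest


def _load_inputs(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = Path(cfg.out_dir)
    ct_path = Path(cfg.ct_csv) if cfg.ct_csv else out / "ct.csv"
    meta_path = Path(cfg.meta_csv) if cfg.meta_csv else out / "meta.csv"
    for p, stage in ((ct_path, "simulate"), (meta_path, "simulate")):
        if not p.exists():
            raise FileNotFoundError(
                f"missing upstream artifact {p}; run the '{stage}' stage "
                f"or point ct_csv/meta_csv at existing inputs")
    return io.read_ct_long(ct_path), io.read_meta(meta_path)


def cmd_run(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in canonical order."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ran: dict = {}

    if "qc" in stages:
        ct, meta = _load_inputs(cfg)
        norm, meta_qc, report = qc.normalize(ct, meta,
                                             min_present=cfg.min_present,
                                             band=cfg.replicate_band)
        io.write_matrix(norm, out / "normalized.csv")
        io.write_meta(meta_qc, out / "meta_qc.csv")
        io.write_json(report.as_dict(), out / "qc_report.json")
        for organ, samples in meta_qc.groupby("organ").groups.items():
            cols = [s for s in samples if s in norm.columns]
            io.write_matrix(norm[cols], out / f"normalized_{organ}.csv")
        ran["qc"] = {"genes": int(norm.shape[0]), "samples": int(norm.shape[1]),
                     "removed_genes": len(report.removed_genes),
                     "removed_samples": len(report.removed_samples)}

    norm = meta_qc = None
    if set(stages) & {"stats", "fit", "network"}:
        npath, mpath = out / "normalized.csv", out / "meta_qc.csv"
        if not npath.exists():
            raise FileNotFoundError(f"missing upstream artifact {npath}; "
                                    f"run the 'qc' stage first")
        norm = pd.read_csv(npath, index_col=0)
        meta_qc = io.read_meta(mpath)

    if "stats" in stages:
        pca = stats.run_pca(norm, meta_qc)
        io.write_matrix(pca.scores, out / "pca_scores.csv")
        io.write_matrix(pca.loadings, out / "pca_loadings.csv")
        anova = stats.two_way_anova(norm, meta_qc, run_tukey=False)
        anova.table.to_csv(out / "anova.csv")
        sig = stats.significant_genes(anova, "strain")
        io.write_json({"significant_strain_genes":
                       [f"{o}:{g}" for o, g in sig.index],
                       "alpha": 0.05}, out / "significant.json")
        ran["stats"] = {"n_pca_components": int(pca.scores.shape[1]),
                        "n_significant_strain": int(len(sig))}

    strains = tuple(sorted(meta_qc["strain"].unique())) if meta_qc is not None else ()
    if "fit" in stages:
        fit_info = {}
        for strain in strains:
            im = estimate_network(norm, meta_qc, strain, cfg.hmf())
            io.write_node_matrix(im.K, out / f"K_{strain}.csv")
            io.write_json(im.diagnostics, out / f"fit_diagnostics_{strain}.json")
            traj = summarize_replicates(norm, meta_qc, strain)
            scaled, _ = minmax_scale(traj)
            sim = simulate_fitted_model(im, scaled.values.to_numpy()[:, 0],
                                        t_span=cfg.sim_span, n_out=cfg.sim_n_out)
            sim_df = sim.values.copy()
            sim_df.index = [f"{o}:{g}" for o, g in sim_df.index]
            sim_df.columns = [f"{t:g}" for t in sim.times]
            sim_df.to_csv(out / f"sim_{strain}.csv", float_format="%.10g")
            fit_info[strain] = {"selected_penalty":
                                im.diagnostics["selected_penalty"],
                                "rmse": im.diagnostics["rmse"]}
        ran["fit"] = fit_info

    if "network" in stages:
        net_info = {}
        edge_sets = {}
        for strain in strains:
            kpath = out / f"K_{strain}.csv"
            if not kpath.exists():
                raise FileNotFoundError(f"missing upstream artifact {kpath}; "
                                        f"run the 'fit' stage first")
            K = io.read_node_matrix(kpath)
            edges = network.threshold_by_sd(K, factor=cfg.sd_factor)
            edge_sets[strain] = edges
            network.export_network(edges, out / f"edges_{strain}.tsv", "tsv")
            network.export_network(edges, out / f"edges_{strain}.graphml",
                                   "graphml")
            counts = network.organ_edge_counts(
                edges, organs=tuple(sorted({o for o, _ in K.index})))
            counts.to_csv(out / f"organ_counts_{strain}.csv")
            sim_path = out / f"sim_{strain}.csv"
            if sim_path.exists():
                sim_df = pd.read_csv(sim_path, index_col=0)
                idx = pd.MultiIndex.from_tuples(
                    [tuple(s.split(":", 1)) for s in sim_df.index],
                    names=["organ", "gene"])
                from .synthetic import TrajectorySet
                traj = TrajectorySet(
                    times=np.array([float(c) for c in sim_df.columns]),
                    values=pd.DataFrame(sim_df.to_numpy(), index=idx))
                network.peak_order(traj).table.to_csv(
                    out / f"peak_order_{strain}.csv", index=False)
            net_info[strain] = {"n_edges": len(edges)}
        if len(edge_sets) == 2:
            a, b = strains
            organs = sorted({o for o, _ in
                             io.read_node_matrix(out / f"K_{a}.csv").index})
            reg = {}
            for organ in organs:
                only_a, common, only_b = network.regulator_sets(
                    edge_sets[a], edge_sets[b], organ)
                reg[organ] = {f"only_{a}": sorted(only_a),
                              "common": sorted(common),
                              f"only_{b}": sorted(only_b)}
            io.write_json(reg, out / "regulator_sets.json")
        ran["network"] = net_info

    manifest = _manifest(cfg, {"stage": "run", "stages": list(stages),
                               "results": ran})
    io.write_json(manifest, out / "run_manifest.json")
    return manifest


def cmd_report(cfg: PipelineConfig) -> dict:
    """Summarize existing artifacts into JSON + Markdown."""
    out = Path(cfg.out_dir)
    summary: dict = {"config_hash": cfg.content_hash(), "seed": cfg.seed}
    qc_path = out / "qc_report.json"
    if qc_path.exists():
        rep = io.read_json(qc_path)
        summary["qc"] = {"removed_genes": len(rep["removed_genes"]),
                         "removed_samples": len(rep["removed_samples"]),
                         "replicate_merges": len(rep["replicate_merges"])}
    sig_path = out / "significant.json"
    if sig_path.exists():
        summary["significant_strain_genes"] = len(
            io.read_json(sig_path)["significant_strain_genes"])
    edges = {p.stem.split("_", 1)[1]: len(pd.read_csv(p, sep="\t"))
             for p in sorted(out.glob("edges_*.tsv"))}
    if edges:
        summary["edges"] = edges
    reg_path = out / "regulator_sets.json"
    if reg_path.exists():
        reg = io.read_json(reg_path)
        summary["regulators"] = {
            organ: {k: len(v) for k, v in parts.items()}
            for organ, parts in reg.items()}
    peaks = {p.stem.split("_")[-1]: pd.read_csv(p).head(5).to_dict("records")
             for p in sorted(out.glob("peak_order_*.csv"))}
    if peaks:
        summary["earliest_peaks"] = peaks

    io.write_json(summary, out / "summary.json")
    lines = ["# Pipeline summary", ""]
    for key, val in summary.items():
        lines.append(f"- **{key}**: {json.dumps(val, default=str)}")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    return summary
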