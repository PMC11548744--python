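"""Synthetic multi-organ qPCR data from a known sparse linear network.

The generator is the test bed for the whole pipeline: it draws a sparse
stable interaction matrix K over (organ, gene) nodes, integrates
dE/dt = K·E, and converts expression into Ct-scale measurements with the
study's factorial layout (strains x ages x organs x animals), replicate
noise, missing reactions and duplicate-chip technical replicates.

Ct mapping: the qPCR instrument reports quantification cycles, which
are -log2 of abundance up to an offset.  We use
``Ct = offset - log2(max(expression, floor))`` with offset 25 cycles and
floor 1e-6, keeping Ct in a plausible 5-30 cycle range, plus Gaussian
replicate noise on the Ct scale (a stand-in; the study states no
replicate noise model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign
from .dynamics import integrate_linear_ode

log = logging.getLogger(__name__)

CT_OFFSET_DEFAULT = 25.0
EXPRESSION_FLOOR = 1e-6


@dataclass
class GroundTruthNetwork:
    """A known sparse stable interaction matrix over (organ, gene) nodes."""

    node_labels: list[tuple[str, str]]
    K: np.ndarray          # (n, n), 1/week; K[target, regulator]
    density: float         # requested off-diagonal density

    def __post_init__(self) -> None:
        n = len(self.node_labels)
        if self.K.shape != (n, n):
            raise ValueError("K dimension must match node_labels")

    @property
    def spectral_abscissa(self) -> float:
        """Max real part of the eigenvalues of K (1/week)."""
        return float(np.max(np.linalg.eigvals(self.K).real))

    @property
    def true_edges(self) -> list[tuple[int, int]]:
        """(target, regulator) index pairs of nonzero off-diagonals."""
        tgt, reg = np.nonzero(self.K)
        return [(int(t), int(r)) for t, r in zip(tgt, reg) if t != r]

    def as_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.node_labels, names=["organ", "gene"])
        return pd.DataFrame(self.K, index=idx, columns=idx)


@dataclass
class TrajectorySet:
    """Expression trajectories per (organ, gene) node on a shared time grid."""

    times: np.ndarray                  # weeks, increasing
    values: pd.DataFrame               # rows: MultiIndex (organ, gene); cols: 0..T-1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape[1] != self.times.size:
            raise ValueError("values columns must match times")

    def node_array(self) -> np.ndarray:
        return self.values.to_numpy()

    def at_age(self, age: float) -> pd.Series:
        j = int(np.argmin(np.abs(self.times - age)))
        if abs(self.times[j] - age) > 1e-9:
            raise KeyError(f"age {age} not on trajectory grid")
        return self.values.iloc[:, j]


@dataclass
class SyntheticDataset:
    """Ct measurements + metadata + the generating truth."""

    ct: pd.DataFrame                   # genes x samples, NaN = missing reaction
    meta: pd.DataFrame                 # per sample: strain, sex, organ, age_weeks, animal_id, chip_id
    truth: GroundTruthNetwork
    true_trajectories: dict[str, TrajectorySet] = field(default_factory=dict)
    seed: int = 0


def generate_ground_truth_network(design: StudyDesign, density: float = 0.05,
                                  coeff_scale: float = 0.2,
                                  stability_bound: float = -0.05,
                                  seed: int = 0,
                                  decay_spread: float = 0.15
                                  ) -> GroundTruthNetwork:
    """Draw a sparse stable K over the design's (organ, gene) nodes.

    Off-diagonal support: exactly ``round(density * n*(n-1))`` entries
    chosen uniformly; magnitudes ~ Laplace(0, coeff_scale) (heavy-tailed,
    sparsity-realistic).  The diagonal is set to
    ``-(row off-diagonal L1) + stability_bound - uniform(0, decay_spread)``
    so Gershgorin discs put every eigenvalue's real part at or below
    ``stability_bound``; the per-node uniform margin gives every gene its
    own turnover rate — without it, all unregulated nodes would decay as
    the same exponential and their regulatory roles would be
    indistinguishable from any single trajectory.
    """
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = design.node_labels()
    n = len(nodes)
    n_off = n * (n - 1)
    n_edges = int(round(density * n_off))
    if density > 0 and n_edges == 0:
        raise ValueError("empty network: density rounds to zero edges")

    K = np.zeros((n, n))
    if n_edges:
        flat = rng.choice(n_off, size=n_edges, replace=False)
        # map flat off-diagonal index -> (row, col) skipping the diagonal
        rows = flat // (n - 1)
        cols = flat % (n - 1)
        cols = cols + (cols >= rows)
        K[rows, cols] = rng.laplace(0.0, coeff_scale, size=n_edges)
    # diagonal dominance => spectral abscissa <= stability_bound
    row_l1 = np.sum(np.abs(K), axis=1)
    margin = rng.uniform(0.0, decay_spread, size=n)
    np.fill_diagonal(K, -row_l1 + stability_bound - margin)
    return GroundTruthNetwork(node_labels=nodes, K=K, density=density)


def simulate_trajectories(network: GroundTruthNetwork, t_grid: np.ndarray,
                          E0: np.ndarray) -> TrajectorySet:
    """Integrate dE/dt = K·E from E(t_grid[0]) = E0 (exact expm steps)."""
    states = integrate_linear_ode(network.K, E0, np.asarray(t_grid, dtype=float))
    idx = pd.MultiIndex.from_tuples(network.node_labels, names=["organ", "gene"])
    return TrajectorySet(times=np.asarray(t_grid, dtype=float),
                         values=pd.DataFrame(states.T, index=idx))


def expression_to_ct(expression: np.ndarray, ct_offset: float = CT_OFFSET_DEFAULT,
                     floor: float = EXPRESSION_FLOOR) -> np.ndarray:
    """Ct = offset - log2(expression), clipping nonpositive values to a floor."""
    expr = np.asarray(expression, dtype=float)
    n_clip = int(np.sum(expr < floor))
    if n_clip:
        log.debug("clipped %d nonpositive/sub-floor expression values", n_clip)
    return ct_offset - np.log2(np.maximum(expr, floor))


def ct_to_expression(ct: np.ndarray, ct_offset: float = CT_OFFSET_DEFAULT) -> np.ndarray:
    return np.power(2.0, ct_offset - np.asarray(ct, dtype=float))


def sample_qpcr_dataset(traj: TrajectorySet | dict[str, TrajectorySet],
                        design: StudyDesign,
                        ct_offset: float = CT_OFFSET_DEFAULT,
                        noise_sd: float = 0.25,
                        missing_rate: float = 0.02,
                        chip_replicate_fraction: float = 0.0,
                        seed: int = 0,
                        truth: GroundTruthNetwork | None = None) -> SyntheticDataset:
    """Emit a Ct-scale dataset with the design's factorial structure.

    ``traj`` may be one TrajectorySet (shared by both strains) or a
    mapping strain -> TrajectorySet.  Every (strain, organ, age) cell
    gets ``replicates_per_cell`` samples; each sample measures every
    panel gene from its organ's trajectory at its age.  A fraction of
    entries is set missing at random and a fraction of samples is
    duplicated as second-chip technical replicates with independent
    noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    traj_by_strain = traj if isinstance(traj, dict) else {s: traj for s in design.strains}

    genes = list(design.genes)
    sample_ids, meta_rows, columns = [], [], []
    n_clip_total = 0
    for strain in design.strains:
        ts = traj_by_strain[strain]
        for organ in design.organs:
            for age in design.ages_weeks:
                col_expr = ts.at_age(age).loc[organ].reindex(genes).to_numpy()
                n_clip_total += int(np.sum(col_expr < EXPRESSION_FLOOR))
                for animal in range(1, design.replicates_per_cell + 1):
                    sid = f"{strain}_{organ}_{age:g}w_a{animal}"
                    ct_col = expression_to_ct(col_expr, ct_offset)
                    if noise_sd > 0:
                        ct_col = ct_col + rng.normal(0.0, noise_sd, size=len(genes))
                    sample_ids.append(sid)
                    columns.append(ct_col)
                    meta_rows.append((strain, design.sex, organ, age,
                                      f"{strain}{animal}_{age:g}w", "chip1"))

    ct = pd.DataFrame(np.column_stack(columns), index=genes, columns=sample_ids)
    if n_clip_total:
        log.warning("%d of %d expression values clipped to the floor before "
                    "Ct conversion (trajectories crossed zero)",
                    n_clip_total, ct.size)
    meta = pd.DataFrame(meta_rows, index=sample_ids,
                        columns=["strain", "sex", "organ", "age_weeks",
                                 "animal_id", "chip_id"])

    if chip_replicate_fraction > 0:
        n_dup = int(round(chip_replicate_fraction * ct.shape[1]))
        dup_ids = list(rng.choice(ct.columns, size=n_dup, replace=False))
        for sid in dup_ids:
            sid2 = f"{sid}_chip2"
            base = ct_to_expression(ct[sid].to_numpy(), ct_offset)
            ct[sid2] = expression_to_ct(base, ct_offset) + \
                rng.normal(0.0, max(noise_sd, 1e-12), size=len(genes))
            row = meta.loc[sid].copy()
            row["chip_id"] = "chip2"
            meta.loc[sid2] = row

    if missing_rate > 0:
        mask = rng.random(ct.shape) < missing_rate
        ct = ct.mask(mask)

    return SyntheticDataset(ct=ct, meta=meta, truth=truth, true_trajectories=(
        traj_by_strain if isinstance(traj, dict) else {"shared": traj}),
        seed=seed)


def inject_missingness(ct: pd.DataFrame, genes: list[str] | None = None,
                       samples: list[str] | None = None,
                       fraction: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Blank a fraction of entries of targeted genes (rows) / samples (cols).

    Used to build QC fixtures whose removal pattern is known by
    construction (e.g. a gene driven below the 60%-present rule).
    """
    rng = np.random.default_rng(seed)
    out = ct.copy()
    for g in genes or []:
        cols = rng.choice(out.columns, size=int(round(fraction * out.shape[1])),
                          replace=False)
        out.loc[g, cols] = np.nan
    for s in samples or []:
        rows = rng.choice(out.index, size=int(round(fraction * out.shape[0])),
                          replace=False)
        out.loc[rows, s] = np.nan
    return out


def make_study_qc_fixture(seed: int = 0) -> SyntheticDataset:
    """Full-scale cohort whose QC outcome is known by construction.

    150 samples x 96 genes with a light random missingness background,
    plus targeted missingness driving exactly 4 genes and 4 samples
    below the 60%-present rule — the gene/sample pruning outcome of a
    realistic chip-qPCR campaign.  The removal pattern is constructed,
    not inferred: which reactions failed in the real study is unknown.
    """
    from .design import female_design
    design = female_design()
    ds = make_synthetic_dataset(design, density=0.02, noise_sd=0.25,
                                missing_rate=0.01, seed=seed)
    ss = np.random.SeedSequence(seed + 77)
    s_genes, s_samples = (int(c.generate_state(1)[0] % 2**31)
                          for c in ss.spawn(2))
    rng = np.random.default_rng(s_genes)
    bad_genes = list(rng.choice(ds.ct.index, size=4, replace=False))
    rng2 = np.random.default_rng(s_samples)
    bad_samples = list(rng2.choice(ds.ct.columns, size=4, replace=False))
    ct = inject_missingness(ds.ct, genes=bad_genes, fraction=0.55,
                            seed=s_genes)
    ct = inject_missingness(ct, samples=bad_samples, fraction=0.55,
                            seed=s_samples)
    ds.ct = ct
    return ds


def make_normalized_dataset(design: StudyDesign,
                            truth: GroundTruthNetwork,
                            noise_sd: float = 0.05,
                            positive_floor: float = 0.5,
                            seed: int = 0
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized-scale (log2 relative expression) replicated dataset.

    Skips the Ct / median-reference machinery and emits data directly on
    the scale the network-identification stage consumes: per sample,
    log2 of the (positively shifted) node trajectory at that age plus
    Gaussian replicate noise.  This is the input for parameter-recovery
    studies, where the reference-gene common mode of a small panel would
    otherwise confound the estimator being tested.

    Returns (norm, meta): genes x samples matrix plus sample metadata.
    """
    rng = np.random.default_rng(seed)
    ages = np.asarray(design.ages_weeks, dtype=float)
    genes = list(design.genes)
    cols, sample_ids, meta_rows = [], [], []
    for strain in design.strains:
        E0 = rng.uniform(0.2, 1.0, size=truth.K.shape[0])
        traj = simulate_trajectories(truth, ages, E0)
        vals = traj.values.to_numpy()
        shift = np.maximum(0.0, positive_floor - vals.min(axis=1))
        logv = pd.DataFrame(np.log2(vals + shift[:, None]),
                            index=traj.values.index)
        for organ in design.organs:
            block = logv.loc[organ].reindex(genes).to_numpy()
            for j, age in enumerate(ages):
                for a in range(1, design.replicates_per_cell + 1):
                    sid = f"{strain}_{organ}_{age:g}w_a{a}"
                    cols.append(block[:, j]
                                + rng.normal(0.0, noise_sd, size=len(genes)))
                    sample_ids.append(sid)
                    meta_rows.append((strain, design.sex, organ, age,
                                      f"{strain}{a}_{age:g}w", "chip1"))
    norm = pd.DataFrame(np.column_stack(cols), index=genes, columns=sample_ids)
    meta = pd.DataFrame(meta_rows, index=sample_ids,
                        columns=["strain", "sex", "organ", "age_weeks",
                                 "animal_id", "chip_id"])
    return norm, meta


def make_synthetic_dataset(design: StudyDesign, density: float = 0.05,
                           coeff_scale: float = 0.2,
                           stability_bound: float = -0.05,
                           noise_sd: float = 0.25,
                           missing_rate: float = 0.02,
                           chip_replicate_fraction: float = 0.0,
                           positive_floor: float = 0.5,
                           seed: int = 0) -> SyntheticDataset:
    """One-call cohort: shared ground-truth K, strain-specific initial states.

    Both strains follow the same regulatory network but start from
    independent initial expression states (uniform(0.2, 1.0) per node),
    giving distinct strain trajectories, as in a strain contrast where
    topology is shared but state differs.

    Before Ct conversion each node's trajectory is shifted by a constant
    so its minimum is at least ``positive_floor``: measured transcript
    abundance never crosses zero, and the log2 Ct mapping stays in its
    gentle near-linear regime.  A static per-node offset is invisible to
    the modulating-function regression (the basis integrates constants
    to zero) and is removed anyway by the −ΔΔCt centering, so the
    dataset's identifiable structure is unchanged.
    """
    ss = np.random.SeedSequence(seed)
    s_net, s_init, s_ct = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    truth = generate_ground_truth_network(design, density=density,
                                          coeff_scale=coeff_scale,
                                          stability_bound=stability_bound,
                                          seed=s_net)
    rng = np.random.default_rng(s_init)
    t_grid = np.asarray(design.ages_weeks, dtype=float)
    traj = {}
    for strain in design.strains:
        E0 = rng.uniform(0.2, 1.0, size=truth.K.shape[0])
        ts = simulate_trajectories(truth, t_grid, E0)
        if positive_floor is not None:
            vals = ts.values.to_numpy()
            shift = np.maximum(0.0, positive_floor - vals.min(axis=1))
            ts = TrajectorySet(times=ts.times,
                               values=pd.DataFrame(vals + shift[:, None],
                                                   index=ts.values.index))
        traj[strain] = ts
    ds = sample_qpcr_dataset(traj, design, noise_sd=noise_sd,
                             missing_rate=missing_rate,
                             chip_replicate_fraction=chip_replicate_fraction,
                             seed=s_ct, truth=truth)
    ds.seed = seed
    return ds
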