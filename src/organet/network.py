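"""Network-level summaries of a fitted interaction matrix.

Turns K into the reported artifacts: directed edge sets thresholded at
±2·SD from the mean of all coefficients or at a fraction of the maximum
magnitude, organ-by-organ edge counts, regulator-gene set comparisons
between two networks, peak-expression orderings of simulated
trajectories, and edge-list / GraphML exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .hmf import InteractionMatrix
from .synthetic import TrajectorySet

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["src_organ", "src_gene", "dst_organ", "dst_gene", "weight", "sign"]


@dataclass
class NetworkEdgeSet:
    """Directed regulator → target edges with provenance of the rule."""

    edges: pd.DataFrame                       # EDGE_COLUMNS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dup = self.edges.duplicated(subset=EDGE_COLUMNS[:4])
        if dup.any():
            raise ValueError("duplicate (regulator, target) pairs")

    def __len__(self) -> int:
        return len(self.edges)

    def regulators(self, organ: str | None = None) -> set[str]:
        e = self.edges
        if organ is not None:
            e = e[e["src_organ"] == organ]
        return set(e["src_gene"])


def _K_frame(K: InteractionMatrix | pd.DataFrame) -> pd.DataFrame:
    return K.K if isinstance(K, InteractionMatrix) else K


def _edges_from_mask(Kdf: pd.DataFrame, mask: np.ndarray,
                     provenance: dict) -> NetworkEdgeSet:
    tgt_idx, reg_idx = np.nonzero(mask)
    vals = Kdf.to_numpy()
    rows = []
    for t, r in zip(tgt_idx, reg_idx):
        src = Kdf.columns[r]
        dst = Kdf.index[t]
        w = float(vals[t, r])
        rows.append((src[0], src[1], dst[0], dst[1], w, int(np.sign(w))))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return NetworkEdgeSet(edges=edges, provenance=provenance)


def threshold_by_sd(K: InteractionMatrix | pd.DataFrame, factor: float = 2.0,
                    include_zeros: bool = True) -> NetworkEdgeSet:
    """Keep coefficients more than ``factor``·SD away from the mean.

    Mean and SD are taken over all entries of K (including the elastic
    net's exact zeros) by default; ``include_zeros=False`` restricts the
    population to nonzero entries (the text of the rule is ambiguous).
    """
    Kdf = _K_frame(K)
    if Kdf.size == 0:
        raise ValueError("empty interaction matrix")
    vals = Kdf.to_numpy()
    pop = vals.ravel() if include_zeros else vals[vals != 0]
    mu = float(np.mean(pop)) if pop.size else 0.0
    sd = float(np.std(pop)) if pop.size else 0.0
    prov = {"rule": "sd", "factor": factor, "mean": mu, "sd": sd,
            "include_zeros": include_zeros}
    if sd == 0.0:
        log.warning("zero SD of interaction coefficients; empty edge set")
        return NetworkEdgeSet(edges=pd.DataFrame(columns=EDGE_COLUMNS),
                              provenance=prov)
    mask = np.abs(vals - mu) > factor * sd
    return _edges_from_mask(Kdf, mask, prov)


def threshold_by_max_fraction(K: InteractionMatrix | pd.DataFrame,
                              frac: float,
                              scope_organs: tuple[str, ...] | None = None
                              ) -> NetworkEdgeSet:
    """Keep |k| > frac · max|k| within a node scope.

    ``scope_organs`` restricts both regulator and target nodes to a set
    of organs (e.g. the adrenal-kidney block); None means all nodes.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    Kdf = _K_frame(K)
    if scope_organs is not None:
        rows = [lab for lab in Kdf.index if lab[0] in scope_organs]
        cols = [lab for lab in Kdf.columns if lab[0] in scope_organs]
        if not rows or not cols:
            raise ValueError("empty scope")
        Kdf = Kdf.loc[rows, cols]
    vals = np.abs(Kdf.to_numpy())
    vmax = float(vals.max()) if vals.size else 0.0
    prov = {"rule": "max_fraction", "frac": frac, "max_abs": vmax,
            "scope_organs": list(scope_organs) if scope_organs else None}
    mask = vals > frac * vmax
    return _edges_from_mask(Kdf, mask, prov)


def organ_edge_counts(edges: NetworkEdgeSet,
                      organs: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Source-organ x target-organ edge count matrix."""
    e = edges.edges
    if organs is None:
        organs = tuple(sorted(set(e["src_organ"]) | set(e["dst_organ"])))
    counts = pd.DataFrame(0, index=list(organs), columns=list(organs))
    for (src, dst), grp in e.groupby(["src_organ", "dst_organ"]):
        counts.loc[src, dst] = len(grp)
    return counts


def regulator_sets(edges_a: NetworkEdgeSet, edges_b: NetworkEdgeSet,
                   organ: str) -> tuple[set[str], set[str], set[str]]:
    """Three-way partition of regulator genes from one organ.

    Returns (only in A, common, only in B).
    """
    a = edges_a.regulators(organ)
    b = edges_b.regulators(organ)
    return a - b, a & b, b - a


@dataclass
class PeakOrdering:
    table: pd.DataFrame            # organ, gene, peak_time sorted ascending


def peak_order(traj: TrajectorySet) -> PeakOrdering:
    """Sort nodes by the time their simulated expression peaks.

    Ties (including constant trajectories, whose argmax is the first
    grid time) break by organ label then gene label.
    """
    vals = traj.values.to_numpy()
    peak_idx = np.argmax(vals, axis=1)        # first max wins
    peak_t = traj.times[peak_idx]
    tab = pd.DataFrame({
        "organ": [lab[0] for lab in traj.values.index],
        "gene": [lab[1] for lab in traj.values.index],
        "peak_time": peak_t,
    }).sort_values(["peak_time", "organ", "gene"], kind="mergesort")
    return PeakOrdering(table=tab.reset_index(drop=True))


def export_network(edges: NetworkEdgeSet, path: str | Path,
                   format: str = "tsv") -> Path:
    """Write the edge set as an edge-list TSV or GraphML file.

    TSV weights use 17 significant digits so a read round-trips to full
    double precision.
    """
    path = Path(path)
    if format == "tsv":
        edges.edges.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "graphml":
        g = nx.DiGraph()
        for _, row in edges.edges.iterrows():
            u = f"{row.src_organ}:{row.src_gene}"
            v = f"{row.dst_organ}:{row.dst_gene}"
            g.add_node(u, organ=row.src_organ, gene=row.src_gene)
            g.add_node(v, organ=row.dst_organ, gene=row.dst_gene)
            g.add_edge(u, v, weight=float(row.weight), sign=int(row.sign))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_edge_list(path: str | Path) -> NetworkEdgeSet:
    edges = pd.read_csv(path, sep="\t")
    if edges.empty:
        edges = pd.DataFrame(columns=EDGE_COLUMNS)
    return NetworkEdgeSet(edges=edges[EDGE_COLUMNS] if len(edges) else edges,
                          provenance={"source": str(path)})
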