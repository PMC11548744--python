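"""Quality control and normalization of raw qPCR Ct matrices.

The normalization scheme is the median-reference ΔCt / −ΔΔCt used for
high-throughput chip qPCR: within each organ, every sample's gene Ct is
referenced to the median Ct of that sample over a subset of robustly
expressed genes (ΔCt), then each gene is centered by its cross-sample
median ΔCt and negated so that positive values mean above-median
expression on a log2 scale (−ΔΔCt).

QC rules
--------
* genes, then samples, with < 60% present reactions are removed;
* duplicate-chip technical replicates are averaged when their
  zero-intercept regression slope is inside (0.85, 1.15), otherwise the
  replicate with more present reactions is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    removed_genes: list[str] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    replicate_merges: list[dict] = field(default_factory=list)
    reference_genes: dict[str, list[str]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "removed_genes": self.removed_genes,
            "removed_samples": self.removed_samples,
            "replicate_merges": self.replicate_merges,
            "reference_genes": self.reference_genes,
        }


def filter_low_data(ct: pd.DataFrame, min_present: float = 0.6
                    ) -> tuple[pd.DataFrame, QCReport]:
    """Drop genes, then samples, with present-fraction < ``min_present``.

    One pass each, genes first: a gene's fraction is judged over all
    incoming samples, a sample's fraction over the retained genes.
    """
    if not 0 < min_present <= 1:
        raise ValueError("min_present must be in (0, 1]")
    report = QCReport()
    gene_frac = ct.notna().mean(axis=1)
    keep_genes = gene_frac >= min_present
    report.removed_genes = list(ct.index[~keep_genes])
    out = ct.loc[keep_genes]
    if out.empty:
        raise ValueError("empty matrix after QC: all genes removed")
    samp_frac = out.notna().mean(axis=0)
    keep_samples = samp_frac >= min_present
    report.removed_samples = list(out.columns[~keep_samples])
    out = out.loc[:, keep_samples]
    if out.shape[1] == 0:
        raise ValueError("empty matrix after QC: all samples removed")
    return out, report


def replicate_agreement_slope(x: pd.Series, y: pd.Series) -> float:
    """Zero-intercept regression slope of y on x over co-present genes."""
    ok = x.notna() & y.notna()
    xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
    denom = float(np.dot(xv, xv))
    if denom == 0.0:
        return np.nan
    return float(np.dot(xv, yv) / denom)


def merge_chip_replicates(ct: pd.DataFrame, meta: pd.DataFrame,
                          band: tuple[float, float] = (0.85, 1.15)
                          ) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Reconcile duplicate-chip technical replicates.

    Replicate groups share (animal_id, organ, age_weeks) with distinct
    chip_id.  Pairs whose agreement slope lies inside ``band`` are
    replaced by the per-gene mean; otherwise the replicate with more
    present reactions is kept and the exclusion logged.
    """
    report = QCReport()
    meta = meta.loc[[s for s in ct.columns if s in meta.index]]
    groups = meta.groupby(["animal_id", "organ", "age_weeks"], sort=False)
    drop: list[str] = []
    out = ct.copy()
    for key, grp in groups:
        if len(grp) == 1:
            continue
        if grp["chip_id"].nunique() != len(grp) or len(grp) > 2:
            raise ValueError(f"unsupported replicate multiplicity for {key}")
        a, b = list(grp.index)
        slope = replicate_agreement_slope(ct[a], ct[b])
        entry = {"samples": [a, b], "slope": None if np.isnan(slope) else slope}
        if np.isfinite(slope) and band[0] < slope < band[1]:
            out[a] = ct[[a, b]].mean(axis=1)
            drop.append(b)
            entry["action"] = "averaged"
        else:
            keep = a if ct[a].notna().sum() >= ct[b].notna().sum() else b
            lose = b if keep == a else a
            drop.append(lose)
            entry["action"] = f"kept {keep}"
            log.info("replicate pair %s outside band (slope=%.3f); kept %s",
                     key, slope, keep)
        report.replicate_merges.append(entry)
    out = out.drop(columns=drop)
    meta_out = meta.drop(index=[s for s in drop if s in meta.index])
    return out, meta_out, report


def robust_genes(ct: pd.DataFrame, min_present: float = 0.6) -> list[str]:
    """Genes with present-fraction strictly above ``min_present``."""
    frac = ct.notna().mean(axis=1)
    return list(ct.index[frac > min_present])


def delta_ct(ct: pd.DataFrame, meta: pd.DataFrame,
             robust_min_present: float = 0.6
             ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """ΔCt: per organ, subtract each sample's median Ct over robust genes.

    Returns the ΔCt matrix and the per-organ robust reference subset.
    Missing entries propagate as missing.
    """
    delta = pd.DataFrame(np.nan, index=ct.index, columns=ct.columns)
    refsets: dict[str, list[str]] = {}
    for organ, samples in meta.groupby("organ").groups.items():
        cols = [s for s in samples if s in ct.columns]
        if not cols:
            continue
        sub = ct[cols]
        ref = robust_genes(sub, robust_min_present)
        if not ref:
            raise ValueError(f"no reference subset: organ {organ!r} has no "
                             f"genes above {robust_min_present:.0%} present")
        refsets[str(organ)] = ref
        med = sub.loc[ref].median(axis=0, skipna=True)
        delta[cols] = sub.sub(med, axis=1)
    return delta, refsets


def neg_delta_delta_ct(delta: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """−ΔΔCt: per organ, center each gene by its cross-sample median, negate.

    A gene present in fewer than 2 samples of an organ is set missing
    there (its median would be the value itself).
    """
    out = pd.DataFrame(np.nan, index=delta.index, columns=delta.columns)
    for organ, samples in meta.groupby("organ").groups.items():
        cols = [s for s in samples if s in delta.columns]
        if not cols:
            continue
        sub = delta[cols]
        n_present = sub.notna().sum(axis=1)
        med = sub.median(axis=1, skipna=True)
        vals = -(sub.sub(med, axis=0))
        few = n_present < 2
        if few.any():
            log.info("organ %s: %d genes present in <2 samples set missing",
                     organ, int(few.sum()))
            vals.loc[few] = np.nan
        out[cols] = vals
    return out


def normalize(ct: pd.DataFrame, meta: pd.DataFrame,
              min_present: float = 0.6,
              band: tuple[float, float] = (0.85, 1.15)
              ) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Full QC + normalization: filter → merge replicates → ΔCt → −ΔΔCt."""
    filtered, rep1 = filter_low_data(ct, min_present)
    merged, meta_out, rep2 = merge_chip_replicates(filtered, meta, band)
    delta, refsets = delta_ct(merged, meta_out, min_present)
    norm = neg_delta_delta_ct(delta, meta_out)
    report = QCReport(removed_genes=rep1.removed_genes,
                      removed_samples=rep1.removed_samples,
                      replicate_merges=rep2.replicate_merges,
                      reference_genes=refsets)
    return norm, meta_out, report


def rank_reference_stability(ct: pd.DataFrame, meta: pd.DataFrame | None = None,
                             organ: str | None = None) -> pd.Series:
    """Pairwise-variation stability ranking of candidate reference genes.

    For each fully observed candidate gene j, the score is the mean over
    partner genes k of the standard deviation across samples of the
    pairwise Ct difference (Ct is already log2-scale, so a Ct difference
    is a log-ratio).  Lower scores mean more stable expression; the
    ranking documents the choice of the median-vector reference over any
    single housekeeping gene.
    """
    sub = ct
    if meta is not None and organ is not None:
        cols = meta.index[meta["organ"] == organ]
        sub = ct[[c for c in cols if c in ct.columns]]
    full = sub.dropna(axis=0)
    if full.shape[0] < 3:
        raise ValueError("insufficient candidates: need >=3 fully present genes")
    X = full.to_numpy()
    n = X.shape[0]
    scores = np.empty(n)
    for j in range(n):
        diffs = X[j] - X          # (n, samples) pairwise log-ratios
        sds = np.std(diffs, axis=1, ddof=1)
        scores[j] = np.sum(sds) / (n - 1)   # excludes the zero self-term
    return pd.Series(scores, index=full.index, name="stability").sort_values()
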