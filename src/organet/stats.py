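"""Exploratory statistics: PCA staging and per-gene factorial ANOVA.

PCA is run on the −ΔΔCt matrix (samples as observations, genes as
features) to stage the cohort; per-gene two-way ANOVA (age x strain,
type-II sums of squares, Tukey HSD post hoc at p < 0.05) calls
differential expression within each organ, and a sex-contrast ANOVA
(age x sex) tests strain differences shared across a reduced panel.

Missing values: genes with any missingness inside the analyzed sample
subset are dropped for that PCA only (no imputation at n = 3); the
ANOVA uses whatever replicates are present and withholds statistics for
genes with empty design cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

_EPS_SS = 1e-12


@dataclass
class PcaResult:
    scores: pd.DataFrame              # samples x components
    loadings: pd.DataFrame            # genes x components
    variance_explained: np.ndarray    # fraction per component
    dropped_genes: list[str] = field(default_factory=list)


def run_pca(norm: pd.DataFrame, meta: pd.DataFrame | None = None,
            subset: pd.Index | list[str] | None = None,
            n_components: int | None = None,
            scale: bool = False) -> PcaResult:
    """Centered (optionally scaled) SVD of the samples-by-genes matrix.

    ``subset`` restricts to a list of sample ids.  Genes with any
    missing value in the subset are dropped for this decomposition.
    """
    cols = list(subset) if subset is not None else list(norm.columns)
    sub = norm[cols]
    complete = sub.dropna(axis=0)
    dropped = [g for g in sub.index if g not in complete.index]
    X = complete.to_numpy().T    # samples x genes
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_comp = min(X.shape)
    k = max_comp if n_components is None else min(n_components, max_comp)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=cols, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=complete.index,
                              columns=comp_names),
        variance_explained=pca.explained_variance_ratio_,
        dropped_genes=dropped,
    )


def top_loading_genes(pca: PcaResult, component: int | str, n: int
                      ) -> tuple[list[str], list[str]]:
    """Top-n most positively and most negatively loading genes.

    ``component`` is 1-based (or a "PCk" label).  Ties break
    lexicographically on the gene label.
    """
    name = component if isinstance(component, str) else f"PC{component}"
    load = pca.loadings[name]
    if n > len(load):
        raise ValueError("n exceeds gene count")
    order_pos = sorted(load.index, key=lambda g: (-load[g], g))
    order_neg = sorted(load.index, key=lambda g: (load[g], g))
    return order_pos[:n], order_neg[:n]


def anova_two_way(values: np.ndarray, fa: np.ndarray, fb: np.ndarray,
                  names: tuple[str, str] = ("A", "B")) -> dict:
    """Two-way ANOVA with interaction, type-II SS, exact-fit guarded.

    When the residual SS is (numerically) zero, each effect follows the
    convention F = 0, p = 1 if its SS is zero, else F = inf, p = 0.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "A": pd.Categorical(fa), "B": pd.Categorical(fb)})
    model = ols("value ~ C(A) * C(B)", data=df).fit()
    tab = anova_lm(model, typ=2)
    ss_resid = float(tab.loc["Residual", "sum_sq"])
    total_ss = float(np.sum((df["value"] - df["value"].mean()) ** 2))
    out: dict = {"ss_resid": ss_resid, "df_resid": float(tab.loc["Residual", "df"])}
    rows = {names[0]: "C(A)", names[1]: "C(B)",
            f"{names[0]}:{names[1]}": "C(A):C(B)"}
    degenerate = ss_resid <= _EPS_SS * max(total_ss, 1.0)
    for label, row in rows.items():
        ss = float(tab.loc[row, "sum_sq"])
        if degenerate:
            zero_eff = ss <= _EPS_SS * max(total_ss, 1.0)
            F, p = (0.0, 1.0) if zero_eff else (np.inf, 0.0)
        else:
            F = float(tab.loc[row, "F"])
            p = float(tab.loc[row, "PR(>F)"])
        out[f"F_{label}"] = F
        out[f"p_{label}"] = p
        out[f"ss_{label}"] = ss
    return out


def tukey_pairs(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons with pooled error, tidy output."""
    res = pairwise_tukeyhsd(np.asarray(values, dtype=float),
                            np.asarray(groups).astype(str))
    return pd.DataFrame(res.summary().data[1:],
                        columns=res.summary().data[0])


@dataclass
class AnovaResult:
    table: pd.DataFrame                        # per (organ, gene) F/p columns
    tukey: dict[tuple, dict[str, pd.DataFrame]] = field(default_factory=dict)
    group_means: pd.DataFrame | None = None


def two_way_anova(norm: pd.DataFrame, meta: pd.DataFrame,
                  factors: tuple[str, str] = ("age_weeks", "strain"),
                  run_tukey: bool = True) -> AnovaResult:
    """Per-gene, per-organ age x strain ANOVA on the normalized matrix."""
    fa_name, fb_name = factors
    rows, tukey, means = [], {}, []
    for organ, samples in meta.groupby("organ").groups.items():
        cols = [s for s in samples if s in norm.columns]
        sub_meta = meta.loc[cols]
        for gene in norm.index:
            y = norm.loc[gene, cols]
            ok = y.notna()
            if ok.sum() < 4:
                continue
            fa = sub_meta.loc[ok, fa_name].to_numpy()
            fb = sub_meta.loc[ok, fb_name].to_numpy()
            cells = pd.crosstab(fa, fb)
            rec = {"organ": organ, "gene": gene}
            if (cells.to_numpy() == 0).any() or cells.shape[0] < 2 or cells.shape[1] < 2:
                rec["flagged"] = "empty cells"
                rows.append(rec)
                continue
            rec.update(anova_two_way(y[ok].to_numpy(), fa, fb,
                                     names=(fa_name, fb_name)))
            rec["flagged"] = ""
            rows.append(rec)
            cm = (pd.DataFrame({"value": y[ok].to_numpy(), fa_name: fa, fb_name: fb})
                  .groupby([fa_name, fb_name])["value"].agg(["mean", "sem", "count"]))
            cm["organ"], cm["gene"] = organ, gene
            means.append(cm.reset_index())
            if run_tukey:
                tukey[(organ, gene)] = {
                    fa_name: tukey_pairs(y[ok].to_numpy(), fa),
                    fb_name: tukey_pairs(y[ok].to_numpy(), fb),
                }
    table = pd.DataFrame(rows).set_index(["organ", "gene"])
    gm = pd.concat(means, ignore_index=True) if means else None
    return AnovaResult(table=table, tukey=tukey, group_means=gm)


def significant_genes(result: AnovaResult, effect: str, alpha: float = 0.05
                      ) -> pd.DataFrame:
    col = f"p_{effect}"
    tab = result.table
    return tab[tab[col].notna() & (tab[col] < alpha)]


def strain_contrast_means(norm: pd.DataFrame, meta: pd.DataFrame,
                          strains: tuple[str, str] = ("SHR", "WKY")
                          ) -> pd.DataFrame:
    """Δ = mean(strain A) − mean(strain B) per (gene, organ, age)."""
    hi, lo = strains
    recs = []
    for (organ, age), samples in meta.groupby(["organ", "age_weeks"]).groups.items():
        cols = [s for s in samples if s in norm.columns]
        sm = meta.loc[cols]
        a = norm[[c for c in cols if sm.loc[c, "strain"] == hi]].mean(axis=1)
        b = norm[[c for c in cols if sm.loc[c, "strain"] == lo]].mean(axis=1)
        d = a - b
        for gene, val in d.items():
            recs.append({"organ": organ, "age_weeks": age, "gene": gene,
                         "delta": val})
    return pd.DataFrame(recs)


def sex_contrast(norm_f: pd.DataFrame, meta_f: pd.DataFrame,
                 norm_m: pd.DataFrame, meta_m: pd.DataFrame,
                 strains: tuple[str, str] = ("SHR", "WKY"),
                 run_tukey: bool = True) -> tuple[pd.DataFrame, AnovaResult]:
    """Age x sex ANOVA on the strain-difference values of the shared panel.

    Restricted to genes, organs and ages present in both cohorts.  Each
    sex contributes one Δ = mean(SHR) − mean(WKY) per (gene, organ,
    age); organs act as replicates within each (age, sex) cell so the
    interaction term has positive error degrees of freedom.
    """
    genes = sorted(set(norm_f.index) & set(norm_m.index))
    organs = sorted(set(meta_f["organ"]) & set(meta_m["organ"]))
    ages = sorted(set(meta_f["age_weeks"]) & set(meta_m["age_weeks"]))
    if not genes or not organs or len(ages) < 2:
        raise ValueError("no shared genes/organs/ages between cohorts")

    parts = []
    for norm, meta, sex in ((norm_f, meta_f, "F"), (norm_m, meta_m, "M")):
        keep = meta["organ"].isin(organs) & meta["age_weeks"].isin(ages)
        d = strain_contrast_means(norm.loc[genes], meta[keep], strains)
        d["sex"] = sex
        parts.append(d)
    delta = pd.concat(parts, ignore_index=True).dropna(subset=["delta"])

    rows, tukey = [], {}
    for gene, grp in delta.groupby("gene"):
        cells = pd.crosstab(grp["age_weeks"], grp["sex"])
        rec = {"gene": gene}
        if (cells.to_numpy() == 0).any() or cells.shape[1] < 2:
            rec["flagged"] = "empty cells"
            rows.append(rec)
            continue
        rec.update(anova_two_way(grp["delta"].to_numpy(),
                                 grp["age_weeks"].to_numpy(),
                                 grp["sex"].to_numpy(),
                                 names=("age_weeks", "sex")))
        rec["flagged"] = ""
        rows.append(rec)
        if run_tukey:
            tukey[(gene,)] = {
                "age_weeks": tukey_pairs(grp["delta"].to_numpy(),
                                         grp["age_weeks"].to_numpy()),
                "sex": tukey_pairs(grp["delta"].to_numpy(),
                                   grp["sex"].to_numpy()),
            }
    table = pd.DataFrame(rows).set_index("gene")
    return delta, AnovaResult(table=table, tukey=tukey)


def expected_tukey_pair_count(levels: int) -> int:
    return len(list(combinations(range(levels), 2)))
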