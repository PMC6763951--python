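"""Metabolite-table processing: from a replicated LC-MS long table to a
screened trait matrix.

The pipeline is the standard untargeted-metabolomics preparation: require
detection (relative to media controls) in at least 3 of 5 replicates, sum
replicate abundances per ion mode and keep the larger ion-mode sum, drop
metabolites with more than 50% missing values, impute the rest with half
the minimum observed value, variance-stabilise with the generalized log,
autoscale each metabolite to mean 0 / SD 1, and test group differences
with one-way ANOVA under Benjamini–Hochberg FDR control.  Externally
computed genome–metabolite association scores are max-normalised per
metabolite; heatmap layout uses Euclidean distance with Ward linkage.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

STAGES = ("raw", "imputed", "glog", "autoscaled", "normalized_score")


@dataclass
class TraitMatrix:
    """Strains × metabolites matrix with a processing-stage tag."""

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage: {self.stage!r}")

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise ValueError(f"expected stage '{stage}', got '{self.stage}'")


def detection_thresholds(table: pd.DataFrame, n_sd: float = 3.0) -> pd.Series:
    """Per metabolite × ion mode detection cut-off: mean + n_sd · SD of the
    media-control abundances (0 when a metabolite/mode has no controls)."""
    ctrl = table[table["is_control"]]
    if ctrl.empty:
        return pd.Series(dtype=float)
    g = ctrl.groupby(["metabolite", "ion_mode"])["abundance"]
    return (g.mean() + n_sd * g.std(ddof=1).fillna(0.0)).rename("threshold")


def build_trait_matrix(
    table: pd.DataFrame,
    min_replicates: int = 3,
    total_replicates: int = 5,
    n_sd: float = 3.0,
) -> TraitMatrix:
    """Collapse the long LC-MS table to a raw strains × metabolites matrix.

    A strain × metabolite value is retained only if, in at least one ion
    mode, the metabolite is detected above the media-control threshold in
    >= ``min_replicates`` replicates.  Retained values are the larger of
    the two per-mode replicate-abundance sums.  Non-detections are NaN.
    """
    if min_replicates > total_replicates:
        raise ValueError("min_replicates cannot exceed total_replicates")
    thresholds = detection_thresholds(table, n_sd=n_sd)
    samples = table[~table["is_control"]].copy()
    if samples.empty:
        raise ValueError("no sample rows in table")
    thr = thresholds.reindex(
        pd.MultiIndex.from_frame(samples[["metabolite", "ion_mode"]])
    ).fillna(0.0).to_numpy()
    samples["detected"] = samples["abundance"].to_numpy() > thr
    grp = samples.groupby(["strain", "metabolite", "ion_mode"])
    stats_df = grp.agg(n_detected=("detected", "sum"), total=("abundance", "sum"))
    detected = stats_df["n_detected"] >= min_replicates
    mode_ok = detected.groupby(level=["strain", "metabolite"]).any()
    sums = stats_df["total"].groupby(level=["strain", "metabolite"]).max()
    values = sums.where(mode_ok).unstack("metabolite")
    values = values.reindex(index=sorted(samples["strain"].unique()),
                            columns=sorted(samples["metabolite"].unique()))
    return TraitMatrix(values=values, stage="raw")


def build_replicate_matrix(
    table: pd.DataFrame,
    min_replicates: int = 3,
    total_replicates: int = 5,
    n_sd: float = 3.0,
) -> tuple[TraitMatrix, dict[str, str]]:
    """Replicate-level variant for ANOVA: rows are strain::replicate, the
    value is the larger ion-mode abundance of that single replicate, kept
    only for strain × metabolite combinations passing the detection rule.
    Returns the matrix plus the row -> strain group map."""
    collapsed = build_trait_matrix(table, min_replicates, total_replicates, n_sd)
    keep = collapsed.values.notna()
    samples = table[~table["is_control"]]
    per_rep = (
        samples.groupby(["strain", "replicate", "metabolite"])["abundance"].max().unstack()
    )
    rows = {}
    groups = {}
    for (strain, rep), row in per_rep.iterrows():
        label = f"{strain}::{rep}"
        mask = keep.loc[strain] if strain in keep.index else False
        rows[label] = row.where(mask)
        groups[label] = strain
    values = pd.DataFrame(rows).T
    return TraitMatrix(values=values, stage="raw"), groups


def impute_and_filter_missing(m: TraitMatrix, max_missing_fraction: float = 0.5) -> TraitMatrix:
    """Drop metabolites with missing fraction > ``max_missing_fraction``;
    replace remaining NaNs with half the matrix-wide minimum positive value."""
    m.require_stage("raw")
    vals = m.values
    frac_missing = vals.isna().mean(axis=0)
    kept = vals.loc[:, frac_missing <= max_missing_fraction]
    if kept.shape[1] == 0:
        raise ValueError("all metabolite columns exceeded the missingness limit")
    positive = kept.to_numpy()[np.isfinite(kept.to_numpy()) & (kept.to_numpy() > 0)]
    fill = positive.min() / 2.0 if positive.size else 0.0
    return TraitMatrix(values=kept.fillna(fill), stage="imputed")


def glog(x, lam: float = 1.0):
    """Generalized log: log2((x + sqrt(x² + λ)) / 2).  glog(0; 1) = −1 and
    glog → log2(x) as λ → 0 for x > 0."""
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + lam)) / 2.0)


def glog_autoscale(m: TraitMatrix, lam: float = 1.0) -> TraitMatrix:
    """glog-transform then autoscale each metabolite to mean 0, sample SD 1.

    Metabolite columns with zero variance after the transform carry no
    information and are dropped with a warning.
    """
    m.require_stage("imputed")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    g = pd.DataFrame(glog(m.values.to_numpy(), lam), index=m.values.index,
                     columns=m.values.columns)
    sd = g.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} zero-variance metabolite column(s)")
        g = g.loc[:, ~zero]
        sd = sd[~zero]
    scaled = (g - g.mean(axis=0)) / sd
    return TraitMatrix(values=scaled, stage="autoscaled")


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values).

    E.g. p = [0.01, 0.02, 0.04] adjusts to q = [0.03, 0.03, 0.04].
    """
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def anova_fdr(
    m: TraitMatrix, groups: Mapping[str, str], alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA per metabolite across groups with BH q-values.

    ``groups`` maps each row label (observation) to its group.  Metabolites
    where any group has fewer than 2 non-missing observations, or where all
    values are identical, are skipped with a warning (F undefined).
    Returns (metabolite, F, p, q, significant) with significant = q < alpha.
    """
    labels = pd.Series({r: groups[r] for r in m.values.index})
    if labels.nunique() < 2:
        raise ValueError("need at least two groups")
    rows = []
    skipped = []
    for met in m.values.columns:
        col = m.values[met]
        arrays = [col[labels == g].dropna().to_numpy() for g in labels.unique()]
        arrays = [a for a in arrays if a.size > 0]
        if len(arrays) < 2 or any(a.size < 2 for a in arrays):
            skipped.append(met)
            continue
        pooled = np.concatenate(arrays)
        if np.ptp(pooled) == 0:
            skipped.append(met)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*arrays)
        if not np.isfinite(f):
            skipped.append(met)
            continue
        rows.append((met, float(f), float(p)))
    if skipped:
        warnings.warn(f"skipped {len(skipped)} metabolite(s) with undefined F")
    out = pd.DataFrame(rows, columns=["metabolite", "F", "p"])
    if len(out):
        out["q"] = bh_qvalues(out["p"])
        out["significant"] = out["q"] < alpha
    else:
        out["q"] = []
        out["significant"] = []
    return out


def normalize_scores(scores: pd.DataFrame) -> TraitMatrix:
    """Per-metabolite max-normalisation of an association-score matrix:
    each column divided by its maximum, so the top strain scores 1.
    All-zero (or non-positive) columns are dropped with a warning."""
    mx = scores.max(axis=0)
    bad = ~(mx > 0)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} column(s) without a positive score")
    kept = scores.loc[:, ~bad]
    return TraitMatrix(values=kept / kept.max(axis=0), stage="normalized_score")


def ward_cluster_order(m: TraitMatrix) -> dict:
    """Euclidean/Ward dendrogram leaf orders for heatmap layout.

    Returns row and column leaf orders (as label lists) plus the scipy
    linkage matrices.
    """
    vals = m.values
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    row_link = linkage(vals.to_numpy(), method="ward", metric="euclidean")
    row_order = [vals.index[i] for i in leaves_list(row_link)]
    if vals.shape[1] >= 2:
        col_link = linkage(vals.to_numpy().T, method="ward", metric="euclidean")
        col_order = [vals.columns[i] for i in leaves_list(col_link)]
    else:
        col_link, col_order = None, list(vals.columns)
    return {"row_order": row_order, "col_order": col_order,
            "row_linkage": row_link, "col_linkage": col_link}


def read_lcms_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["is_control"] = df["is_control"].astype(bool)
    return df


def write_trait_matrix(m: TraitMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="strain")
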