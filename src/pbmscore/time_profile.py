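"""Tumor immune microenvironment (TIME) profiling of whole-bone-marrow
expression: signature-based composition scores, filtering, z-normalisation,
Ward clustering into k patient groups, and cluster associations with the
PBM score and survival.

Composition is estimated with the same single-sample signature-score engine
used for the tumor compartment, applied to the paired whole-bone-marrow
profiles with one marker set per immune cell type.  Users with an external
fraction-scale composition matrix (rows summing to <= 1) can feed it
directly; the mean-fraction filter only applies on that scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io import ClinicalTable, ExpressionMatrix, GeneSignature
from .scoring import score_signatures
from .stats import wilcoxon_rank_sum
from .survival import km_logrank

logger = logging.getLogger(__name__)

#: Stromal cell types excluded from the TIME heat-map by name.
DEFAULT_EXCLUDE = ("Osteoblast", "Osteoclast", "Adipocyte")


def estimate_time(
    wbm: ExpressionMatrix,
    signatures: list[GeneSignature],
    n_perm: int = 1000,
    seed: int | None = 0,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Per-sample immune-cell-type scores of whole-bone-marrow profiles.

    Returns a samples x cell-types matrix of permutation-normalised
    signature scores.
    """
    return score_signatures(wbm, signatures, n_perm=n_perm, seed=seed, min_genes=min_genes)


@dataclass
class FilterResult:
    matrix: pd.DataFrame
    excluded: dict[str, str]  # cell type -> reason


def filter_cell_types(
    matrix: pd.DataFrame,
    exclude_names=DEFAULT_EXCLUDE,
    min_mean_fraction: float | None = None,
) -> FilterResult:
    """Drop named cell types and, for fraction-scale input, rare ones.

    ``min_mean_fraction`` (e.g. 0.01 for the 1% rule) requires the input to
    be on a fraction scale: all values non-negative with per-sample sums
    <= 1; applying it to score-scale input is an error.
    """
    if matrix.empty:
        raise ValueError("empty cell-type matrix")
    excluded: dict[str, str] = {}
    keep = matrix.copy()
    for name in exclude_names:
        if name in keep.columns:
            keep = keep.drop(columns=[name])
            excluded[name] = "named exclusion"
    if min_mean_fraction is not None:
        vals = matrix.to_numpy(dtype=float)
        if (vals < 0).any() or (vals.sum(axis=1) > 1.0 + 1e-9).any():
            raise ValueError(
                "min_mean_fraction requires fraction-scale input "
                "(non-negative, per-sample sums <= 1)"
            )
        means = keep.mean(axis=0)
        rare = means[means < min_mean_fraction].index
        for name in rare:
            excluded[name] = f"mean fraction {means[name]:.4f} < {min_mean_fraction}"
        keep = keep.drop(columns=list(rare))
    if keep.shape[1] == 0:
        raise ValueError("all cell types excluded")
    for name, reason in excluded.items():
        logger.info("excluded cell type %r: %s", name, reason)
    return FilterResult(matrix=keep, excluded=excluded)


def z_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardise each cell type to mean 0, sample sd 1 (ddof = 1)."""
    sd = matrix.std(axis=0, ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance cell types: {zero}")
    return (matrix - matrix.mean(axis=0)) / sd


@dataclass
class TIMEClusters:
    labels: pd.Series  # per sample, 'C1'..'Ck' (C1 = largest)
    k: int
    linkage_method: str = "ward"

    def __post_init__(self) -> None:
        if self.labels.nunique() != self.k:
            raise ValueError("cluster count does not match k")


def cluster_time(matrix: pd.DataFrame, k: int = 5, seed: int | None = None) -> TIMEClusters:
    """Agglomerative Ward clustering of samples on Euclidean distance,
    cut at k clusters; labels renumbered by descending cluster size
    (ties by first appearance).  Ward linkage is deterministic, so the
    seed is unused and accepted only for interface uniformity."""
    if matrix.shape[0] < k:
        raise ValueError(f"need >= {k} samples, have {matrix.shape[0]}")
    Z = linkage(matrix.to_numpy(dtype=float), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], list(raw).index(c)))
    rename = {c: f"C{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series([rename[c] for c in raw], index=matrix.index, name="cluster")
    return TIMEClusters(labels=labels, k=int(labels.nunique()))


def cluster_associations(
    clusters: TIMEClusters,
    pbm: pd.Series,
    clinical: ClinicalTable | None = None,
    time_matrix: pd.DataFrame | None = None,
) -> dict:
    """Relate TIME clusters to the PBM score and survival.

    Reports per-cluster PBM summaries, Wilcoxon p of every cluster against
    the highest-PBM cluster, the log-rank test across clusters (when
    survival data are supplied), and per-cell-type Wilcoxon comparisons
    between PBM-high and PBM-low samples (when the cell-type matrix is
    supplied).  Singleton clusters are flagged unstable, not fatal.
    """
    if not clusters.labels.index.equals(pbm.index):
        if set(clusters.labels.index) != set(pbm.index):
            raise ValueError("cluster and PBM sample ids do not match")
        pbm = pbm.loc[clusters.labels.index]
    by_cluster = pbm.groupby(clusters.labels)
    summary = by_cluster.agg(["mean", "median", "size"])
    top = summary["mean"].idxmax()
    report: dict = {
        "per_cluster_pbm": summary,
        "highest_pbm_cluster": top,
        "vs_highest": {},
        "unstable_clusters": [],
    }
    top_vals = pbm[clusters.labels == top].to_numpy()
    for c in summary.index:
        if c == top:
            continue
        vals = pbm[clusters.labels == c].to_numpy()
        if len(vals) < 2 or len(top_vals) < 2:
            logger.warning("cluster %s comparison unstable (singleton)", c)
            report["unstable_clusters"].append(c)
            continue
        res = wilcoxon_rank_sum(vals, top_vals, mode="approx")
        report["vs_highest"][c] = {"p": res.p_value, "direction": res.direction}
    if clinical is not None and {"os_time", "os_event"} <= set(clinical.data.columns):
        aligned = clinical.data.loc[clusters.labels.index]
        km = km_logrank(
            aligned["os_time"].to_numpy(),
            aligned["os_event"].to_numpy(),
            clusters.labels.to_numpy(),
        )
        report["logrank"] = {"chi_square": km.chi_square, "p": km.p_value}
        medians = {}
        for c, curve in km.curves.items():
            s = curve.iloc[:, 0]
            below = s[s <= 0.5]
            medians[c] = float(below.index[0]) if len(below) else np.inf
        report["best_surviving_cluster"] = max(medians, key=medians.get)
        report["worst_surviving_cluster"] = min(medians, key=medians.get)
    if time_matrix is not None:
        tm = time_matrix.loc[clusters.labels.index]
        med = float(np.median(pbm))
        high = pbm > med
        per_type = {}
        for cell in tm.columns:
            res = wilcoxon_rank_sum(
                tm.loc[high, cell].to_numpy(), tm.loc[~high, cell].to_numpy(), mode="approx"
            )
            per_type[cell] = {"p": res.p_value, "direction": res.direction}
        report["pbm_high_vs_low_by_cell_type"] = per_type
    return report
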