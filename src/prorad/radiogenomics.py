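"""Radiogenomic association: expression filtering, feature-gene correlation
under FDR control, two-way clustering and enrichment-input export.

Genes are first filtered for significant expression (remove when median
< 0.25 AND interquartile range < 0.5 on the normalized scale).  Each
retained gene is then correlated (Pearson) with each radiomic feature
across the aligned biopsy samples; two-sided p-values come from the exact
t-transform with n - 2 degrees of freedom and are Benjamini-Hochberg
adjusted over the whole feature x gene family.  Heatmaps use hierarchical
clustering on the correlation distance d = 1 - r with average linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "CorrelationResult",
    "filter_expression",
    "correlate",
    "cluster_heatmap",
    "sample_clustering",
    "export_enrichment_inputs",
    "linkage_to_newick",
]

#: Filter thresholds on the normalized (SCAN-like, ~[0, 1]) expression scale.
FILTER_MEDIAN = 0.25
FILTER_IQR = 0.50


@dataclass
class CorrelationResult:
    """Feature x gene Pearson correlation with FDR control.

    All matrices are features (rows) x genes (columns) DataFrames sharing
    labels; dropped_features / dropped_genes list constant profiles excluded
    from the family.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    p_fdr: pd.DataFrame
    n_samples: int
    alpha: float = 0.05
    dropped_features: list[str] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def significant_raw(self) -> pd.DataFrame:
        return self.p < self.alpha

    @property
    def significant_fdr(self) -> pd.DataFrame:
        return self.p_fdr < self.alpha

    @property
    def n_significant_raw(self) -> int:
        return int(self.significant_raw.to_numpy().sum())

    @property
    def n_significant_fdr(self) -> int:
        return int(self.significant_fdr.to_numpy().sum())


def filter_expression(expr: pd.DataFrame, median_cutoff: float = FILTER_MEDIAN,
                      iqr_cutoff: float = FILTER_IQR, mode: str = "and",
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove low-expression genes from a genes x samples matrix.

    Default removal rule: median < ``median_cutoff`` AND IQR < ``iqr_cutoff``
    (a gene survives if either criterion clears it).  ``mode="or"`` removes
    on either condition instead.  Returns (filtered matrix, per-gene log with
    median, IQR and the removal flag).
    """
    if expr.shape[1] < 2:
        raise ConfigurationError("need at least 2 samples to filter expression")
    if mode not in ("and", "or"):
        raise ConfigurationError("mode must be 'and' or 'or'")
    med = expr.median(axis=1)
    q75, q25 = expr.quantile(0.75, axis=1), expr.quantile(0.25, axis=1)
    iqr = q75 - q25
    low_med, low_iqr = med < median_cutoff, iqr < iqr_cutoff
    removed = (low_med & low_iqr) if mode == "and" else (low_med | low_iqr)
    log = pd.DataFrame({"median": med, "iqr": iqr, "removed": removed})
    out = expr.loc[~removed]
    if out.empty:
        warnings.warn("expression filter removed every gene")
    return out, log


def _drop_constant(df_rows: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    sd = df_rows.std(axis=1, ddof=0)
    dropped = list(df_rows.index[sd == 0])
    return df_rows.loc[sd > 0], dropped


def correlate(features: pd.DataFrame, expr: pd.DataFrame,
              alpha: float = 0.05) -> CorrelationResult:
    """Pearson-correlate every radiomic feature with every gene.

    ``features`` is samples x features; ``expr`` is genes x samples; they are
    aligned on their shared sample ids (at least 4 required).  Constant
    features or genes are excluded from the family with a log entry.  BH
    adjustment is applied over all evaluated feature-gene pairs.
    """
    shared = [s for s in features.index if s in expr.columns]
    if len(shared) < 4:
        raise ConfigurationError(
            f"only {len(shared)} shared samples between features and expression")
    F = features.loc[shared].T          # features x samples
    G = expr[shared]                    # genes x samples
    F, dropped_f = _drop_constant(F)
    G, dropped_g = _drop_constant(G)
    if dropped_f:
        warnings.warn(f"constant feature(s) excluded from correlation: {dropped_f}")
    if dropped_g:
        warnings.warn(f"constant gene(s) excluded from correlation: {dropped_g}")
    if F.empty or G.empty:
        raise DegenerateInputError("no varying features or genes to correlate")

    n = len(shared)
    Fz = F.to_numpy(dtype=float)
    Gz = G.to_numpy(dtype=float)
    Fz = (Fz - Fz.mean(1, keepdims=True)) / Fz.std(1, keepdims=True)
    Gz = (Gz - Gz.mean(1, keepdims=True)) / Gz.std(1, keepdims=True)
    r = np.clip(Fz @ Gz.T / n, -1.0, 1.0)

    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)

    _, p_adj, _, _ = multipletests(p.ravel(), method="fdr_bh")
    p_fdr = p_adj.reshape(p.shape)

    feats, genes = list(F.index), list(G.index)
    mk = lambda m: pd.DataFrame(m, index=feats, columns=genes)
    return CorrelationResult(r=mk(r), p=mk(p), p_fdr=mk(p_fdr), n_samples=n,
                             alpha=alpha, dropped_features=dropped_f,
                             dropped_genes=dropped_g)


def _correlation_linkage(rows: np.ndarray, method: str) -> np.ndarray:
    """Average-linkage (by default) agglomeration on d = 1 - Pearson r
    between row profiles."""
    if not np.all(np.isfinite(rows)):
        bad = np.where(~np.isfinite(rows).all(axis=1))[0]
        raise ConfigurationError(f"non-finite values in rows {bad.tolist()}")
    r = np.corrcoef(rows)
    d = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return hierarchy.linkage(squareform(d, checks=False), method=method)


def cluster_heatmap(matrix: pd.DataFrame, out_path: str | Path | None = None,
                    signatures: dict | None = None, method: str = "average",
                    ) -> dict:
    """Two-way hierarchical clustering of a feature x gene matrix on
    correlation distance; optionally renders an annotated heatmap.

    ``signatures`` may map panel names to {"up": [...], "down": [...]} gene
    lists; genes in an up-list are marked red, down-list blue, above their
    columns.  Returns row/column leaf orders and linkage matrices.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ConfigurationError("need at least a 2 x 2 matrix to cluster")
    row_Z = _correlation_linkage(matrix.to_numpy(dtype=float), method)
    col_Z = _correlation_linkage(matrix.to_numpy(dtype=float).T, method)
    row_order = list(hierarchy.leaves_list(row_Z))
    col_order = list(hierarchy.leaves_list(col_Z))
    result = {
        "row_order": row_order, "col_order": col_order,
        "row_labels": [matrix.index[i] for i in row_order],
        "col_labels": [matrix.columns[i] for i in col_order],
        "row_linkage": row_Z, "col_linkage": col_Z,
    }
    if out_path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        up, down = set(), set()
        for panel in (signatures or {}).values():
            up |= set(panel.get("up", []))
            down |= set(panel.get("down", []))
        M = matrix.to_numpy(dtype=float)[np.ix_(row_order, col_order)]
        fig, ax = plt.subplots(figsize=(max(6, matrix.shape[1] * 0.14),
                                        max(4, matrix.shape[0] * 0.14)))
        im = ax.imshow(M, aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_yticks(range(len(row_order)))
        ax.set_yticklabels(result["row_labels"], fontsize=4)
        ax.set_xticks(range(len(col_order)))
        ax.set_xticklabels(result["col_labels"], fontsize=4, rotation=90)
        for j, g in enumerate(result["col_labels"]):
            if g in up:
                ax.plot(j, -1.2, "s", color="darkred", ms=3, clip_on=False)
            elif g in down:
                ax.plot(j, -1.2, "s", color="blue", ms=3, clip_on=False)
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        result["figure_path"] = str(out_path)
    return result


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage matrix to a Newick string with branch
    lengths taken from merge-height differences."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        return (f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
                f":{length:.10g}")

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def sample_clustering(expr: pd.DataFrame, gene_subset: list[str] | None = None,
                      method: str = "average") -> dict:
    """Cluster samples on the correlation distance of their expression
    profiles, optionally restricted to a gene subset; exports Newick."""
    genes = list(expr.index if gene_subset is None else
                 [g for g in gene_subset if g in expr.index])
    if not genes:
        raise ConfigurationError("gene subset does not intersect the matrix")
    sub = expr.loc[genes]
    Z = _correlation_linkage(sub.to_numpy(dtype=float).T, method)
    labels = list(sub.columns)
    return {"linkage": Z, "labels": labels,
            "leaf_order": list(hierarchy.leaves_list(Z)),
            "newick": linkage_to_newick(Z, labels)}


def export_enrichment_inputs(result: CorrelationResult, out_dir: str | Path,
                             p_cutoff: float = 0.05) -> dict[str, list[str]]:
    """Write, per radiomic feature, the list of genes with raw p < cutoff
    (one plain-text file per feature, one gene per line), ready for external
    enrichment tools.  Empty lists are written as empty files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lists: dict[str, list[str]] = {}
    for feat in result.p.index:
        genes = list(result.p.columns[result.p.loc[feat] < p_cutoff])
        lists[feat] = genes
        safe = feat.replace("/", "_")
        (out / f"{safe}.txt").write_text("\n".join(genes) + ("\n" if genes else ""))
    return lists
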