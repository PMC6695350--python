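"""Temporally gated gene selection and hierarchical clustering.

Genes whose heat response depends on the time of day are selected by the
interaction term of the condition-by-time model (adjusted p below the
cutoff; no fold-change cut by default, since the interaction effect size
mixes two contrasts).  The selected genes are clustered on per-gene
z-scored expression profiles with agglomerative hierarchical clustering
(Euclidean distance, complete linkage) and the tree is cut into
``n_clusters`` groups representing the major time-of-day response shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import CountMatrix, Thresholds, ValidationError, normalized_counts, GROUPS


@dataclass
class TemporalGeneSet:
    """Genes passing the interaction-term threshold with their statistics."""

    table: pd.DataFrame  # index gene: log2FC, padj of the interaction term

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


def select_temporal_genes(
    de3, thresholds: Thresholds | None = None, apply_lfc_cut: bool = False
) -> TemporalGeneSet:
    """Interaction-significant genes from the analysis-3 result.

    ``apply_lfc_cut`` additionally requires |interaction log2FC| above the
    fold-change cutoff (off by default).
    """
    thresholds = thresholds or Thresholds()
    if de3.contrast != "interaction":
        raise ValidationError(
            f"expected the interaction contrast, got {de3.contrast!r}"
        )
    t = de3.table
    keep = t["padj"] < thresholds.padj_cut
    if apply_lfc_cut:
        keep &= t["log2FC"].abs() > thresholds.lfc_cut
    return TemporalGeneSet(t.loc[keep, ["log2FC", "padj"]].copy())


@dataclass
class ClusterAssignment:
    """Per-gene cluster labels and per-group mean z-scored profiles."""

    labels: pd.Series  # gene -> group id 1..k
    profiles: pd.DataFrame  # group id x profile columns (mean z-score)
    sizes: pd.Series

    @property
    def k(self) -> int:
        return len(self.sizes)


def _zscore_rows(mat: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    vals = mat.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mean) / sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=mat.index, columns=mat.columns), list(mat.index[flat])


def cluster_temporal(
    genes: TemporalGeneSet,
    m: CountMatrix,
    thresholds: Thresholds | None = None,
    use_condition_means: bool = True,
    use_normalized: bool = True,
    method: str = "complete",
    metric: str = "euclidean",
) -> ClusterAssignment:
    """Hierarchical clustering of the temporal gene set.

    Profiles are either the four per-condition means (default) or all
    individual samples, computed from size-factor-normalized counts by
    default (``use_normalized=False`` clusters raw counts).  Rows are
    z-scored (zero-variance rows become all-zero profiles), clustered with
    the given linkage/metric, and the dendrogram is cut into
    ``thresholds.n_clusters`` groups.  Groups are relabeled 1..k by
    decreasing size, ties broken by the smallest member gene id, making
    the labeling invariant to gene input order.
    """
    thresholds = thresholds or Thresholds()
    k = thresholds.n_clusters
    if len(genes) < k:
        raise ValidationError(
            f"need at least n_clusters={k} genes, got {len(genes)}"
        )
    missing = [g for g in genes.genes if g not in m.genes]
    if missing:
        raise ValidationError(f"gene(s) absent from count matrix: {missing[:5]}")

    expr = normalized_counts(m) if use_normalized else m.counts.astype(float)
    expr = expr.loc[genes.genes]
    if use_condition_means:
        labels = m.group_labels()
        expr = pd.DataFrame(
            {g: expr.loc[:, (labels == g).to_numpy()].mean(axis=1) for g in GROUPS}
        )
    # deterministic input order for scipy regardless of caller ordering
    expr = expr.sort_index()
    z, _flat = _zscore_rows(expr)

    if len(z) == 1 or k == 1:
        raw = np.ones(len(z), dtype=int)
    else:
        link = hierarchy.linkage(pdist(z.to_numpy(), metric=metric), method=method)
        raw = hierarchy.fcluster(link, t=k, criterion="maxclust")

    # relabel by decreasing size; ties by smallest member gene id
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), min(z.index[raw == c])),
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = pd.Series([remap[c] for c in raw], index=z.index, name="cluster")

    profiles = z.groupby(labels).mean()
    profiles.index.name = "cluster"
    sizes = labels.value_counts().sort_index()
    return ClusterAssignment(labels=labels, profiles=profiles, sizes=sizes)
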