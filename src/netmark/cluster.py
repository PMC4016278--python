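"""Hierarchical clustering of the signature genes and separation scoring.

Samples (and genes) are clustered agglomeratively on the signature subset
of the log2 matrix. Defaults are the community norm for expression
heatmaps: gene rows standardized to mean 0 / sd 1, correlation distance
(1 - Pearson), average linkage. Whether the two-branch cut of the sample
dendrogram separates cases from controls is quantified as cluster purity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix, PhenotypeLabels
from .errors import DegenerateInputError, ParameterError


def standardize_rows(em: ExpressionMatrix) -> pd.DataFrame:
    """Gene rows to mean 0, sd 1; constant rows become all-zero."""
    x = em.values
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    z = x.sub(mu, axis=0)
    nz = sd > 0
    z.loc[nz] = z.loc[nz].div(sd[nz], axis=0)
    return z


def hierarchical_cluster(
    em_subset: ExpressionMatrix,
    axis: str = "samples",
    distance: str = "correlation",
    linkage_method: str = "average",
    standardize: bool = True,
) -> np.ndarray:
    """Agglomerative merge tree (SciPy linkage matrix) over one axis.

    ``axis="samples"`` clusters columns; ``axis="genes"`` clusters rows.
    Distance is ``"correlation"`` (1 - Pearson) or ``"euclidean"``;
    linkage ``"average"`` or ``"complete"``. Ties in merge distances are
    broken by input order (SciPy convention), so the tree is deterministic
    for a given row/column ordering.
    """
    if axis not in ("samples", "genes"):
        raise ParameterError(f"axis must be 'samples' or 'genes', got {axis!r}")
    if distance not in ("correlation", "euclidean"):
        raise ParameterError(f"unknown distance {distance!r}")
    if linkage_method not in ("average", "complete"):
        raise ParameterError(f"unknown linkage {linkage_method!r}")
    data = standardize_rows(em_subset) if standardize else em_subset.values
    obs = data.to_numpy().T if axis == "samples" else data.to_numpy()
    if obs.shape[0] < 2:
        raise ParameterError("need >= 2 items to cluster")
    if distance == "correlation":
        # constant vectors make the correlation distance 0/0; treat as
        # maximally uninformative (distance 1) instead of propagating NaN
        with np.errstate(invalid="ignore", divide="ignore"):
            dmat = pdist(obs, metric="correlation")
        if np.isnan(dmat).any():
            if (obs.std(axis=1) == 0).any():
                dmat = np.where(np.isnan(dmat), 1.0, dmat)
            else:
                raise DegenerateInputError("NaN distances in clustering input")
    else:
        dmat = pdist(obs, metric="euclidean")
    if np.isnan(dmat).any():
        raise DegenerateInputError("NaN distances in clustering input")
    return linkage(np.clip(dmat, 0.0, None), method=linkage_method)


def cut_two(tree: np.ndarray) -> np.ndarray:
    """Two-branch cut; returns cluster ids in {1, 2} per leaf."""
    return fcluster(tree, t=2, criterion="maxclust")


def sample_separation_score(
    tree: np.ndarray, sample_ids: list[str], labels: PhenotypeLabels
) -> float:
    """Purity of the k=2 sample partition against the phenotype.

    purity = (majority-label count in cluster 1 + majority-label count in
    cluster 2) / n; 1.0 means the cut reproduces the case/control split.
    """
    assign = cut_two(tree)
    y = labels.encode(sample_ids)
    total = 0
    for c in np.unique(assign):
        yc = y[assign == c]
        total += max((yc == 1).sum(), (yc == 0).sum())
    return float(total) / len(sample_ids)


def partition_genes(
    tree: np.ndarray, em_subset: ExpressionMatrix, labels: PhenotypeLabels
) -> pd.DataFrame:
    """k=2 cut of the gene tree, annotated by mean case-control difference.

    Each gene group's ``group_direction`` is the sign of (case mean -
    control mean) averaged over its genes: "up" for positive, "down"
    otherwise. A group collapsing to a singleton under tied distances is
    simply reported as such.
    """
    assign = cut_two(tree)
    y = labels.encode(em_subset.sample_ids).astype(bool)
    x = em_subset.values.to_numpy()
    diff = x[:, y].mean(axis=1) - x[:, ~y].mean(axis=1)
    out = pd.DataFrame(
        {"cluster": assign, "case_minus_control": diff},
        index=pd.Index(em_subset.gene_ids, name="gene_id"),
    )
    group_dir = {
        c: ("up" if diff[assign == c].mean() > 0 else "down") for c in np.unique(assign)
    }
    out["group_direction"] = [group_dir[c] for c in assign]
    return out
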