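"""Phenotype-correlation gene selection.

A gene is phenotype-related when the Pearson correlation between its
expression vector and the binary case/control encoding (control=0, case=1;
the point-biserial correlation) is strictly above the threshold in absolute
value, |r| > 0.8 by default. Phenotype-related genes are then intersected
with the significant DEG list; genes that clear the correlation threshold
without being DEGs are reported separately rather than silently dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PhenotypeLabels
from .errors import ParameterError

log = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.8


def phenotype_correlation(em: ExpressionMatrix, y: PhenotypeLabels) -> pd.Series:
    """Per-gene Pearson r between expression and the 0/1 phenotype.

    Genes with zero variance get r = 0 (logged) so the pipeline stays
    total; the sign convention matches ``direction`` in the DE table
    (r > 0 means higher in cases).
    """
    y.check_matches(em)
    yv = y.encode(em.sample_ids)
    if yv.std() == 0:
        raise ParameterError("phenotype is constant; correlation undefined")
    x = em.values.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    yc = yv - yv.mean()
    denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((yc**2).sum())
    num = xc @ yc
    r = np.zeros(em.n_genes)
    ok = denom > 0
    r[ok] = num[ok] / denom[ok]
    if (~ok).any():
        log.warning(
            "phenotype_correlation: %d zero-variance genes assigned r=0", int((~ok).sum())
        )
    return pd.Series(np.clip(r, -1.0, 1.0), index=pd.Index(em.gene_ids, name="gene_id"), name="r")


def select_phenotype_genes(r: pd.Series, threshold: float = DEFAULT_R_THRESHOLD) -> set[str]:
    """Genes with |r| strictly above the threshold (r = threshold excluded)."""
    if not 0.0 < threshold < 1.0:
        raise ParameterError("threshold must be in (0, 1)")
    return set(r.index[r.abs() > threshold])


def intersect_with_degs(
    selected: set[str], degs: pd.DataFrame
) -> tuple[set[str], list[str]]:
    """Intersect phenotype-related genes with significant DEGs.

    Returns (phenotype-related DEGs, exceptions) where the exceptions are
    phenotype-related genes that are NOT significant DEGs, reported sorted.
    """
    sig = set(degs.index[degs["significant"]])
    inter = selected & sig
    exceptions = sorted(selected - sig)
    if exceptions:
        log.info(
            "intersect_with_degs: %d phenotype-related genes are not DEGs: %s",
            len(exceptions), exceptions[:10],
        )
    return inter, exceptions


def correlation_table(
    em: ExpressionMatrix,
    y: PhenotypeLabels,
    degs: pd.DataFrame,
    threshold: float = DEFAULT_R_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene table: r, selected, is_deg, phenotype_related_deg."""
    r = phenotype_correlation(em, y)
    selected = r.abs() > threshold
    is_deg = pd.Series(False, index=r.index)
    sig = degs.index[degs["significant"]]
    is_deg.loc[is_deg.index.intersection(sig)] = True
    return pd.DataFrame(
        {
            "r": r,
            "selected": selected,
            "is_deg": is_deg,
            "phenotype_related_deg": selected & is_deg,
        }
    )
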