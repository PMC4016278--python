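"""Expression-table ingestion and normalization.

Pipeline order is fixed: read -> collapse probes to genes (mean) ->
global normalization (every array's mean signal forced to a common target,
default 100) -> log2 transform. All downstream statistics operate on the
log2 matrix.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, ExpressionMatrix, PhenotypeLabels, ProbeMatrix
from .errors import DegenerateInputError, FormatError

log = logging.getLogger(__name__)

DEFAULT_TARGET_MEAN = 100.0


def _read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    # pandas silently mangles duplicate column names; check the raw header
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise FormatError(f"duplicate sample columns in {path}: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate row ids in {path}: {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy()][0]
            raise FormatError(f"non-numeric cell in {path} at row {row!r}, column {col!r}")
        df[col] = coerced.astype(float)
    return df


def read_expression_table(
    path: str | Path, probe_map_path: str | Path | None = None
) -> ProbeMatrix | ExpressionMatrix:
    """Read a TSV expression table (first column = row ids, header = samples).

    With ``probe_map_path`` (a two-column ``probe_id<TAB>gene_id`` TSV) the
    rows are treated as probes and a :class:`ProbeMatrix` is returned;
    otherwise rows are genes and a linear-scale :class:`ExpressionMatrix`
    is returned. Row order follows the file.
    """
    df = _read_matrix(path)
    if probe_map_path is None:
        return ExpressionMatrix(df, scale="linear")
    mp = Path(probe_map_path)
    if not mp.exists():
        raise FormatError(f"no such file: {mp}")
    pairs = pd.read_csv(mp, sep="\t", header=None, names=["probe_id", "gene_id"], dtype=str)
    if pairs.isna().any().any():
        raise FormatError(f"malformed probe map {mp}: expected two tab-separated columns")
    probe_to_gene = dict(zip(pairs["probe_id"], pairs["gene_id"]))
    return ProbeMatrix(df, probe_to_gene)


def read_labels(path: str | Path) -> PhenotypeLabels:
    """Read a ``sample_id<TAB>group`` TSV with group in {case, control}."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["sample_id", "group"]:
        raise FormatError(
            f"labels file {path} must have header 'sample_id\\tgroup', got {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        raise FormatError(f"duplicate sample ids in {path}")
    bad = set(df["group"]) - {CASE, CONTROL}
    if bad:
        raise FormatError(f"unknown groups in {path}: {sorted(bad)}")
    return PhenotypeLabels(dict(zip(df["sample_id"], df["group"])))


def collapse_probes(pm: ProbeMatrix) -> ExpressionMatrix:
    """Collapse probes to genes by per-sample arithmetic mean.

    Probes without a gene mapping are dropped (count logged). Output rows
    are ordered by each gene's first probe occurrence; sample columns are
    unchanged.
    """
    if not pm.probe_to_gene:
        raise DegenerateInputError("probe_to_gene map is empty")
    mapped = [p for p in pm.probe_ids if p in pm.probe_to_gene]
    dropped = len(pm.probe_ids) - len(mapped)
    if not mapped:
        raise DegenerateInputError("no probe maps to any gene; empty result")
    if dropped:
        log.info("collapse_probes: dropped %d unmapped probes", dropped)
    sub = pm.values.loc[mapped]
    genes = pd.Index([pm.probe_to_gene[p] for p in mapped], name="gene_id")
    order = genes.drop_duplicates()
    collapsed = sub.groupby(genes, sort=False).mean().loc[order]
    return ExpressionMatrix(collapsed, scale="linear")


def normalize_global(
    em: ExpressionMatrix, target_mean: float = DEFAULT_TARGET_MEAN
) -> ExpressionMatrix:
    """Scale each array (column) so its mean signal equals ``target_mean``."""
    if em.scale != "linear":
        raise DegenerateInputError("normalize_global requires a linear-scale matrix")
    col_means = em.values.mean(axis=0)
    bad = col_means[col_means <= 0]
    if len(bad):
        raise DegenerateInputError(
            f"non-positive column mean for samples {list(bad.index)}"
        )
    return ExpressionMatrix(em.values * (target_mean / col_means), scale="linear")


def log2_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2; refuses an already log-scale matrix."""
    if em.scale != "linear":
        raise DegenerateInputError("matrix is already log2-scale")
    if (em.values.to_numpy() <= 0).any():
        raise DegenerateInputError("log2_transform requires strictly positive values")
    return ExpressionMatrix(np.log2(em.values), scale="log2")


def preprocess(
    data: ProbeMatrix | ExpressionMatrix,
    target_mean: float = DEFAULT_TARGET_MEAN,
    log_scale: bool = True,
) -> ExpressionMatrix:
    """collapse (if probe-level) -> normalize_global -> optional log2."""
    em = collapse_probes(data) if isinstance(data, ProbeMatrix) else data
    em = normalize_global(em, target_mean)
    return log2_transform(em) if log_scale else em
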