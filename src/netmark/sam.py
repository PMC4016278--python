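"""SAM-style moderated two-sample statistic with a pooled permutation null.

For gene *i* with case/control groups of sizes n1, n2:

    d_i = (mean_case,i - mean_ctrl,i) / (s_i + s0)

where s_i is the equal-variance pooled standard error

    s_i = sqrt( (1/n1 + 1/n2) * (SS_case,i + SS_ctrl,i) / (n1 + n2 - 2) )

and s0 (the "fudge factor") is a small constant that keeps low-variance
genes from dominating; by default it is estimated by minimizing the
coefficient of variation of the d spread across the variance spectrum over
a grid of percentiles of s.

Significance comes from a pooled permutation null: under each case/control
relabeling the full d* vector is recomputed (with the same s0) and all
permuted statistics across all genes form one null sample, so that

    p_i = (1 + #{ |d*| >= |d_i| }) / (1 + n_perm * n_genes).

When the number of distinct labelings C(n, n1) is small the null is
enumerated exhaustively (deterministic, seed-free); otherwise distinct
labelings are sampled without replacement. Benjamini–Hochberg adjustment
is then applied across genes, with the significance call at q < alpha.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PhenotypeLabels
from .errors import DegenerateInputError, ParameterError
from .seeding import substream

log = logging.getLogger(__name__)

#: SAM convention: enumerate the null exhaustively below this count
EXHAUSTIVE_LIMIT = 10_000


@dataclass
class SamConfig:
    """Settings for a SAM run.

    s0_mode: "percentile" (CV-minimizing percentile of s, the default),
    "fixed" (use s0_value directly), or "median" (median of s).
    """

    s0_mode: str = "percentile"
    s0_value: float | None = None
    n_perm: int = 1000
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ParameterError("n_perm must be >= 1")
        if self.s0_mode not in ("percentile", "fixed", "median"):
            raise ParameterError(f"unknown s0_mode {self.s0_mode!r}")
        if self.s0_mode == "fixed" and (self.s0_value is None or self.s0_value < 0):
            raise ParameterError("s0_mode='fixed' requires s0_value >= 0")


def _group_stats(x: np.ndarray, case_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (numerator, pooled standard error) for one labeling."""
    n1 = int(case_mask.sum())
    n2 = case_mask.size - n1
    mean_case = x[:, case_mask].mean(axis=1)
    mean_ctrl = x[:, ~case_mask].mean(axis=1)
    ss_case = ((x[:, case_mask] - mean_case[:, None]) ** 2).sum(axis=1)
    ss_ctrl = ((x[:, ~case_mask] - mean_ctrl[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss_case + ss_ctrl) / (n1 + n2 - 2))
    return mean_case - mean_ctrl, s


def sam_statistic(
    em: ExpressionMatrix, y: PhenotypeLabels, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return per-gene (d, s) for the observed labeling."""
    y.check_matches(em)
    if s0 < 0:
        raise ParameterError("s0 must be >= 0")
    case_mask = y.encode(em.sample_ids).astype(bool)
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ParameterError("both groups need >= 2 samples")
    num, s = _group_stats(em.values.to_numpy(), case_mask)
    denom = s + s0
    if np.any(denom == 0):
        gene = em.gene_ids[int(np.argmax(denom == 0))]
        raise DegenerateInputError(
            f"zero variance and s0=0 leaves d undefined for gene {gene!r}"
        )
    return num / denom, s


def estimate_s0(
    s: np.ndarray,
    numerators: np.ndarray,
    cfg: SamConfig,
    percentile_grid: np.ndarray | None = None,
) -> float:
    """Estimate the fudge factor s0.

    In "percentile" mode, candidates are percentiles of s (0..100 in steps
    of 5 by default). For each candidate the genes are binned into ~100
    equal-occupancy groups by s, the spread of d within each bin is taken
    as a MAD-based scale, and the candidate minimizing the coefficient of
    variation of those scales across bins wins — i.e. the s0 that makes the
    spread of d most uniform across the variance spectrum.
    """
    s = np.asarray(s, dtype=float)
    numerators = np.asarray(numerators, dtype=float)
    if s.size < 10:
        raise ParameterError("estimate_s0 needs at least 10 genes")
    if cfg.s0_mode == "fixed":
        return float(cfg.s0_value)
    if cfg.s0_mode == "median":
        return float(np.median(s))
    if np.allclose(s, s[0]):
        warnings.warn("all s identical; s0 percentile search is degenerate", stacklevel=2)
        return float(s[0])
    if percentile_grid is None:
        percentile_grid = np.arange(0, 101, 5)
    n_bins = min(100, max(2, s.size // 10))
    # fixed equal-occupancy binning by s, shared across candidates
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    best_s0, best_cv = 0.0, np.inf
    for pct in percentile_grid:
        cand = float(np.percentile(s, pct))
        d = numerators / (s + cand)
        scales = np.array(
            [1.4826 * np.median(np.abs(d[b] - np.median(d[b]))) for b in bins]
        )
        mean_scale = scales.mean()
        if mean_scale == 0:
            continue
        cv = scales.std(ddof=1) / mean_scale
        if cv < best_cv:
            best_cv, best_s0 = cv, cand
    return best_s0


def _labelings(n: int, n1: int, n_perm: int, seed: int) -> tuple[np.ndarray, bool]:
    """Case-indicator matrix of distinct labelings; (matrix, exhaustive?).

    Exhaustive when C(n, n1) <= n_perm; otherwise Monte-Carlo sampling of
    distinct labelings (without replacement).
    """
    total = comb(n, n1)
    if total <= n_perm:
        masks = np.zeros((total, n), dtype=bool)
        for row, idx in enumerate(itertools.combinations(range(n), n1)):
            masks[row, list(idx)] = True
        return masks, True
    rng = substream(seed, "sam_permutations")
    seen: set[tuple[int, ...]] = set()
    rows = []
    while len(rows) < n_perm:
        idx = tuple(sorted(map(int, rng.choice(n, size=n1, replace=False))))
        if idx in seen:
            continue
        seen.add(idx)
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        rows.append(mask)
    return np.array(rows), False


def permutation_pvalues(
    em: ExpressionMatrix,
    y: PhenotypeLabels,
    s0: float,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """Pooled permutation p-values for |d| against the across-gene null."""
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    y.check_matches(em)
    case_mask = y.encode(em.sample_ids).astype(bool)
    n, n1 = case_mask.size, int(case_mask.sum())
    d_obs, _ = sam_statistic(em, y, s0)

    masks, exhaustive = _labelings(n, n1, n_perm, seed)
    x = em.values.to_numpy()
    n2 = n - n1
    if exhaustive:
        # same arithmetic path as the observed statistic, so the identity
        # labeling reproduces d_obs bit-for-bit
        d_perm = np.empty((em.n_genes, masks.shape[0]))
        for col, mask in enumerate(masks):
            num, s = _group_stats(x, mask)
            d_perm[:, col] = num / (s + s0)
    else:
        p_mat = masks.astype(float)  # n_perm x n
        sum_all = x.sum(axis=1)[:, None]
        sq_all = (x**2).sum(axis=1)[:, None]
        sum_case = x @ p_mat.T  # genes x n_perm
        sq_case = (x**2) @ p_mat.T
        mean_case = sum_case / n1
        mean_ctrl = (sum_all - sum_case) / n2
        ss_case = np.clip(sq_case - n1 * mean_case**2, 0.0, None)
        ss_ctrl = np.clip((sq_all - sq_case) - n2 * mean_ctrl**2, 0.0, None)
        s_perm = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss_case + ss_ctrl) / (n - 2))
        d_perm = (mean_case - mean_ctrl) / (s_perm + s0)

    pooled = np.sort(np.abs(d_perm).ravel())
    n_perm_eff = masks.shape[0]
    # count of pooled null values >= |d_i|
    counts = pooled.size - np.searchsorted(pooled, np.abs(d_obs), side="left")
    p = (1.0 + counts) / (1.0 + n_perm_eff * em.n_genes)
    if exhaustive:
        log.info("permutation_pvalues: exhaustive null with %d labelings", n_perm_eff)
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, None, 1.0)
    return q


def call_degs(
    em: ExpressionMatrix,
    y: PhenotypeLabels,
    cfg: SamConfig | None = None,
    sam_fdr: bool = False,
) -> pd.DataFrame:
    """Full differential-expression table at the configured FDR threshold.

    Columns: gene_id (index), d, s, p_raw, q, direction, significant —
    sorted by q then |d| descending. With ``sam_fdr=True`` an extra
    ``fdr_sam`` column reports SAM's native median-false-positive FDR at
    each gene's |d| cutoff, as a cross-check on the BH q-values.
    """
    cfg = cfg or SamConfig()
    num, s = _numerator_and_s(em, y)
    s0 = estimate_s0(s, num, cfg)
    d, s = sam_statistic(em, y, s0)
    p = permutation_pvalues(em, y, s0, cfg.n_perm, cfg.seed)
    q = bh_adjust(p)
    direction = np.where(num > 0, "up", "down")
    table = pd.DataFrame(
        {
            "d": d,
            "s": s,
            "p_raw": p,
            "q": q,
            "direction": direction,
            "significant": q < cfg.alpha,
        },
        index=pd.Index(em.gene_ids, name="gene_id"),
    )
    table.attrs["s0"] = s0
    table.attrs["alpha"] = cfg.alpha
    if sam_fdr:
        table["fdr_sam"] = _sam_native_fdr(em, y, s0, d, cfg)
    table = table.sort_values(
        ["q", "d"], key=lambda c: c if c.name == "q" else -c.abs(), kind="stable"
    )
    n_sig = int(table["significant"].sum())
    n_up = int((table["significant"] & (table["direction"] == "up")).sum())
    log.info(
        "call_degs: %d significant at q<%g (%d up, %d down); s0=%.4g",
        n_sig, cfg.alpha, n_up, n_sig - n_up, s0,
    )
    return table


def _numerator_and_s(em: ExpressionMatrix, y: PhenotypeLabels):
    case_mask = y.encode(em.sample_ids).astype(bool)
    return _group_stats(em.values.to_numpy(), case_mask)


def _sam_native_fdr(em, y, s0, d_obs, cfg) -> np.ndarray:
    """SAM's median-false-positive FDR at each observed |d| threshold."""
    case_mask = y.encode(em.sample_ids).astype(bool)
    masks, _ = _labelings(case_mask.size, int(case_mask.sum()), cfg.n_perm, cfg.seed)
    x = em.values.to_numpy()
    abs_null = np.empty((masks.shape[0], em.n_genes))
    for k, mask in enumerate(masks):
        num, s = _group_stats(x, mask)
        abs_null[k] = np.abs(num / (s + s0))
    abs_obs = np.abs(d_obs)
    sorted_null = np.sort(abs_null, axis=1)
    # per-permutation false-positive counts at every observed |d| cutoff
    fp_counts = np.stack(
        [
            sorted_null.shape[1] - np.searchsorted(row, abs_obs, side="left")
            for row in sorted_null
        ]
    )
    median_fp = np.median(fp_counts, axis=0)
    called = np.array([(abs_obs >= cut).sum() for cut in abs_obs])
    return np.minimum(1.0, median_fp / np.maximum(called, 1))
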