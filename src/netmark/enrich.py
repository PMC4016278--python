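"""Gene-set over-representation by the exact hypergeometric tail test.

For a candidate list of size k drawn from a universe of N genes and a set
with K members in the universe, the enrichment p-value is the upper tail

    p = P[X >= overlap],  X ~ Hypergeometric(N, K, k)

followed by Benjamini–Hochberg adjustment across the sets tested in one
invocation, with significance called at FDR < 0.05. This is a plain exact
over-representation test; it is not DAVID's jackknifed EASE variant.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .errors import FormatError, ParameterError
from .sam import bh_adjust

log = logging.getLogger(__name__)

DEFAULT_ENRICH_FDR = 0.05


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: ``set_id<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a set are collapsed; an empty description field
    is tolerated. Fewer than three fields on a line is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT lines need >= 3 fields")
            sid, _desc, *genes = fields
            if sid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
            sets[sid] = sorted(dict.fromkeys(g for g in genes if g))
    return sets


def hypergeometric_enrichment(
    gene_list: set[str],
    sets: dict[str, list[str]],
    universe: set[str],
    fdr_threshold: float = DEFAULT_ENRICH_FDR,
) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in each set, BH-adjusted.

    Set membership and the candidate list are both intersected with the
    universe first; candidate genes outside the universe are dropped with
    a warning. Output is sorted by p then set_id (deterministic).
    """
    if not universe:
        raise ParameterError("empty universe")
    outside = gene_list - universe
    if outside:
        log.warning(
            "hypergeometric_enrichment: dropped %d list genes outside the universe",
            len(outside),
        )
    lst = gene_list & universe
    N, k = len(universe), len(lst)
    rows = []
    for sid, members in sets.items():
        in_univ = set(members) & universe
        K = len(in_univ)
        overlap = len(lst & in_univ)
        # upper tail P[X >= overlap]
        p = float(hypergeom.sf(overlap - 1, N, K, k)) if K else 1.0
        rows.append((sid, K, overlap, N, k, min(max(p, 1e-300), 1.0)))
    table = pd.DataFrame(
        rows, columns=["set_id", "set_size", "overlap", "universe_size", "list_size", "p"]
    )
    table["fdr"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    table["significant"] = table["fdr"] < fdr_threshold
    return table.sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)
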