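"""Synthetic two-group expression study with planted structure.

Emulates the design the pipeline targets: a small case/control microarray
cohort (by default 10 vs 10 samples), a gene universe with a planted set of
differentially expressed (DE) genes, an interactome whose edges are partly
co-expressed with a known hub, and a gene-set collection with one set
constructed to overlap the planted DE genes. The generator returns a
:class:`~netmark.containers.GroundTruth` describing everything it planted,
which is the recovery oracle for every downstream stage.

Model
-----
Per-gene baseline abundance on the log2 scale is drawn from
``Normal(8, 1.5)`` (typical for mean-100-normalized oligonucleotide arrays
after log transform). Planted DE genes are shifted by ``±effect_size`` log2
units in the case group (half up, half down; an odd remainder goes up).
I.i.d. Gaussian noise with standard deviation ``noise_sd`` is added on the
log2 scale, and intensities are ``2**log2`` so all values are positive.

Co-expression between interactome partners is induced by re-drawing the
partners' log2 residuals from a shared latent factor with loading
``sqrt(0.95)`` (pairwise residual correlation 0.95), never by copying
columns, which would plant degenerate r = 1 edges.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, ExpressionMatrix, GroundTruth, PhenotypeLabels
from .errors import ParameterError
from .seeding import substream

#: residual correlation planted on co-expressed edges (loading**2)
LATENT_R2 = 0.95

#: residual-sd shrinkage for the planted hub. The hub is modeled as a
#: tightly regulated driver gene: with full background noise its
#: phenotype correlation would sit at the |r| > 0.8 cutoff's sampling
#: margin, so hub recovery would probe the marginal filter's noise rather
#: than the network stage the hub is planted to exercise.
HUB_SD_SHRINK = 0.6

UP = "up"
DOWN = "down"


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def generate_expression(
    n_genes: int,
    n_per_group: int,
    n_de: int,
    effect_size: float,
    noise_sd: float,
    seed: int,
) -> tuple[ExpressionMatrix, PhenotypeLabels, GroundTruth]:
    """Generate a linear-scale expression matrix with planted DE genes.

    Returns the matrix (genes x 2*n_per_group samples, positive
    intensities), the case/control labels, and the ground truth recording
    which genes were shifted and in which direction.
    """
    if n_de > n_genes:
        raise ParameterError(f"n_de={n_de} exceeds n_genes={n_genes}")
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2 (within-group variance undefined)")
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be > 0")

    rng = substream(seed, "expression")
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    case_ids = [f"case_{i + 1:02d}" for i in range(n_per_group)]
    control_ids = [f"control_{i + 1:02d}" for i in range(n_per_group)]
    sample_ids = case_ids + control_ids

    baseline = rng.normal(8.0, 1.5, size=n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    n_up = n_de - n_de // 2  # odd remainder goes up
    up_idx, down_idx = de_idx[:n_up], de_idx[n_up:]

    shift = np.zeros((n_genes, 2 * n_per_group))
    shift[up_idx, :n_per_group] = effect_size
    shift[down_idx, :n_per_group] = -effect_size

    log2_values = (
        baseline[:, None] + shift + rng.normal(0.0, noise_sd, size=(n_genes, 2 * n_per_group))
    )
    values = pd.DataFrame(
        np.exp2(log2_values), index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
    )
    em = ExpressionMatrix(values, scale="linear")
    labels = PhenotypeLabels(
        {**{s: CASE for s in case_ids}, **{s: CONTROL for s in control_ids}}
    )
    direction = {gene_ids[i]: UP for i in up_idx}
    direction.update({gene_ids[i]: DOWN for i in down_idx})
    truth = GroundTruth(
        de_gene_ids={gene_ids[i] for i in de_idx},
        de_direction=direction,
        effect_size=float(effect_size),
        seed=int(seed),
    )
    return em, labels, truth


def _row_moments(
    log2: pd.DataFrame, gene: str, is_case: np.ndarray, per_group: bool
) -> tuple[np.ndarray, float]:
    """Mean structure and pooled within-group sd of one row.

    DE genes keep their empirical per-group means (the planted shift);
    null genes get their grand mean, so a spurious finite-sample group
    difference is not locked into the re-drawn row."""
    row = log2.loc[gene].to_numpy()
    if per_group:
        mu = np.where(is_case, row[is_case].mean(), row[~is_case].mean())
    else:
        mu = np.full(row.size, row.mean())
    sd = math.sqrt((np.var(row[is_case], ddof=1) + np.var(row[~is_case], ddof=1)) / 2.0)
    return mu, sd


def _redraw_with_factors(
    log2: pd.DataFrame,
    gene: str,
    is_case: np.ndarray,
    factors: np.ndarray,
    loadings: np.ndarray,
    rng: np.random.Generator,
    per_group: bool = True,
    sd_scale: float = 1.0,
) -> None:
    """Re-draw one row around its mean structure with residuals built from
    the given latent factors (rows of ``factors``) plus an independent
    component filling the remaining unit variance. Mutates ``log2`` in
    place."""
    mu, sd = _row_moments(log2, gene, is_case, per_group)
    sd *= sd_scale
    load2 = float((loadings**2).sum())
    if load2 > 1.0:
        raise ParameterError("latent loadings exceed the unit variance budget")
    eps = rng.normal(0.0, 1.0, size=log2.shape[1])
    resid = loadings @ factors + math.sqrt(1.0 - load2) * eps
    log2.loc[gene] = mu + sd * resid


def generate_interactome(
    em: ExpressionMatrix,
    labels: PhenotypeLabels,
    truth: GroundTruth,
    n_edges: int,
    planted_hub_degree: int,
    frac_coexpressed: float,
    seed: int,
) -> tuple[pd.DataFrame, ExpressionMatrix, GroundTruth]:
    """Generate an interactome over the matrix's genes, planting a hub.

    One designated node (the hub, itself an up-regulated planted DE gene)
    receives ``planted_hub_degree`` co-expressed edges to other planted DE
    genes of either direction; a fraction ``frac_coexpressed`` of all edges
    (hub edges included) connect co-expressed pairs; remaining edges
    connect independent genes. No self-loops, no duplicate unordered pairs.

    Non-hub co-expressed pairs share one latent factor per pair (residual
    correlation 0.95). The hub's residual variance is split across one
    latent factor per hub edge, each shared with that edge's partner, with
    the loading sign matched to the partner's DE direction; together with
    the concordant or anti-concordant group shift this puts every planted
    hub edge well past the |r| > 0.8 co-expression filter without planting
    a single module-wide factor that would dominate sample profiles.

    Returns the edge table (columns ``gene_a``, ``gene_b``, canonical
    order), a new expression matrix with the co-expressed rows re-drawn,
    and the updated ground truth.
    """
    genes = em.gene_ids
    n = len(genes)
    if not 0.0 <= frac_coexpressed <= 1.0:
        raise ParameterError("frac_coexpressed must be in [0, 1]")
    if n_edges > n * (n - 1) // 2:
        raise ParameterError(f"n_edges={n_edges} exceeds C({n},2)")
    if planted_hub_degree >= n:
        raise ParameterError("planted_hub_degree must be < number of genes")

    rng = substream(seed, "interactome")
    if em.scale != "linear":
        raise ParameterError("generate_interactome expects the linear-scale matrix")
    log2 = pd.DataFrame(
        np.log2(em.values.to_numpy()), index=em.values.index, columns=em.values.columns
    )

    edges: list[tuple[str, str]] = []
    used_pairs: set[tuple[str, str]] = set()
    coexpressed: set[tuple[str, str]] = set()
    reserved: set[str] = set()  # genes whose rows were re-drawn; keep disjoint
    hub = None

    case = set(labels.case_ids)
    is_case = np.array([s in case for s in log2.columns])
    n_coexpr = int(round(frac_coexpressed * n_edges))
    if planted_hub_degree > 0:
        k = planted_hub_degree
        up_genes = sorted(g for g, d in truth.de_direction.items() if d == UP)
        de_genes = sorted(truth.de_gene_ids)
        if not up_genes or len(de_genes) < k + 1:
            raise ParameterError(
                "planted_hub_degree requires an up-regulated hub candidate and "
                "at least planted_hub_degree other planted DE genes"
            )
        hub = str(rng.choice(up_genes))
        partners = [str(g) for g in rng.choice(sorted(set(de_genes) - {hub}), k, False)]
        # one latent per hub edge; the hub splits its residual variance
        # across them, each partner loads sqrt(LATENT_R2) with the sign of
        # its own DE direction so the total edge correlation clears the
        # filter on the correct side
        factors = rng.normal(0.0, 1.0, size=(k, log2.shape[1]))
        hub_load = np.full(k, math.sqrt(LATENT_R2 / k))
        _redraw_with_factors(
            log2, hub, is_case, factors, hub_load, rng, sd_scale=HUB_SD_SHRINK
        )
        for j, p in enumerate(partners):
            sign = 1.0 if truth.de_direction[p] == UP else -1.0
            load = np.zeros(k)
            load[j] = sign * math.sqrt(LATENT_R2)
            _redraw_with_factors(log2, p, is_case, factors, load, rng)
            e = _canonical(hub, p)
            edges.append(e)
            used_pairs.add(e)
            coexpressed.add(e)
        reserved.update([hub] + partners)

    # additional co-expressed pairs, disjoint from the hub module and from
    # the DE genes so they do not compete for network membership
    n_extra_pairs = max(0, n_coexpr - planted_hub_degree)
    pool = sorted(set(genes) - reserved - truth.de_gene_ids)
    if len(pool) < 2 * n_extra_pairs:
        raise ParameterError("not enough free genes for the requested co-expressed edges")
    picked = rng.choice(pool, size=2 * n_extra_pairs, replace=False)
    lam = np.array([math.sqrt(LATENT_R2)])
    for i in range(n_extra_pairs):
        a, b = str(picked[2 * i]), str(picked[2 * i + 1])
        z = rng.normal(0.0, 1.0, size=(1, log2.shape[1]))
        _redraw_with_factors(log2, a, is_case, z, lam, rng, per_group=False)
        _redraw_with_factors(log2, b, is_case, z, lam, rng, per_group=False)
        e = _canonical(a, b)
        edges.append(e)
        used_pairs.add(e)
        coexpressed.add(e)

    # background edges between independent genes
    n_random = n_edges - len(edges)
    attempts = 0
    while n_random > 0:
        attempts += 1
        if attempts > 200 * n_edges + 1000:
            raise ParameterError("duplicate-pair exhaustion while sampling random edges")
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        e = _canonical(genes[i], genes[j])
        if e in used_pairs:
            continue
        edges.append(e)
        used_pairs.add(e)
        n_random -= 1

    new_em = ExpressionMatrix(np.exp2(log2), scale="linear")
    truth.planted_hub = hub
    truth.coexpressed_edges = coexpressed
    edge_df = pd.DataFrame(edges, columns=["gene_a", "gene_b"])
    return edge_df, new_em, truth


def generate_gene_sets(
    genes: list[str],
    truth: GroundTruth,
    n_sets: int,
    set_size: int,
    de_overlap: int,
    seed: int,
) -> dict[str, list[str]]:
    """Generate a gene-set collection with exactly one planted enriched set.

    The enriched set contains ``de_overlap`` planted DE genes (the rest of
    its members are non-DE); all other sets are uniform random draws from
    the full gene universe. The enriched set's id is written to
    ``truth.enriched_set_id``.
    """
    if set_size > len(genes):
        raise ParameterError(f"set_size={set_size} exceeds universe size {len(genes)}")
    if de_overlap > min(set_size, len(truth.de_gene_ids)):
        raise ParameterError(
            "de_overlap must be <= min(set_size, number of planted DE genes)"
        )
    rng = substream(seed, "gene_sets")
    set_ids = [f"GS{i:04d}" for i in range(n_sets)]
    enriched_pos = int(rng.integers(0, n_sets))

    de_sorted = sorted(truth.de_gene_ids)
    non_de_sorted = sorted(set(genes) - truth.de_gene_ids)
    collection: dict[str, list[str]] = {}
    for pos, sid in enumerate(set_ids):
        if pos == enriched_pos:
            members = list(rng.choice(de_sorted, size=de_overlap, replace=False))
            members += list(
                rng.choice(non_de_sorted, size=set_size - de_overlap, replace=False)
            )
        else:
            members = list(rng.choice(sorted(genes), size=set_size, replace=False))
        collection[sid] = sorted(str(g) for g in members)
    truth.enriched_set_id = set_ids[enriched_pos]
    return collection


@dataclass
class SyntheticParams:
    """Study conditions for the synthetic cohort.

    Defaults mirror the targeted design at test scale: a 10 vs 10 cohort,
    a 2,000-gene universe with 200 planted DE genes at a 2.0 log2-unit
    shift over noise sd 0.5, a 400-edge interactome with a degree-6 planted
    hub and 10% co-expressed edges, and 50 gene sets of 20 genes with one
    set overlapping 15 planted DE genes.
    """

    n_genes: int = 2000
    n_per_group: int = 10
    n_de: int = 200
    effect_size: float = 2.0
    noise_sd: float = 0.5
    n_edges: int = 400
    planted_hub_degree: int = 6
    frac_coexpressed: float = 0.1
    n_sets: int = 50
    set_size: int = 20
    de_overlap: int = 15


@dataclass
class SyntheticBundle:
    """Everything one synthetic study comprises."""

    expression: ExpressionMatrix
    labels: PhenotypeLabels
    edges: pd.DataFrame
    gene_sets: dict[str, list[str]]
    truth: GroundTruth
    params: SyntheticParams


def generate_dataset(params: SyntheticParams, seed: int) -> SyntheticBundle:
    """Generate the full synthetic study from one seed."""
    em, labels, truth = generate_expression(
        params.n_genes,
        params.n_per_group,
        params.n_de,
        params.effect_size,
        params.noise_sd,
        seed,
    )
    edges, em, truth = generate_interactome(
        em,
        labels,
        truth,
        params.n_edges,
        params.planted_hub_degree,
        params.frac_coexpressed,
        seed,
    )
    gene_sets = generate_gene_sets(
        em.gene_ids, truth, params.n_sets, params.set_size, params.de_overlap, seed
    )
    return SyntheticBundle(em, labels, edges, gene_sets, truth, params)


def write_gmt(gene_sets: dict[str, list[str]], path: Path, description: str = "synthetic") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in gene_sets:
            fh.write("\t".join([sid, description] + list(gene_sets[sid])) + "\n")


def write_fixture_bundle(out_dir: str | Path, bundle: SyntheticBundle) -> dict:
    """Write the bundle as plain-text fixtures; return the file manifest.

    Files: ``expression.tsv`` (linear intensities, first column gene_id),
    ``labels.tsv``, ``edges.tsv``, ``sets.gmt``, ``truth.json``, and
    ``manifest.json`` listing paths, seed and parameters.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": out / "expression.tsv",
            "labels": out / "labels.tsv",
            "edges": out / "edges.tsv",
            "gene_sets": out / "sets.gmt",
            "truth": out / "truth.json",
        }
        bundle.expression.values.to_csv(paths["expression"], sep="\t")
        with open(paths["labels"], "w", encoding="utf-8") as fh:
            fh.write("sample_id\tgroup\n")
            for s, g in bundle.labels.groups.items():
                fh.write(f"{s}\t{g}\n")
        bundle.edges.to_csv(paths["edges"], sep="\t", index=False, header=False)
        write_gmt(bundle.gene_sets, paths["gene_sets"])
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            json.dump(bundle.truth.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest = {
            "files": {k: str(p) for k, p in paths.items()},
            "seed": bundle.truth.seed,
            "params": asdict(bundle.params),
            "sha256": {
                k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()
            },
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except OSError as exc:
        raise OSError(f"failed writing fixture bundle under {out}: {exc}") from exc
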