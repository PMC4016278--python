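"""Core in-memory containers for the pipeline.

Expression data is held as a pandas DataFrame (rows = probes or genes,
columns = samples) wrapped in a thin dataclass that tracks the measurement
scale, so that scale-sensitive operations (log transform, SAM, correlations)
can refuse inputs on the wrong scale instead of silently producing nonsense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, ParameterError

LINEAR = "linear"
LOG2 = "log2"


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dupes}")


@dataclass
class ExpressionMatrix:
    """A genes x samples intensity matrix with a scale tag.

    ``values.index`` are gene identifiers, ``values.columns`` sample
    identifiers; both must be unique. ``scale`` is ``"linear"`` (positive
    intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ParameterError(f"unknown scale tag {self.scale!r}")
        _check_unique(list(self.values.index), "gene ids")
        _check_unique(list(self.values.columns), "sample ids")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise FormatError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ProbeMatrix:
    """Probe-level intensities plus a (possibly many-to-one) probe->gene map.

    Probes absent from the map are allowed; they are dropped at collapse
    time with a logged count.
    """

    values: pd.DataFrame
    probe_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "probe ids")
        _check_unique(list(self.values.columns), "sample ids")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr) & (arr > 0)):
            raise FormatError("probe matrix values must be finite and > 0")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


CASE = "case"
CONTROL = "control"


@dataclass
class PhenotypeLabels:
    """Binary case/control labels over a sample set.

    ``groups`` maps sample id -> {"case", "control"}. The numeric encoding
    used by every statistic is control=0, case=1.
    """

    groups: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values() if g not in (CASE, CONTROL)}
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        if not self.case_ids or not self.control_ids:
            raise DegenerateInputError("both case and control groups must be non-empty")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)

    @property
    def case_ids(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == CASE]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == CONTROL]

    def encode(self, sample_ids: list[str] | None = None) -> np.ndarray:
        """0/1 vector (control=0, case=1) in the given sample order."""
        ids = self.sample_ids if sample_ids is None else sample_ids
        missing = [s for s in ids if s not in self.groups]
        if missing:
            raise FormatError(f"samples without phenotype label: {missing}")
        return np.array([1 if self.groups[s] == CASE else 0 for s in ids], dtype=float)

    def check_matches(self, em: ExpressionMatrix) -> None:
        if set(self.groups) != set(em.sample_ids):
            raise FormatError(
                "phenotype sample ids do not match the expression matrix: "
                f"labels-only={sorted(set(self.groups) - set(em.sample_ids))}, "
                f"matrix-only={sorted(set(em.sample_ids) - set(self.groups))}"
            )


@dataclass
class GroundTruth:
    """What the synthetic generator planted, for downstream recovery checks."""

    de_gene_ids: set[str] = field(default_factory=set)
    de_direction: dict[str, str] = field(default_factory=dict)
    effect_size: float = 0.0
    planted_hub: str | None = None
    coexpressed_edges: set[tuple[str, str]] = field(default_factory=set)
    enriched_set_id: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "de_gene_ids": sorted(self.de_gene_ids),
            "de_direction": dict(sorted(self.de_direction.items())),
            "effect_size": self.effect_size,
            "planted_hub": self.planted_hub,
            "coexpressed_edges": sorted(list(e) for e in self.coexpressed_edges),
            "enriched_set_id": self.enriched_set_id,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            de_gene_ids=set(d["de_gene_ids"]),
            de_direction=dict(d["de_direction"]),
            effect_size=float(d["effect_size"]),
            planted_hub=d["planted_hub"],
            coexpressed_edges={tuple(e) for e in d["coexpressed_edges"]},
            enriched_set_id=d["enriched_set_id"],
            seed=int(d["seed"]),
        )
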