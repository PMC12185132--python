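"""Core in-memory containers shared across the pipeline stages.

The pipeline moves a genes x samples matrix through a fixed chain of
stages (counts -> cpm -> log -> normalized -> adjusted -> standardized);
:class:`ExpressionMatrix` enforces that ordering so a stage can never be
applied to the wrong input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed stages, in pipeline order. Transitions must move forward.
STAGES = ("counts", "cpm", "log", "normalized", "adjusted", "standardized")


class StageError(ValueError):
    """Raised when an operation receives a matrix at the wrong stage."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values tagged with a pipeline stage.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    stage
        One of :data:`STAGES`.
    """

    values: pd.DataFrame
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def advance(self, new_values: pd.DataFrame, new_stage: str) -> "ExpressionMatrix":
        """Return a new matrix at ``new_stage``, enforcing forward stage order."""
        if new_stage not in STAGES:
            raise StageError(f"unknown stage {new_stage!r}")
        if STAGES.index(new_stage) <= STAGES.index(self.stage) and new_stage != self.stage:
            raise StageError(
                f"cannot move backwards from stage {self.stage!r} to {new_stage!r}"
            )
        return ExpressionMatrix(values=new_values, stage=new_stage)

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"operation requires stage in {stages}, got {self.stage!r}"
            )


@dataclass
class SampleTable:
    """Per-sample metadata: condition, batch, and further covariates.

    ``retained`` covariates carry biological signal that adjustment must
    preserve (treatment/condition, temperature, ...); ``unwanted``
    covariates are technical (batch, instrument, ...) and are removed.
    """

    table: pd.DataFrame
    retained: list[str] = field(default_factory=lambda: ["condition"])
    unwanted: list[str] = field(default_factory=lambda: ["batch"])

    def __post_init__(self) -> None:
        if "sample" in self.table.columns:
            self.table = self.table.set_index("sample")
        for col in ("condition",):
            if col not in self.table.columns:
                raise ValueError(f"sample table must have a {col!r} column")
        for col in self.retained + self.unwanted:
            if col not in self.table.columns:
                raise ValueError(f"covariate column {col!r} missing from sample table")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in sample table")

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def conditions(self) -> list[str]:
        """Unique condition labels in first-appearance order."""
        return list(dict.fromkeys(self.table["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        mask = self.table["condition"] == condition
        return self.table.index[mask].tolist()

    def check_matches(self, expr: ExpressionMatrix) -> None:
        missing = set(expr.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")

    def subset(self, sample_ids: list[str]) -> "SampleTable":
        return SampleTable(
            table=self.table.loc[sample_ids].copy(),
            retained=list(self.retained),
            unwanted=list(self.unwanted),
        )


Pair = tuple[int, int]


def canonical_pair(i: int, j: int) -> Pair:
    """Unordered gene pair as a sorted tuple; rejects self pairs."""
    if i == j:
        raise ValueError("self pair")
    return (i, j) if i < j else (j, i)


@dataclass
class GroundTruth:
    """Known multi-condition precision structure behind simulated data."""

    precision_set: dict[str, np.ndarray]
    shared_support: set[Pair]
    specific_support: dict[str, set[Pair]]
    condition_names: list[str]

    def __post_init__(self) -> None:
        for name, theta in self.precision_set.items():
            if not np.allclose(theta, theta.T):
                raise ValueError(f"precision matrix for {name} not symmetric")
            if np.linalg.eigvalsh(theta).min() <= 0:
                raise ValueError(f"precision matrix for {name} not positive definite")
        for k in self.condition_names:
            if self.specific_support[k] & self.shared_support:
                raise ValueError("specific support overlaps shared support")

    def support(self, condition: str) -> set[Pair]:
        return self.shared_support | self.specific_support[condition]

    @property
    def p(self) -> int:
        return next(iter(self.precision_set.values())).shape[0]


@dataclass
class SpeciesPanelTruth:
    """Planted multi-species HOG-edge panel with known conservation status.

    ``edge_lists`` maps species -> condition -> list of gene-id pairs;
    ``hog_maps`` maps species -> gene id -> HOG id; ``planted_conserved``
    is the set of HOG pairs engineered to satisfy the three-clade
    conservation rule (and no other pair satisfies it).
    """

    species: list[str]
    hog_maps: dict[str, dict[str, str]]
    edge_lists: dict[str, dict[str, list[tuple[str, str]]]]
    planted_conserved: set[tuple[str, str]]
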