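"""Shared domain types for the multi-study expression / survival pipeline.

The pipeline consumes per-study log2 expression matrices with two-class
(cancer vs normal) labels, immune gene sets, and per-patient survival
tables.  All containers are thin dataclasses around pandas/numpy objects
and validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CANCER = "cancer"
NORMAL = "normal"
VALID_CLASSES = frozenset({CANCER, NORMAL})


@dataclass
class ExpressionStudy:
    """One study's genes x samples log2 expression matrix with class labels.

    Parameters
    ----------
    study_id : str
        Short identifier for the study (e.g. the cancer type).
    values : pandas.DataFrame
        Genes in rows (index = unique gene symbols), samples in columns,
        entries are normalized log2 expression intensities.
    class_of : mapping of sample id -> {"cancer", "normal"}
        Must cover every sample column; each class needs at least two
        samples so label permutations are possible.
    """

    study_id: str
    values: pd.DataFrame
    class_of: Mapping[str, str]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str).str.upper()
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(
                f"study {self.study_id!r}: duplicate gene symbols {dups}"
            )
        missing = [s for s in self.values.columns if s not in self.class_of]
        if missing:
            raise ValueError(
                f"study {self.study_id!r}: samples without class label: {missing}"
            )
        bad = {s: c for s, c in self.class_of.items() if c not in VALID_CLASSES}
        if bad:
            raise ValueError(
                f"study {self.study_id!r}: invalid class labels {bad}; "
                f"expected one of {sorted(VALID_CLASSES)}"
            )
        for cls in (CANCER, NORMAL):
            if len(self.sample_ids(cls)) < 2:
                raise ValueError(
                    f"study {self.study_id!r}: class {cls!r} has fewer than 2 samples"
                )
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError(f"study {self.study_id!r}: non-finite expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sample_ids(self, cls: str) -> list[str]:
        return [s for s in self.values.columns if self.class_of[s] == cls]

    def class_matrix(self, cls: str) -> np.ndarray:
        """Genes x samples submatrix for one class, as a float array."""
        return self.values[self.sample_ids(cls)].to_numpy()


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (symbols uppercased on load)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(m.upper() for m in self.members))


@dataclass
class SurvivalCohort:
    """Per-patient survival times with censoring and gene expression.

    ``table`` holds one row per patient with columns ``time`` (months,
    strictly positive), ``event`` (1 = death/recurrence, 0 = censored)
    and one column per gene (log2 expression).
    """

    cohort_id: str
    table: pd.DataFrame
    gene_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "time" not in self.table.columns or "event" not in self.table.columns:
            raise ValueError("cohort table needs 'time' and 'event' columns")
        if not self.gene_columns:
            self.gene_columns = [
                c for c in self.table.columns if c not in ("time", "event")
            ]
        t = self.table["time"].to_numpy(dtype=float)
        if (t <= 0).any() or not np.isfinite(t).all():
            raise ValueError("survival times must be strictly positive and finite")
        ev = self.table["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (event)")
        absent = [g for g in self.gene_columns if g not in self.table.columns]
        if absent:
            raise ValueError(f"genes missing from cohort table: {absent}")

    @property
    def n_patients(self) -> int:
        return len(self.table)

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    def expression(self, gene: str) -> np.ndarray:
        return self.table[gene].to_numpy(dtype=float)


DEFAULT_FDR_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3)


@dataclass
class PipelineConfig:
    """Tunable constants for the whole pipeline.

    ``fdr_threshold_grid`` is the grid of per-study FDR thresholds l used
    by the consistency meta-analysis; ``fc_cutoff``/``fc_exclusion_min_studies``
    encode the signature rule "exclude genes with fold change < 2 in five
    or more cancer types".
    """

    fdr_threshold_grid: Sequence[float] = DEFAULT_FDR_GRID
    n_label_permutations: int = 100       # B_de, label permutations per study
    n_fdrg_permutations: int = 20         # B_g, within-study FDR shuffles
    fdrg_target: float = 0.05
    min_called: int | None = None         # None -> all studies (strict consistency)
    fc_exclusion_min_studies: int = 5
    fc_cutoff: float = 2.0
    cutpoint_percentile_range: tuple[float, float] = (0.15, 0.85)
    n_pairs: int = 100                    # cap on cross-class pairs for rank product
    seed: int = 0

    def __post_init__(self) -> None:
        grid = [float(l) for l in self.fdr_threshold_grid]
        if not grid or any(not (0.0 < l < 1.0) for l in grid):
            raise ValueError("fdr_threshold_grid values must lie in (0, 1)")
        if sorted(grid) != grid:
            raise ValueError("fdr_threshold_grid must be sorted ascending")
        self.fdr_threshold_grid = tuple(grid)
        lo, hi = self.cutpoint_percentile_range
        if not (0.05 <= lo < hi <= 0.95):
            raise ValueError("cutpoint_percentile_range must be within [0.05, 0.95]")
        if not (0.0 < self.fdrg_target < 1.0):
            raise ValueError("fdrg_target must be in (0, 1)")
        for name in ("n_label_permutations", "n_fdrg_permutations", "n_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
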