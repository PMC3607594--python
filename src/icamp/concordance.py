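"""Validation-cohort concordance labeling.

Each signature gene is labeled elevated / repressed / unchanged /
undetermined in an independent disease from counts of external datasets
showing significant (p < 0.05) up- or down-regulation:

* elevated: at least 1 dataset up and none down, OR at least 3 up and at
  most 1 down;
* repressed: the mirror rule;
* unchanged: no significant call in either direction;
* undetermined: anything else (conflicting evidence, or both rules firing
  simultaneously, which happens when both directions reach 3 calls), and
  genes tested in no dataset.

A gene is concordant when its validation label agrees with its signature
direction (up & elevated, or down & repressed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

LABELS = ("elevated", "repressed", "unchanged", "undetermined")


@dataclass(frozen=True)
class DirectionEvidence:
    """Counts of validation datasets calling a gene up or down."""

    gene: str
    n_up: int
    n_down: int
    n_tested: int

    def __post_init__(self) -> None:
        if min(self.n_up, self.n_down, self.n_tested) < 0:
            raise ValueError("evidence counts must be non-negative")
        if self.n_up + self.n_down > self.n_tested:
            raise ValueError(
                f"{self.gene}: n_up + n_down exceeds n_tested "
                f"({self.n_up}+{self.n_down} > {self.n_tested})"
            )


@dataclass(frozen=True)
class ConcordanceLabel:
    gene: str
    label: str
    concordant: bool


def label_gene(ev: DirectionEvidence) -> str:
    """Apply the elevation/repression labeling rule to one gene."""
    if ev.n_tested == 0:
        log.debug("%s tested in no dataset; labeling undetermined", ev.gene)
        return "undetermined"
    elevated = (ev.n_up >= 1 and ev.n_down == 0) or (ev.n_up >= 3 and ev.n_down <= 1)
    repressed = (ev.n_down >= 1 and ev.n_up == 0) or (ev.n_down >= 3 and ev.n_up <= 1)
    if elevated and repressed:
        return "undetermined"
    if elevated:
        return "elevated"
    if repressed:
        return "repressed"
    if ev.n_up == 0 and ev.n_down == 0:
        return "unchanged"
    return "undetermined"


@dataclass
class ConcordanceSummary:
    table: pd.DataFrame          # per gene: direction, label, concordant
    crosstab: pd.DataFrame       # signature direction x validation label
    n_concordant: int
    n_genes: int

    def concordant_by_direction(self, direction: str) -> int:
        t = self.table
        return int(((t["direction"] == direction) & t["concordant"]).sum())


def concordance_summary(
    labels: Mapping[str, str] | Iterable[ConcordanceLabel],
    signature: Iterable,  # SignatureGene or (gene, direction) pairs
) -> ConcordanceSummary:
    """Cross-tabulate signature direction against validation label.

    ``signature`` may be SignatureGene objects or (gene, direction)
    pairs.  A signature gene missing from ``labels`` is counted as
    undetermined with a warning.
    """
    if not isinstance(labels, Mapping):
        labels = {cl.gene: cl.label for cl in labels}
    labels = {g.upper(): v for g, v in labels.items()}
    rows = []
    for item in signature:
        if hasattr(item, "gene"):
            gene, direction = item.gene, item.direction
        else:
            gene, direction = item
        gene = gene.upper()
        label = labels.get(gene)
        if label is None:
            log.warning("gene %s missing from validation labels; "
                        "counting as undetermined", gene)
            label = "undetermined"
        concordant = (direction == "up" and label == "elevated") or (
            direction == "down" and label == "repressed"
        )
        rows.append({"gene": gene, "direction": direction, "label": label,
                     "concordant": concordant})
    table = pd.DataFrame(rows, columns=["gene", "direction", "label", "concordant"])
    if len(table):
        crosstab = pd.crosstab(table["direction"], table["label"])
    else:
        crosstab = pd.DataFrame()
    crosstab = crosstab.reindex(columns=list(LABELS), fill_value=0)
    return ConcordanceSummary(
        table=table,
        crosstab=crosstab,
        n_concordant=int(table["concordant"].sum()) if len(table) else 0,
        n_genes=len(table),
    )


def read_evidence_table(path) -> list[DirectionEvidence]:
    """Read a TSV with columns gene, n_up, n_down, n_tested."""
    df = pd.read_csv(path, sep="\t")
    return [
        DirectionEvidence(
            gene=str(r.gene).upper(),
            n_up=int(r.n_up),
            n_down=int(r.n_down),
            n_tested=int(r.n_tested),
        )
        for r in df.itertuples()
    ]
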