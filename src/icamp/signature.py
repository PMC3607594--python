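"""Inflammatory signature derivation.

Consistently dysregulated genes are intersected with immune/inflammation
gene sets and then filtered on effect size: a gene whose fold change is
below 2 in five or more of the cancer types is excluded.  Fold changes
are directional — FC > 1 always means "changed in the called direction" —
and are computed from class means of log2 expression (a geometric mean on
the linear scale) by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .datatypes import ExpressionStudy, GeneSet, PipelineConfig

log = logging.getLogger(__name__)


@dataclass
class SignatureGene:
    """A candidate signature gene with its per-study evidence."""

    gene: str
    direction: str  # "up" or "down"
    fc_per_study: dict[str, float | None] = field(default_factory=dict)
    n_studies_fc_below_cutoff: int = 0
    immune: bool = False
    retained: bool = False


def directional_fold_change(
    study: ExpressionStudy,
    gene: str,
    direction: str,
    method: str = "log-mean",
) -> float | None:
    """Linear-scale fold change of a gene in its called direction.

    With ``method="log-mean"`` (default) the class means are taken on the
    log2 scale, i.e. FC = 2^(mean_cancer - mean_normal) for "up" and its
    reciprocal for "down" — a geometric-mean ratio on the linear scale.
    ``method="linear-mean"`` averages 2^x within each class instead.
    Returns None (distinguished missing value) when the gene is not
    measured in the study.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    gene = gene.upper()
    if gene not in study.values.index:
        return None
    row = study.values.loc[gene]
    cancer = row[study.sample_ids("cancer")]
    normal = row[study.sample_ids("normal")]
    if method == "log-mean":
        delta = float(cancer.mean() - normal.mean())
        fc_up = 2.0 ** delta
    elif method == "linear-mean":
        fc_up = float((2.0 ** cancer).mean() / (2.0 ** normal).mean())
    else:
        raise ValueError(f"unknown fold-change method {method!r}")
    return fc_up if direction == "up" else 1.0 / fc_up


def apply_immune_filter(
    selected_genes: Iterable[str], gene_sets: Sequence[GeneSet]
) -> list[str]:
    """Keep only genes annotated in the union of the immune gene sets."""
    union: set[str] = set()
    for gs in gene_sets:
        union |= gs.members
    if not union:
        raise ValueError("empty immune gene-set union")
    kept, dropped = [], []
    for g in selected_genes:
        (kept if g.upper() in union else dropped).append(g.upper())
    if dropped:
        log.info("immune filter dropped %d of %d genes", len(dropped),
                 len(kept) + len(dropped))
    return kept


def apply_fc_exclusion(
    genes: list[SignatureGene], config: PipelineConfig | None = None
) -> list[SignatureGene]:
    """Apply the fold-change exclusion rule in place and return the input.

    A gene is excluded when its directional FC is below ``fc_cutoff``
    (default 2; FC exactly equal to the cutoff counts as NOT below) in
    ``fc_exclusion_min_studies`` (default 5) or more studies.  Studies
    where the gene is unmeasured (FC is None) count toward the
    below-cutoff tally — a conservative choice.  Non-immune genes are
    never retained.
    """
    config = config or PipelineConfig()
    for sg in genes:
        n_below = sum(
            1
            for fc in sg.fc_per_study.values()
            if fc is None or fc < config.fc_cutoff
        )
        sg.n_studies_fc_below_cutoff = n_below
        sg.retained = sg.immune and n_below < config.fc_exclusion_min_studies
    return genes


def build_signature(
    selected: dict[str, list[str]],
    studies: Sequence[ExpressionStudy],
    gene_sets: Sequence[GeneSet],
    config: PipelineConfig | None = None,
    fc_method: str = "log-mean",
) -> list[SignatureGene]:
    """Full signature derivation from per-direction selected gene lists.

    ``selected`` maps "up"/"down" to the consistency-selected genes.
    Returns one SignatureGene per candidate with immune flag, per-study
    fold changes and retained status; the signature is the retained
    subset.
    """
    config = config or PipelineConfig()
    immune_union = apply_immune_filter(
        [g for genes in selected.values() for g in genes], gene_sets
    )
    immune_set = set(immune_union)
    out: list[SignatureGene] = []
    for direction, genes in selected.items():
        for gene in genes:
            gene = gene.upper()
            fc = {
                s.study_id: directional_fold_change(s, gene, direction, fc_method)
                for s in studies
            }
            out.append(
                SignatureGene(
                    gene=gene,
                    direction=direction,
                    fc_per_study=fc,
                    immune=gene in immune_set,
                )
            )
    apply_fc_exclusion(out, config)
    n_ret = sum(sg.retained for sg in out)
    log.info("signature: %d of %d candidates retained", n_ret, len(out))
    return out


def geometric_mean_fc(sg: SignatureGene) -> float | None:
    """Geometric mean of a gene's measured per-study fold changes."""
    vals = [fc for fc in sg.fc_per_study.values() if fc is not None and fc > 0]
    if not vals:
        return None
    return math.exp(sum(math.log(v) for v in vals) / len(vals))
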