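"""Synthetic-data generators with known ground truth for every pipeline stage.

The multi-study generator emulates a panel of independent two-class
microarray studies sharing a gene universe: a minority of genes is
consistently up- or down-regulated across all studies with per-study log2
effects drawn from a common range, some genes are sporadically
dysregulated in a single study, and the rest are null.  Within-class
noise is Gaussian on the log2 scale with per-gene baselines around the
typical microarray intensity range.  Survival cohorts follow a
proportional-hazards model with exponential baseline and uniform
censoring calibrated to a target censoring rate.  Direction-evidence
tables emulate counts of external validation datasets calling each gene
up or down.

All generators are fully deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import ExpressionStudy, GeneSet, SurvivalCohort
from .concordance import DirectionEvidence

CATEGORIES = ("consistent_up", "consistent_down", "sporadic", "null")


@dataclass
class MultiStudyTruth:
    """Planted ground truth for a multi-study expression panel."""

    category: dict[str, str]                    # gene -> category
    effects: dict[str, dict[str, float]]        # study -> gene -> log2 effect
    immune: dict[str, bool]                     # gene -> immune membership

    def genes_in(self, category: str) -> list[str]:
        return [g for g, c in self.category.items() if c == category]

    def immune_gene_set(self, name: str = "SYNTH_IMMUNE") -> GeneSet:
        members = frozenset(g for g, f in self.immune.items() if f)
        return GeneSet(name=name, members=members)


@dataclass
class SurvivalTruth:
    """Generative parameters for a proportional-hazards survival cohort."""

    log_hazard_ratios: dict[str, float]   # gene -> beta (per-SD log HR)
    n_null_genes: int = 0
    baseline_hazard: float = 0.02         # events per month at x = 0
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")

    @property
    def gene_names(self) -> list[str]:
        nulls = [f"NULL{i:03d}" for i in range(self.n_null_genes)]
        return list(self.log_hazard_ratios) + nulls


def generate_multistudy(
    n_studies: int = 7,
    n_genes: int = 2000,
    n_consistent_up: int = 60,
    n_consistent_down: int = 60,
    n_sporadic: int = 100,
    effect_log2_range: tuple[float, float] = (1.0, 3.0),
    n_per_class: int = 20,
    noise_sd: float = 1.0,
    missing_fraction: float = 0.0,
    immune_fraction_consistent: float = 0.5,
    immune_fraction_background: float = 0.05,
    seed: int | None = None,
) -> tuple[list[ExpressionStudy], MultiStudyTruth]:
    """Generate a panel of two-class studies with planted consistent DE genes.

    Normal-class values are Gaussian(baseline_g, noise_sd) with per-gene
    baselines ~ N(7, 2); the cancer class adds the planted log2 effect.
    Consistent genes carry the same sign in every study with magnitude
    drawn per study from ``effect_log2_range``; sporadic genes are
    dysregulated in exactly one random study; ``missing_fraction`` of
    genes is dropped per study at random to exercise median imputation.
    """
    n_planted = n_consistent_up + n_consistent_down + n_sporadic
    if n_planted > n_genes:
        raise ValueError("planted gene counts exceed n_genes")
    if not (0.0 <= missing_fraction < 1.0):
        raise ValueError("missing_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)
    up = [genes[i] for i in order[:n_consistent_up]]
    down = [genes[i] for i in order[n_consistent_up:n_consistent_up + n_consistent_down]]
    spor = [genes[i] for i in order[n_consistent_up + n_consistent_down:n_planted]]
    category = {g: "null" for g in genes}
    category.update({g: "consistent_up" for g in up})
    category.update({g: "consistent_down" for g in down})
    category.update({g: "sporadic" for g in spor})

    immune = {}
    for g in genes:
        if category[g] in ("consistent_up", "consistent_down"):
            immune[g] = bool(rng.random() < immune_fraction_consistent)
        else:
            immune[g] = bool(rng.random() < immune_fraction_background)

    baselines = rng.normal(7.0, 2.0, size=n_genes)
    lo, hi = effect_log2_range
    sporadic_study = {g: int(rng.integers(n_studies)) for g in spor}
    sporadic_sign = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in spor}

    studies: list[ExpressionStudy] = []
    effects: dict[str, dict[str, float]] = {}
    for d in range(n_studies):
        sid = f"study{d + 1}"
        eff = np.zeros(n_genes)
        for gi, g in enumerate(genes):
            cat = category[g]
            if cat == "consistent_up":
                eff[gi] = rng.uniform(lo, hi)
            elif cat == "consistent_down":
                eff[gi] = -rng.uniform(lo, hi)
            elif cat == "sporadic" and sporadic_study[g] == d:
                eff[gi] = sporadic_sign[g] * rng.uniform(lo, hi)
        effects[sid] = {g: float(eff[gi]) for gi, g in enumerate(genes)
                        if eff[gi] != 0.0}
        n_samples = 2 * n_per_class
        values = rng.normal(
            baselines[:, None], noise_sd, size=(n_genes, n_samples)
        )
        values[:, :n_per_class] += eff[:, None]   # cancer columns first
        samples = [f"{sid}_C{i}" for i in range(n_per_class)] + [
            f"{sid}_N{i}" for i in range(n_per_class)
        ]
        class_of = {s: ("cancer" if s.split("_")[-1].startswith("C") else "normal")
                    for s in samples}
        df = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                          columns=samples)
        if missing_fraction > 0:
            keep = rng.random(n_genes) >= missing_fraction
            df = df.loc[keep]
        studies.append(ExpressionStudy(study_id=sid, values=df,
                                       class_of=class_of))
    truth = MultiStudyTruth(category=category, effects=effects, immune=immune)
    return studies, truth


def _solve_censoring_horizon(event_times: np.ndarray, target: float) -> float:
    """Horizon c of Uniform(0, c) censoring achieving the target rate.

    With C ~ U(0, c) independent of T, P(censored | T = t) = min(t/c, 1);
    the expected rate over the sample is monotone decreasing in c.
    """
    def rate(c: float) -> float:
        return float(np.minimum(event_times / c, 1.0).mean())

    lo = event_times.min() * 1e-3
    hi = event_times.max() * 1e4
    if rate(hi) > target:       # even huge horizons censor too much (can't happen
        return hi               # for positive times, guard anyway)
    return float(brentq(lambda c: rate(c) - target, lo, hi, xtol=1e-9))


def generate_survival_cohort(
    truth: SurvivalTruth,
    n_patients: int,
    seed: int | None = None,
    cohort_id: str = "cohort",
) -> SurvivalCohort:
    """Proportional-hazards cohort with standard-Gaussian gene expression.

    Event times are exponential with hazard
    baseline * exp(sum_g beta_g x_g); censoring is uniform on [0, c] with
    c solved so the realized censoring fraction matches the target on
    average (within a few percent).
    """
    rng = np.random.default_rng(seed)
    genes = truth.gene_names
    X = rng.standard_normal((n_patients, len(genes)))
    beta = np.array([truth.log_hazard_ratios.get(g, 0.0) for g in genes])
    hazard = truth.baseline_hazard * np.exp(X @ beta)
    t_event = rng.exponential(1.0 / hazard)
    if truth.censoring_rate > 0:
        c = _solve_censoring_horizon(t_event, truth.censoring_rate)
        t_cens = rng.uniform(0.0, c, size=n_patients)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n_patients, dtype=int)
    time = np.maximum(time, 1e-9)
    table = pd.DataFrame(X, columns=genes)
    table.insert(0, "event", event)
    table.insert(0, "time", time)
    return SurvivalCohort(cohort_id=cohort_id, table=table, gene_columns=genes)


def generate_scored_cohort(
    model,
    n_patients: int,
    log_hr_per_unit: float = 0.2,
    baseline_hazard: float = 0.02,
    censoring_rate: float = 0.3,
    seed: int | None = None,
    cohort_id: str = "validation",
) -> SurvivalCohort:
    """Validation cohort whose hazard depends on the model's own score.

    Gene expression is standard Gaussian (already on the model's z scale);
    each patient's integrated score is computed with the frozen model and
    the hazard is baseline * exp(log_hr_per_unit * score), so the true
    per-unit hazard ratio is exp(log_hr_per_unit).
    """
    rng = np.random.default_rng(seed)
    genes = [gr.gene for gr in model.gene_risks_]
    X = rng.standard_normal((n_patients, len(genes)))
    # undo the model's z-scaling so predict() sees the intended z values
    raw = np.empty_like(X)
    for j, g in enumerate(genes):
        mu, sd = model.scaling_[g]
        raw[:, j] = X[:, j] * sd + mu
    table = pd.DataFrame(raw, columns=genes)
    scores = model.predict(table)
    hazard = baseline_hazard * np.exp(log_hr_per_unit * scores)
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        c = _solve_censoring_horizon(t_event, censoring_rate)
        t_cens = rng.uniform(0.0, c, size=n_patients)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n_patients, dtype=int)
    table.insert(0, "event", event)
    table.insert(0, "time", np.maximum(time, 1e-9))
    return SurvivalCohort(cohort_id=cohort_id, table=table, gene_columns=genes)


def generate_direction_evidence(
    labels_truth: Mapping[str, str],
    n_datasets: int = 6,
    sensitivity: float = 0.8,
    false_call_rate: float = 0.05,
    seed: int | None = None,
) -> list[DirectionEvidence]:
    """Fabricate per-gene validation evidence counts with known truth.

    ``labels_truth`` maps gene -> {"up", "down", "null"}.  Each of
    ``n_datasets`` datasets independently calls the true direction with
    probability ``sensitivity`` and the wrong direction with probability
    ``false_call_rate``; null genes are called in either direction with
    probability ``false_call_rate`` each.
    """
    for name, v in (("sensitivity", sensitivity),
                    ("false_call_rate", false_call_rate)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for gene, direction in labels_truth.items():
        n_up = n_down = 0
        for _ in range(n_datasets):
            u = rng.random()
            if direction == "up":
                if u < sensitivity:
                    n_up += 1
                elif u < sensitivity + (1 - sensitivity) * false_call_rate:
                    n_down += 1
            elif direction == "down":
                if u < sensitivity:
                    n_down += 1
                elif u < sensitivity + (1 - sensitivity) * false_call_rate:
                    n_up += 1
            else:
                if u < false_call_rate:
                    n_up += 1
                elif u < 2 * false_call_rate:
                    n_down += 1
        out.append(DirectionEvidence(gene=gene.upper(), n_up=n_up,
                                     n_down=n_down, n_tested=n_datasets))
    return out
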