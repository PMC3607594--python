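"""Per-gene survival stratification and the integrated risk score (IGIS).

Each candidate gene is dichotomized at the expression cutpoint that
maximizes the log-rank statistic over a percentile-bounded scan (an
X-tile-style optimal cutpoint, reported with a Miller–Siegmund minimum-p
correction alongside the uncorrected p).  The hazard ratio of the
worse-surviving (risky) side versus the other, from a univariate Cox
proportional-hazards fit with Breslow tie handling, is the gene's
relative risk (RR).  Genes with uncorrected log-rank p < 0.05 enter the
model.

A patient's integrated score is the sum of the RRs of the model genes for
which the patient falls on the risky side of the training-derived cutoff;
genes on the safe side contribute zero.  Validation freezes the training
cutoffs and z-scaling and fits a Cox model with the score as a continuous
covariate (RR per unit of score); a median-split dichotomized variant is
reported as well.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import SurvivalCohort

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- KM / logrank

@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    timeline: np.ndarray   # event/censor times, ascending, starting at 0
    survival: np.ndarray   # S(t) at each timeline point; S(0) = 1

    def at(self, t: float) -> float:
        i = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[max(i, 0)])

    def to_frame(self) -> pd.DataFrame:
        """Step table with columns time, survival (for TSV export)."""
        return pd.DataFrame({"time": self.timeline, "survival": self.survival})


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier estimate with right censoring; S(0) = 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one subject")
    if (times <= 0).any():
        raise ValueError("times must be strictly positive")
    if events.sum() == 0:
        log.warning("all subjects censored; survival estimate is identically 1")
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KMCurve(
        timeline=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
    )


def _logrank_chi2(times, events, in_group_a) -> float:
    """One-degree-of-freedom log-rank chi-square, vectorized.

    Sums observed-minus-expected events in group A over the risk sets at
    each distinct event time, with the standard hypergeometric variance.
    Returns nan when the variance is zero (no events, or one group empty
    at every event time).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    a = np.asarray(in_group_a, dtype=bool)
    order = np.argsort(times, kind="stable")
    t, e, ga = times[order], events[order], a[order]
    n = len(t)
    # distinct event times and per-time event/at-risk counts
    uniq, first = np.unique(t, return_index=True)
    # at-risk counts just before each distinct time
    n_at_risk = n - first
    csum_a = np.concatenate([[0], np.cumsum(ga)])
    a_at_risk = csum_a[-1] - csum_a[first]
    d_total = np.add.reduceat(e, first)
    d_a = np.add.reduceat(e * ga, first)
    keep = d_total > 0
    N, Na, d, da = n_at_risk[keep], a_at_risk[keep], d_total[keep], d_a[keep]
    expected = d * Na / N
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (Na / N) * (1 - Na / N) * (N - d) / np.where(N > 1, N - 1, 1)
    v = np.nansum(var)
    if v <= 0:
        return float("nan")
    return float((np.sum(da - expected)) ** 2 / v)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi2, p).

    With zero events in the pooled sample the statistic is undefined and
    (nan, nan) is returned as a distinguished result.
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return float("nan"), float("nan")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    chi2 = _logrank_chi2(times, events, group)
    if np.isnan(chi2):
        return float("nan"), float("nan")
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------- Cox RR

def _cox_hr(times, events, covariate) -> tuple[float, float]:
    """Univariate Cox hazard ratio and Wald p (Breslow ties, lifelines)."""
    df = pd.DataFrame({"time": times, "event": events, "x": covariate})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    return float(np.exp(cph.params_["x"])), float(cph.summary.loc["x", "p"])


def relative_risk(times_risky, events_risky, times_ref, events_ref) -> float:
    """Hazard ratio of the risky group vs the reference group.

    Estimated by a univariate Cox proportional-hazards fit on a binary
    group indicator.  When one group has no events the estimate diverges
    and a signed infinity is returned as a distinguished value.
    """
    er, ef = np.asarray(events_risky, int), np.asarray(events_ref, int)
    if len(er) == 0 or len(ef) == 0:
        raise ValueError("both groups must be non-empty")
    if er.sum() + ef.sum() == 0:
        raise ValueError("no events in either group")
    if er.sum() == 0:
        return 0.0
    if ef.sum() == 0:
        return float("inf")
    times = np.concatenate([times_risky, times_ref])
    events = np.concatenate([er, ef])
    x = np.concatenate([np.ones(len(er)), np.zeros(len(ef))])
    try:
        hr, _ = _cox_hr(times, events, x)
    except ConvergenceError:
        return float("inf")
    return hr


# ---------------------------------------------------------------- cutpoint

def miller_siegmund_minp(p_min: float, lo: float, hi: float) -> float:
    """Correct a minimum p-value from a cutpoint scan over [lo, hi] quantiles.

    Approximates the p-value of the maximally selected log-rank statistic
    (improved Bonferroni of Miller & Siegmund); clipped to [p_min, 1].
    """
    if p_min <= 0:
        return 0.0
    if p_min >= 1:
        return 1.0
    z = stats.norm.isf(p_min / 2.0)
    if z <= 1.0:  # approximation invalid for tiny statistics; p is ~1 anyway
        return 1.0
    phi = stats.norm.pdf(z)
    ratio = (hi * (1 - lo)) / (lo * (1 - hi))
    p = phi * (z - 1.0 / z) * np.log(ratio) + 4.0 * phi / z
    return float(min(1.0, max(p_min, p)))


@dataclass
class CutpointResult:
    cutoff: float | None
    risky_side: str | None      # "high" or "low"
    rr: float | None
    p_uncorrected: float | None
    p_corrected: float | None
    chi2: float | None
    n_low: int = 0
    n_high: int = 0

    @property
    def valid(self) -> bool:
        return self.cutoff is not None


def optimal_cutpoint(
    expr,
    times,
    events,
    percentile_range: tuple[float, float] = (0.15, 0.85),
    min_group: int = 5,
) -> CutpointResult:
    """X-tile-style optimal expression cutpoint for survival stratification.

    Scans every observed expression value whose quantile lies within
    ``percentile_range`` as a candidate split (low group: expr <= value),
    keeps the split maximizing the log-rank chi-square, and reports the
    uncorrected p next to the Miller–Siegmund corrected one.  The risky
    side is the side with worse survival, and rr is its Cox hazard ratio
    vs the other side (oriented > 1).  The scan depends on expression
    only through ranks, so strictly monotone transforms leave the chosen
    patient partition unchanged.  Returns an invalid (all-None) result
    when no candidate leaves at least ``min_group`` patients on each side.
    """
    expr = np.asarray(expr, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(expr)
    if n < 20:
        raise ValueError("need at least 20 patients for a cutpoint scan")
    lo, hi = percentile_range
    qlow, qhigh = np.quantile(expr, [lo, hi])
    candidates = np.unique(expr[(expr >= qlow) & (expr <= qhigh)])
    candidates = candidates[candidates < expr.max()]  # split must be two-sided
    best_chi2, best_cut = -np.inf, None
    for c in candidates:
        low = expr <= c
        n_low = int(low.sum())
        if n_low < min_group or n - n_low < min_group:
            continue
        chi2 = _logrank_chi2(times, events, low)
        if not np.isnan(chi2) and chi2 > best_chi2:
            best_chi2, best_cut = chi2, c
    if best_cut is None:
        return CutpointResult(None, None, None, None, None, None)
    low = expr <= best_cut
    p_unc = float(stats.chi2.sf(best_chi2, df=1))
    p_cor = miller_siegmund_minp(p_unc, lo, hi)
    rr_high = relative_risk(times[~low], events[~low], times[low], events[low])
    if rr_high >= 1.0:
        risky_side, rr = "high", rr_high
    else:
        risky_side, rr = "low", float("inf") if rr_high == 0.0 else 1.0 / rr_high
    return CutpointResult(
        cutoff=float(best_cut),
        risky_side=risky_side,
        rr=float(rr),
        p_uncorrected=p_unc,
        p_corrected=p_cor,
        chi2=float(best_chi2),
        n_low=int(low.sum()),
        n_high=int((~low).sum()),
    )


# ---------------------------------------------------------------- IGIS model

@dataclass
class GeneRisk:
    """Per-gene stratification result on the training cohort."""

    gene: str
    cutoff: float              # on z-scaled expression
    risky_side: str            # "high" | "low"
    rr: float
    p: float                   # uncorrected log-rank p
    p_corrected: float
    selected: bool


@dataclass
class IgisResult:
    """Validation statistics for the integrated score on a cohort."""

    scores: np.ndarray
    rr_per_unit: float | None
    p: float | None
    rr_group: float | None = None     # median-split dichotomized variant
    p_group: float | None = None
    degenerate: bool = False


class IgisModel(BaseEstimator):
    """Integrated prognostic gene score: train cutpoints, freeze, validate.

    ``fit`` z-scales each candidate gene on the training cohort, finds its
    optimal survival cutpoint, orients the Cox relative risk so rr > 1
    for the risky side, and keeps genes with uncorrected log-rank
    p < ``p_threshold``.  ``predict`` scores patients as the sum of the
    rr values of the model genes on whose risky side they fall, using the
    frozen training z-scaling and cutoffs.

    Parameters
    ----------
    genes : sequence of str or None
        Candidate genes; None means every gene column of the training
        cohort.
    p_threshold : float
        Per-gene selection threshold on the log-rank p.
    use_corrected : bool
        Select genes on the Miller–Siegmund corrected minimum p instead of
        the uncorrected one.  The default (False) mirrors per-gene
        optimal-cutpoint screening as prognostic tools usually report it;
        the uncorrected minimum p is anti-conservative under the null, so
        calibration studies should set this to True.
    percentile_range : (float, float)
        Quantile bounds of the cutpoint scan.
    min_group : int
        Minimum patients on each side of a candidate cutpoint.
    """

    def __init__(
        self,
        genes: Sequence[str] | None = None,
        p_threshold: float = 0.05,
        percentile_range: tuple[float, float] = (0.15, 0.85),
        min_group: int = 5,
        use_corrected: bool = False,
        random_state: int | None = None,
    ):
        self.genes = genes
        self.p_threshold = p_threshold
        self.percentile_range = percentile_range
        self.min_group = min_group
        self.use_corrected = use_corrected
        self.random_state = random_state

    # -- fitting -------------------------------------------------------
    def fit(self, cohort: SurvivalCohort, y=None) -> "IgisModel":
        genes = list(self.genes) if self.genes is not None else cohort.gene_columns
        absent = [g for g in genes if g not in cohort.table.columns]
        if absent:
            raise ValueError(f"genes absent from training cohort: {absent}")
        times, events = cohort.times, cohort.events
        self.scaling_ = {}
        self.gene_risks_ = []
        self.all_gene_results_ = []
        for gene in genes:
            x = cohort.expression(gene)
            mu, sd = float(x.mean()), float(x.std(ddof=0))
            if sd == 0:
                log.warning("gene %s constant in training cohort; skipped", gene)
                continue
            z = (x - mu) / sd
            cp = optimal_cutpoint(
                z, times, events,
                percentile_range=self.percentile_range,
                min_group=self.min_group,
            )
            if not cp.valid or not np.isfinite(cp.rr):
                continue
            p_screen = cp.p_corrected if self.use_corrected else cp.p_uncorrected
            selected = p_screen < self.p_threshold
            gr = GeneRisk(
                gene=gene, cutoff=cp.cutoff, risky_side=cp.risky_side,
                rr=cp.rr, p=cp.p_uncorrected, p_corrected=cp.p_corrected,
                selected=selected,
            )
            self.all_gene_results_.append(gr)
            if selected:
                self.scaling_[gene] = (mu, sd)
                self.gene_risks_.append(gr)
        if not self.gene_risks_:
            log.warning("no gene passed per-gene screening; model is empty")
        return self

    # -- scoring -------------------------------------------------------
    def _risky(self, gr: GeneRisk, z: np.ndarray) -> np.ndarray:
        return z > gr.cutoff if gr.risky_side == "high" else z <= gr.cutoff

    def predict(self, cohort) -> np.ndarray:
        """Integrated score per patient (sum of rr over risky genes)."""
        table = cohort.table if isinstance(cohort, SurvivalCohort) else cohort
        scores = np.zeros(len(table), dtype=float)
        for gr in self.gene_risks_:
            if gr.gene not in table.columns:
                log.warning("gene %s missing from cohort; contributes 0", gr.gene)
                continue
            mu, sd = self.scaling_[gr.gene]
            z = (table[gr.gene].to_numpy(dtype=float) - mu) / sd
            scores += np.where(self._risky(gr, z), gr.rr, 0.0)
        return scores

    def score_patient(self, patient_expr: Mapping[str, float]) -> float:
        """Integrated score for a single patient's expression mapping."""
        total = 0.0
        for gr in self.gene_risks_:
            if gr.gene not in patient_expr:
                log.warning("gene %s missing from patient; contributes 0", gr.gene)
                continue
            mu, sd = self.scaling_[gr.gene]
            z = (float(patient_expr[gr.gene]) - mu) / sd
            if bool(self._risky(gr, np.asarray([z]))[0]):
                total += gr.rr
        return total

    # -- validation ----------------------------------------------------
    def validate(self, cohort: SurvivalCohort) -> IgisResult:
        """Frozen-cutoff validation on an independent cohort.

        Fits a Cox model with the integrated score as a continuous
        covariate (rr per unit of score) and also reports a median-split
        dichotomized hazard ratio.  A constant score is a distinguished
        degenerate no-result.
        """
        scores = self.predict(cohort)
        if np.ptp(scores) == 0:
            log.warning("integrated score constant on validation cohort")
            return IgisResult(scores=scores, rr_per_unit=None, p=None,
                              degenerate=True)
        rr_unit, p = _cox_hr(cohort.times, cohort.events, scores)
        med = np.median(scores)
        high = scores > med
        rr_group = p_group = None
        if 0 < high.sum() < len(scores):
            rr_raw = relative_risk(
                cohort.times[high], cohort.events[high],
                cohort.times[~high], cohort.events[~high],
            )
            if np.isfinite(rr_raw) and rr_raw > 0:
                rr_group = rr_raw
                _, p_group = logrank_test(
                    cohort.times[high], cohort.events[high],
                    cohort.times[~high], cohort.events[~high],
                )
        return IgisResult(scores=scores, rr_per_unit=rr_unit, p=p,
                          rr_group=rr_group, p_group=p_group)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "genes": [asdict(gr) for gr in self.gene_risks_],
            "scaling": {g: {"mean": m, "sd": s}
                        for g, (m, s) in self.scaling_.items()},
            "p_threshold": self.p_threshold,
            "percentile_range": list(self.percentile_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IgisModel":
        model = cls(
            p_threshold=d.get("p_threshold", 0.05),
            percentile_range=tuple(d.get("percentile_range", (0.15, 0.85))),
        )
        model.gene_risks_ = [GeneRisk(**g) for g in d["genes"]]
        model.scaling_ = {g: (v["mean"], v["sd"])
                          for g, v in d["scaling"].items()}
        model.all_gene_results_ = list(model.gene_risks_)
        return model


# Thin functional wrappers over the estimator -----------------------------

def build_risk_model(
    cohort: SurvivalCohort,
    genes: Sequence[str] | None = None,
    p_threshold: float = 0.05,
    percentile_range: tuple[float, float] = (0.15, 0.85),
    seed: int | None = None,
) -> IgisModel:
    return IgisModel(
        genes=genes, p_threshold=p_threshold,
        percentile_range=percentile_range, random_state=seed,
    ).fit(cohort)


def igis_score(patient_expr: Mapping[str, float], model: IgisModel) -> float:
    return model.score_patient(patient_expr)


def validate_igis(cohort: SurvivalCohort, model: IgisModel) -> IgisResult:
    return model.validate(cohort)
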