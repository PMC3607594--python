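"""Consistency meta-analysis across studies (CDEP).

Per-study FDR values are modeled as a beta-uniform mixture — a uniform
component for non-dysregulated genes plus a decreasing Beta(a, 1)
component (a in (0, 1)) for dysregulated ones.  At an FDR threshold l the
false-positive rate of a study, rho_d(l) = P(f <= l | gene non-DE), is
the null-component CDF, i.e. l itself.  Treating the per-study calls
I(f_{g,d} <= l) of a truly non-dysregulated gene as independent
Bernoulli(rho_d) draws gives a joint "false-call" log-likelihood per
gene; genes whose pattern is too unlikely under that null — called in
enough studies — are selected as consistently differentially expressed.
The selection is calibrated by within-study permutations of the FDR
columns, which estimate FDR_g, the proportion of false positives among
the selected genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import DEFAULT_FDR_GRID, PipelineConfig
from .rankprod import FdrTable

log = logging.getLogger(__name__)

_EPS = 1e-6


@dataclass
class MixtureFit:
    """Fitted beta-uniform mixture for one study's FDR values."""

    study_id: str
    pi_null: float
    alt_shape: float
    loglik: float
    n_em_iterations: int

    @property
    def pi_de(self) -> float:
        return 1.0 - self.pi_null


def _bum_loglik(x: np.ndarray, pi_null: float, a: float) -> float:
    return float(np.log(pi_null + (1.0 - pi_null) * a * x ** (a - 1.0)).sum())


class BetaUniformMixture(BaseEstimator):
    """EM fit of f(x) = pi_null * 1 + (1 - pi_null) * a * x^(a-1).

    The uniform component models null genes; the Beta(a, 1) component with
    a in (0, 1) is decreasing, putting its mass near 0 where dysregulated
    genes' FDR values concentrate.  Multiple restarts are run and the best
    log-likelihood kept.

    Attributes (after fit): ``pi_null_``, ``pi_de_``, ``alpha_``,
    ``loglik_``, ``n_iter_``.
    """

    def __init__(
        self,
        max_iter: int = 1000,
        tol: float = 1e-9,
        n_restarts: int = 5,
        random_state: int | None = None,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None) -> "BetaUniformMixture":
        x = np.asarray(X, dtype=float).ravel()
        if not np.isfinite(x).all():
            raise ValueError("non-finite values in mixture input")
        if x.min() < 0.0 or x.max() > 1.0:
            raise ValueError("mixture input must lie in [0, 1]")
        if np.ptp(x) == 0.0:
            raise ValueError("degenerate input: all values identical")
        x = np.clip(x, _EPS, 1.0 - _EPS)
        logx = np.log(x)
        rng = np.random.default_rng(self.random_state)
        best = None
        for r in range(self.n_restarts):
            if r == 0:
                pi0, a = 0.7, 0.3
            else:
                pi0 = rng.uniform(0.05, 0.95)
                a = rng.uniform(0.05, 0.95)
            prev_ll = -np.inf
            n_iter = 0
            for n_iter in range(1, self.max_iter + 1):
                alt = a * x ** (a - 1.0)
                denom = pi0 + (1.0 - pi0) * alt
                resp_null = pi0 / denom
                pi0 = float(np.clip(resp_null.mean(), _EPS, 1.0 - _EPS))
                w = 1.0 - resp_null
                sw = w.sum()
                if sw <= 0:
                    break
                a = float(np.clip(-sw / (w * logx).sum(), _EPS, 1.0 - _EPS))
                ll = _bum_loglik(x, pi0, a)
                if abs(ll - prev_ll) < self.tol * max(1.0, abs(ll)):
                    prev_ll = ll
                    break
                prev_ll = ll
            cand = (prev_ll, pi0, a, n_iter)
            if best is None or cand[0] > best[0]:
                best = cand
        self.loglik_, self.pi_null_, self.alpha_, self.n_iter_ = best
        # Identifiability guard: as a -> 1 the alternative tends to the
        # uniform and (pi_null, a) is a likelihood ridge.  The pure-uniform
        # model has log-likelihood exactly 0; if the fitted mixture does not
        # beat it by a meaningful likelihood ratio the data are
        # indistinguishable from uniform and the non-DE fraction is reported
        # as ~1 rather than an arbitrary ridge point.
        if 2.0 * self.loglik_ < 9.21:  # chi2(2) 0.99 quantile
            self.pi_null_ = 1.0 - 1.0 / len(x)
            self.alpha_ = 0.5
            self.loglik_ = 0.0
        self.pi_de_ = 1.0 - self.pi_null_
        return self


def fit_beta_mixture(
    fdr_values,
    max_iter: int = 1000,
    tol: float = 1e-9,
    n_restarts: int = 5,
    seed: int | None = None,
    study_id: str = "",
) -> MixtureFit:
    """Fit the beta-uniform mixture to one study's FDR values."""
    est = BetaUniformMixture(
        max_iter=max_iter, tol=tol, n_restarts=n_restarts, random_state=seed
    ).fit(fdr_values)
    return MixtureFit(
        study_id=study_id,
        pi_null=est.pi_null_,
        alt_shape=est.alpha_,
        loglik=est.loglik_,
        n_em_iterations=est.n_iter_,
    )


def false_positive_rate(fit: MixtureFit | None, l: float) -> float:
    """rho_d(l): probability a non-dysregulated gene has FDR <= l.

    The null component of the mixture is uniform on (0, 1), so its CDF at
    l is l itself regardless of the fitted parameters; ``fit`` is accepted
    for interface symmetry.
    """
    if not (0.0 < l < 1.0):
        raise ValueError(f"threshold l must lie in (0, 1), got {l}")
    return float(l)


def consistency_loglik(call_pattern, rhos) -> float:
    """Joint log-likelihood of a call pattern for a truly non-DE gene.

    ll = sum_d [called_d * log rho_d + (1 - called_d) * log(1 - rho_d)]
    under independent per-study Bernoulli(rho_d) false calls.
    """
    calls = np.asarray(call_pattern, dtype=float)
    rho = np.asarray(rhos, dtype=float)
    if calls.shape != rho.shape:
        raise ValueError("call_pattern and rhos must have equal length")
    if ((rho <= 0.0) | (rho >= 1.0)).any():
        raise ValueError("all rho values must lie strictly in (0, 1)")
    return float((calls * np.log(rho) + (1.0 - calls) * np.log1p(-rho)).sum())


@dataclass
class CdepSelection:
    """Result of consistency selection in one direction."""

    direction: str
    l: float | None
    min_called_used: int | None
    score_cutoff: float | None
    selected_genes: list[str]
    fdr_g: float | None
    observed_count: int
    null_counts: list[float] = field(default_factory=list)
    mixture_fits: dict[str, MixtureFit] = field(default_factory=dict)
    gene_table: pd.DataFrame | None = None  # gene, n_called, ll_false, selected


class ConsistentDESelector(BaseEstimator):
    """Select genes consistently called across studies at calibrated FDR_g.

    ``fit`` scans a grid of per-study FDR thresholds l crossed with score
    cutoffs (equivalently, minimum called-study counts k >= ``min_called``).
    At each (l, k) the observed selection is all genes whose false-call
    log-likelihood is at or below the cutoff (i.e. called in >= k
    studies); FDR_g is estimated from ``n_permutations`` within-study
    shuffles of the FDR columns as mean(null selected count) / observed
    count.  The (l, k) pair maximizing the selected-set size subject to
    FDR_g <= ``fdrg_target`` wins; ties prefer smaller FDR_g, then
    stricter l.

    Parameters mirror PipelineConfig; ``min_called=None`` means "called in
    every study" (strict consistency).
    """

    def __init__(
        self,
        threshold_grid=DEFAULT_FDR_GRID,
        min_called: int | None = None,
        fdrg_target: float = 0.05,
        n_permutations: int = 20,
        random_state: int | None = None,
    ):
        self.threshold_grid = threshold_grid
        self.min_called = min_called
        self.fdrg_target = fdrg_target
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, fdr_frame: pd.DataFrame, direction: str = "up",
            fit_mixtures: bool = True,
            measured_mask: pd.DataFrame | None = None) -> "ConsistentDESelector":
        F = fdr_frame.to_numpy(dtype=float)
        genes = list(fdr_frame.index)
        studies = list(fdr_frame.columns)
        n_genes, n_studies = F.shape
        min_called = self.min_called if self.min_called is not None else n_studies
        if not (1 <= min_called <= n_studies):
            raise ValueError(f"min_called must be in [1, {n_studies}]")
        grid = [float(l) for l in self.threshold_grid]

        mixtures: dict[str, MixtureFit] = {}
        if fit_mixtures:
            for j, sid in enumerate(studies):
                col = F[:, j]
                if measured_mask is not None:
                    col = col[~measured_mask[sid].to_numpy()]
                try:
                    mixtures[sid] = fit_beta_mixture(
                        col, seed=None if self.random_state is None
                        else self.random_state + j, study_id=sid)
                except ValueError as exc:  # degenerate column: report, don't abort
                    log.warning("mixture fit failed for study %s: %s", sid, exc)

        # permutation streams per study derived from master seed + study index
        # so adding a study leaves the others' streams unchanged
        master = self.random_state if self.random_state is not None else 0
        perms = np.empty((self.n_permutations, n_genes, n_studies), dtype=np.int32)
        for j in range(n_studies):
            rng = np.random.default_rng(master + 1000 * (j + 1))
            for b in range(self.n_permutations):
                perms[b, :, j] = rng.permutation(n_genes)

        best = None  # (count, -fdr_g, -l, record)
        for l in grid:
            rho = np.full(n_studies, false_positive_rate(None, l))
            calls = F <= l
            n_called = calls.sum(axis=1)
            ll_false = n_called * np.log(l) + (n_studies - n_called) * np.log1p(-l)
            null_called = np.empty((self.n_permutations, n_genes), dtype=np.int16)
            for b in range(self.n_permutations):
                shuffled = np.take_along_axis(calls, perms[b], axis=0)
                null_called[b] = shuffled.sum(axis=1)
            for k in range(min_called, n_studies + 1):
                cutoff = k * np.log(l) + (n_studies - k) * np.log1p(-l)
                selected = ll_false <= cutoff + 1e-12
                obs = int(selected.sum())
                if obs == 0:
                    continue
                nulls = (null_called >= k).sum(axis=1).astype(float)
                fdr_g = min(1.0, float(nulls.mean()) / obs)
                if fdr_g > self.fdrg_target:
                    continue
                key = (obs, -fdr_g, -l)
                if best is None or key > best[0]:
                    best = (key, {
                        "l": l, "k": k, "cutoff": float(cutoff),
                        "selected": selected, "fdr_g": fdr_g, "obs": obs,
                        "nulls": nulls.tolist(),
                        "ll_false": ll_false, "n_called": n_called,
                    })

        if best is None:
            log.warning(
                "no (l, cutoff) pair met FDR_g <= %.3g for direction %s; "
                "returning empty selection", self.fdrg_target, direction)
            # audit table at the loosest grid threshold, nothing selected
            l = grid[-1]
            calls = F <= l
            n_called = calls.sum(axis=1)
            ll_false = n_called * np.log(l) + (n_studies - n_called) * np.log1p(-l)
            table = pd.DataFrame(
                {"n_called": n_called, "ll_false": ll_false,
                 "selected": np.zeros(n_genes, dtype=bool)},
                index=pd.Index(genes, name="gene"),
            )
            self.selection_ = CdepSelection(
                direction=direction, l=None, min_called_used=None,
                score_cutoff=None, selected_genes=[], fdr_g=None,
                observed_count=0, mixture_fits=mixtures, gene_table=table)
            self.selected_genes_ = []
            return self

        rec = best[1]
        sel_genes = [g for g, s in zip(genes, rec["selected"]) if s]
        table = pd.DataFrame(
            {
                "n_called": rec["n_called"],
                "ll_false": rec["ll_false"],
                "selected": rec["selected"],
            },
            index=pd.Index(genes, name="gene"),
        )
        self.selection_ = CdepSelection(
            direction=direction,
            l=rec["l"],
            min_called_used=rec["k"],
            score_cutoff=rec["cutoff"],
            selected_genes=sel_genes,
            fdr_g=rec["fdr_g"],
            observed_count=rec["obs"],
            null_counts=rec["nulls"],
            mixture_fits=mixtures,
            gene_table=table,
        )
        self.selected_genes_ = sel_genes
        return self


def select_consistent_genes(
    fdr_table: FdrTable,
    direction: str,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> CdepSelection:
    """Run the consistency selection on one direction of an FdrTable."""
    config = config or PipelineConfig()
    sel = ConsistentDESelector(
        threshold_grid=config.fdr_threshold_grid,
        min_called=config.min_called,
        fdrg_target=config.fdrg_target,
        n_permutations=config.n_fdrg_permutations,
        random_state=config.seed if seed is None else seed,
    )
    sel.fit(fdr_table.frame(direction), direction=direction,
            measured_mask=fdr_table.imputed)
    return sel.selection_
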