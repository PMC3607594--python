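"""Two-class rank-product differential expression with permutation FDR.

For each study, every cancer sample is paired with every normal sample and
a per-pair log2 fold change is computed.  Genes are ranked within each
pair (rank 1 = most up-regulated for the "up" direction, most
down-regulated for "down") and the rank product is the geometric mean of
a gene's ranks across pairs.  Sample-label permutations give a null
distribution from which a percentage-of-false-prediction (pfp) value is
estimated per gene and direction; the pfp is used downstream as the
per-study "raw FDR".

Genes absent from a study's platform are assigned that study's median FDR
when the per-study results are assembled into a cross-study table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .datatypes import ExpressionStudy

log = logging.getLogger(__name__)

MIN_PERMUTATIONS = 10


def _cross_pairs(n_cancer: int, n_normal: int, n_pairs: int, rng: np.random.Generator):
    """Indices of cancer x normal sample pairs, capped at ``n_pairs``."""
    total = n_cancer * n_normal
    if total <= n_pairs:
        idx = np.arange(total)
    else:
        idx = rng.choice(total, size=n_pairs, replace=False)
    return idx // n_normal, idx % n_normal


def _rank_products(fc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-mean ranks of a genes x pairs fold-change matrix.

    Up-direction ranks are descending (largest fold change = rank 1),
    down-direction ascending; ties get average ranks.
    """
    n_genes = fc.shape[0]
    ranks_down = rankdata(fc, axis=0)
    # average ranks of -x are exactly n + 1 - average ranks of x
    ranks_up = n_genes + 1.0 - ranks_down
    rp_up = np.exp(np.log(ranks_up).mean(axis=1))
    rp_down = np.exp(np.log(ranks_down).mean(axis=1))
    return rp_up, rp_down


def rank_product(
    study: ExpressionStudy, n_pairs: int = 100, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene rank-product statistics (rp_up, rp_down) for one study.

    Uses all cancer-vs-normal cross pairs when their count is at most
    ``n_pairs``, otherwise ``n_pairs`` random pairs drawn with ``seed``.
    """
    rng = np.random.default_rng(seed)
    cancer = study.class_matrix("cancer")
    normal = study.class_matrix("normal")
    ci, ni = _cross_pairs(cancer.shape[1], normal.shape[1], n_pairs, rng)
    fc = cancer[:, ci] - normal[:, ni]
    return _rank_products(fc)


def estimate_pfp(
    study: ExpressionStudy,
    rp_up_obs: np.ndarray,
    rp_down_obs: np.ndarray,
    n_permutations: int = 100,
    n_pairs: int = 100,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation pfp ("raw FDR") per gene for both directions.

    For each of ``n_permutations`` label permutations the rank products
    are recomputed; pfp(g) = [mean permutation count of null statistics
    <= rp_obs(g)] / rank of rp_obs(g).  Each permutation contributes both
    its up and down rank products to a single shared null pool (a random
    cancer-label subset and its complement are equally likely, so the two
    directions share one null law); this also makes the estimate exactly
    antisymmetric under a class-label swap.  Values are made monotone in
    the observed statistic (a gene with smaller rp never gets a larger
    FDR) and clipped to [0, 1].
    """
    if n_permutations < MIN_PERMUTATIONS:
        raise ValueError(
            f"n_permutations={n_permutations} too small; need >= {MIN_PERMUTATIONS}"
        )
    rng = np.random.default_rng(seed)
    # canonical column order (sorted sample id) so the permutation null does
    # not depend on how the matrix happens to be ordered, and a pure label
    # swap leaves the null pool bit-identical
    canon = sorted(study.samples)
    values = study.values[canon].to_numpy()
    n_cancer = len(study.sample_ids("cancer"))
    n_samples = values.shape[1]
    null_pool: list[np.ndarray] = []
    for _ in range(n_permutations):
        perm = rng.permutation(n_samples)
        cancer = values[:, perm[:n_cancer]]
        normal = values[:, perm[n_cancer:]]
        ci, ni = _cross_pairs(cancer.shape[1], normal.shape[1], n_pairs, rng)
        fc = cancer[:, ci] - normal[:, ni]
        rp_u, rp_d = _rank_products(fc)
        null_pool.append(rp_u)
        null_pool.append(rp_d)
    # compare in log space with an ulp-scale slack so exact rank ties are
    # counted identically regardless of floating summation order
    null = np.sort(np.log(np.concatenate(null_pool)))
    # each permutation contributes two null vectors to the shared pool
    n_eff = 2 * n_permutations

    def _pfp(rp_obs: np.ndarray) -> np.ndarray:
        counts = np.searchsorted(null, np.log(rp_obs) + 1e-9,
                                 side="right") / n_eff
        obs_rank = rankdata(rp_obs, method="average")
        pfp = counts / obs_rank
        # enforce monotonicity in the statistic (q-value style step-up)
        order = np.argsort(rp_obs, kind="stable")
        stepped = np.minimum.accumulate(pfp[order][::-1])[::-1]
        out = np.empty_like(pfp)
        out[order] = stepped
        return np.clip(out, 0.0, 1.0)

    return _pfp(rp_up_obs), _pfp(rp_down_obs)


def log2_fold_changes(study: ExpressionStudy) -> np.ndarray:
    """Per-gene mean(cancer) - mean(normal) on the log2 scale."""
    return study.class_matrix("cancer").mean(axis=1) - study.class_matrix(
        "normal"
    ).mean(axis=1)


@dataclass
class DEResult:
    """Per-study differential-expression statistics, one row per gene."""

    study_id: str
    table: pd.DataFrame  # index gene; columns rp_up, fdr_up, rp_down, fdr_down, log2fc

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


class RankProductDE(BaseEstimator):
    """Rank-product differential expression for one two-class study.

    Parameters
    ----------
    n_pairs : int
        Cap on the number of cancer x normal sample pairs used per
        comparison matrix.
    n_permutations : int
        Label permutations for the pfp estimate (>= 10).
    random_state : int or None
        Seed for pair subsampling and permutations.

    Attributes (after fit)
    ----------------------
    rp_up_, rp_down_ : ndarray
        Rank-product statistics per gene.
    fdr_up_, fdr_down_ : ndarray
        Permutation pfp per gene, clipped to [0, 1].
    log2fc_ : ndarray
        mean(cancer) - mean(normal) per gene, log2 units.
    result_ : DEResult
    """

    def __init__(
        self,
        n_pairs: int = 100,
        n_permutations: int = 100,
        random_state: int | None = None,
    ):
        self.n_pairs = n_pairs
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, study: ExpressionStudy) -> "RankProductDE":
        self.rp_up_, self.rp_down_ = rank_product(
            study, n_pairs=self.n_pairs, seed=self.random_state
        )
        self.fdr_up_, self.fdr_down_ = estimate_pfp(
            study,
            self.rp_up_,
            self.rp_down_,
            n_permutations=self.n_permutations,
            n_pairs=self.n_pairs,
            seed=self.random_state,
        )
        self.log2fc_ = log2_fold_changes(study)
        self.result_ = DEResult(
            study_id=study.study_id,
            table=pd.DataFrame(
                {
                    "rp_up": self.rp_up_,
                    "fdr_up": self.fdr_up_,
                    "rp_down": self.rp_down_,
                    "fdr_down": self.fdr_down_,
                    "log2fc": self.log2fc_,
                },
                index=pd.Index(study.genes, name="gene"),
            ),
        )
        return self


def run_de(
    study: ExpressionStudy,
    n_pairs: int = 100,
    n_permutations: int = 100,
    seed: int | None = None,
) -> DEResult:
    """Convenience wrapper: full per-study DE analysis as a DEResult."""
    est = RankProductDE(
        n_pairs=n_pairs, n_permutations=n_permutations, random_state=seed
    )
    return est.fit(study).result_


@dataclass
class FdrTable:
    """Per-gene, per-study raw FDR values over the union gene universe.

    ``fdr_up``/``fdr_down`` are genes x studies frames with every cell
    filled; ``imputed`` marks cells where a gene was absent from the study
    platform and the study's median FDR (per direction) was assigned.
    """

    fdr_up: pd.DataFrame
    fdr_down: pd.DataFrame
    imputed: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.fdr_up.index)

    @property
    def studies(self) -> list[str]:
        return list(self.fdr_up.columns)

    def frame(self, direction: str) -> pd.DataFrame:
        if direction == "up":
            return self.fdr_up
        if direction == "down":
            return self.fdr_down
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def assemble_fdr_table(
    de_results: list[DEResult], universe: list[str] | None = None
) -> FdrTable:
    """Combine per-study DE results over the union gene universe.

    Missing (gene, study) cells are filled with that study's median FDR,
    computed per direction over its measured genes; the imputation mask
    is preserved for audit.
    """
    if len(de_results) < 2:
        raise ValueError("need at least 2 studies to assemble a cross-study table")
    if universe is None:
        universe = sorted(set().union(*(r.genes for r in de_results)))
    if not universe:
        raise ValueError("empty gene universe")
    idx = pd.Index(universe, name="gene")
    cols = [r.study_id for r in de_results]
    up = pd.DataFrame(index=idx, columns=cols, dtype=float)
    down = pd.DataFrame(index=idx, columns=cols, dtype=float)
    mask = pd.DataFrame(True, index=idx, columns=cols)
    for r in de_results:
        common = idx.intersection(r.table.index)
        up.loc[common, r.study_id] = r.table.loc[common, "fdr_up"]
        down.loc[common, r.study_id] = r.table.loc[common, "fdr_down"]
        mask.loc[common, r.study_id] = False
        up[r.study_id] = up[r.study_id].fillna(r.table["fdr_up"].median())
        down[r.study_id] = down[r.study_id].fillna(r.table["fdr_down"].median())
    n_imp = int(mask.to_numpy().sum())
    if n_imp:
        log.info("FDR table: imputed %d of %d cells with study medians",
                 n_imp, mask.size)
    return FdrTable(fdr_up=up, fdr_down=down, imputed=mask)
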