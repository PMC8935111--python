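"""Selection of the number of common modules K and the penalty strength.

K is chosen by clustering stability under repeated random initialization:
for each candidate, B fits are clustered, a consensus matrix records how
often cell pairs co-cluster, and the stability score is the cophenetic
correlation between the consensus dissimilarity and an average-linkage
dendrogram built on it. Among the three most stable candidates, the
middle K is selected (a guard against picking an extreme of the
candidate grid).

The penalty strength (lambda1 = lambda2) is then chosen to maximize a
*specificity score*: for each condition-specific module, the average
expression of its top genes should be high in samples of its own
condition and low elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from . import factorization
from .clustering import cluster_cells
from .study import ProcessedStudy, StudyData

logger = logging.getLogger("scinsight")

DEFAULT_K_CANDIDATES = (5, 7, 9, 11, 13, 15)
DEFAULT_LAMBDA_CANDIDATES = (0.001, 0.01, 0.1, 1.0, 10.0)
DEFAULT_B = 5
SELECTION_LAMBDA = 0.01  # penalty used for all fits during K selection
DEFAULT_TOP_GENES = 100
DEFAULT_SUBSAMPLE = 2000
_EPS = 1e-12


@dataclass
class ConsensusRun:
    """Stability diagnostics for one candidate K."""

    K: int
    B: int
    run_labels: list[np.ndarray]
    consensus: np.ndarray
    stability: float


@dataclass
class SpecificityReport:
    """Specificity diagnostics for one candidate penalty value."""

    lam: float
    A: np.ndarray  # A[j][k][l]: mean top-gene expression, padded with nan
    score: float


def consensus_matrix(run_labels: list[np.ndarray]) -> np.ndarray:
    """Average same-cluster indicator over B runs; entries in [0, 1]."""
    if not run_labels:
        raise ValueError("need at least one label vector")
    M = len(run_labels[0])
    for lab in run_labels:
        if len(lab) != M:
            raise ValueError("label vectors have inconsistent lengths")
    C = np.zeros((M, M))
    for lab in run_labels:
        lab = np.asarray(lab)
        C += (lab[:, None] == lab[None, :]).astype(float)
    return C / len(run_labels)


def stability_score(C: np.ndarray) -> float:
    """Cophenetic correlation of the consensus dissimilarity 1 - C.

    Average-linkage hierarchical clustering is run on D = 1 - C and the
    Pearson correlation between the upper-triangle entries of D and of
    the cophenetic distance matrix is returned. If all runs agree
    perfectly, D is an ultrametric and the score is 1. A constant D has
    no variance; 1 is returned by convention (maximally stable).
    """
    C = np.asarray(C, float)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if condensed.std() == 0:
        logger.warning("constant consensus dissimilarity; stability 1 by convention")
        return 1.0
    Z = linkage(condensed, method="average")
    _, coph_dist = cophenet(Z, condensed)
    if coph_dist.std() == 0:
        return 1.0
    return float(np.corrcoef(condensed, coph_dist)[0, 1])


def pick_middle_K(candidates, scores) -> int:
    """The selection rule: median K among the three most stable candidates.

    Ties in stability are broken toward the larger stability value first
    and then toward the smaller K.
    """
    if len(candidates) < 3:
        raise ValueError("need at least three candidates")
    order = sorted(zip(candidates, scores), key=lambda t: (-t[1], t[0]))
    top3 = sorted(k for k, _ in order[:3])
    return top3[1]


def _subsample_indices(study: StudyData, limit: int, seed: int | None) -> np.ndarray | None:
    M = study.n_cells
    if M <= limit:
        return None
    rng = np.random.default_rng(seed)
    sample_of = study.sample_index_of_cells()
    keep = []
    for l in range(study.n_samples):
        cells = np.flatnonzero(sample_of == l)
        n_keep = max(1, int(round(limit * len(cells) / M)))
        keep.append(rng.choice(cells, size=min(n_keep, len(cells)), replace=False))
    idx = np.sort(np.concatenate(keep))
    logger.info("stability computed on a stratified subsample of %d/%d cells",
                len(idx), M)
    return idx


def select_K(data, candidates=DEFAULT_K_CANDIDATES, B: int = DEFAULT_B,
             seed: int | None = 0, K_j: int = 2,
             lambda_: float = SELECTION_LAMBDA,
             max_iter: int = factorization.DEFAULT_MAX_ITER,
             tol: float = factorization.DEFAULT_TOL,
             n_c: int = 20, resolution: float = 1.0,
             subsample: int = DEFAULT_SUBSAMPLE) -> tuple[int, dict[int, ConsensusRun]]:
    """Choose K by consensus-clustering stability over B random restarts.

    For every candidate, the model is fitted B times from different
    initializations (lambda1 = lambda2 = 0.01) and clustered; the middle
    value of the three highest-stability candidates is returned. For
    studies above ``subsample`` cells, consensus matrices are computed on
    a seeded, sample-stratified subsample to bound memory.
    """
    candidates = list(candidates)
    if len(candidates) < 3:
        raise ValueError("need at least three candidate values of K")
    study = data.study if isinstance(data, ProcessedStudy) else data
    idx = _subsample_indices(study, subsample, seed)
    rng = np.random.default_rng(seed)
    runs: dict[int, ConsensusRun] = {}
    for K in sorted(candidates):
        run_labels = []
        for b in range(B):
            fit_seed = int(rng.integers(0, 2**31 - 1))
            model, _ = factorization.fit(
                data, K=K, K_j=K_j, lambda1=lambda_, lambda2=lambda_,
                seed=fit_seed, max_iter=max_iter, tol=tol)
            labels = cluster_cells(model, n_c=n_c, resolution=resolution,
                                   seed=fit_seed).labels
            run_labels.append(labels if idx is None else labels[idx])
        C = consensus_matrix(run_labels)
        score = stability_score(C)
        runs[K] = ConsensusRun(K, B, run_labels, C, score)
        logger.info("K=%d: stability %.4f", K, score)
    ordered = sorted(runs)
    best = pick_middle_K(ordered, [runs[K].stability for K in ordered])
    return best, runs


def specificity_score(model, data, top_g: int = DEFAULT_TOP_GENES,
                      return_terms: bool = False):
    """How specifically condition modules are expressed in their own condition.

    For module k of condition j, take the ``top_g`` genes with the largest
    membership coefficients and let A[j,k,l] be their mean processed
    expression over the cells of sample l. The score averages, over
    conditions, the ratio of own-condition to other-condition sums of A.
    """
    study = data.study if isinstance(data, ProcessedStudy) else data
    X = study.matrices()
    L, J = study.n_samples, study.n_conditions
    n = study.n_genes
    if top_g > n:
        logger.warning("top_g=%d exceeds %d genes; using all genes", top_g, n)
        top_g = n
    K_max = max(h.shape[0] for h in model.H)
    A = np.full((J, K_max, L), np.nan)
    for j in range(J):
        Hj = model.H[j]
        for k in range(Hj.shape[0]):
            top = np.argsort(-Hj[k], kind="stable")[:top_g]
            for l in range(L):
                A[j, k, l] = X[l][:, top].mean()
    score = 0.0
    for j in range(J):
        own = [l for l in range(L) if study.condition_of[l] == j]
        other = [l for l in range(L) if study.condition_of[l] != j]
        k_j = model.H[j].shape[0]
        num = np.nansum(A[j, :k_j][:, own])
        den = np.nansum(A[j, :k_j][:, other]) if other else 0.0
        score += num / (den + _EPS)
    score /= J
    if return_terms:
        return float(score), A
    return float(score)


def select_lambda(data, K: int, candidates=DEFAULT_LAMBDA_CANDIDATES,
                  seed: int | None = 0, K_j: int = 2,
                  top_g: int = DEFAULT_TOP_GENES,
                  max_iter: int = factorization.DEFAULT_MAX_ITER,
                  tol: float = factorization.DEFAULT_TOL
                  ) -> tuple[float, list[SpecificityReport]]:
    """Choose lambda1 = lambda2 by maximizing the specificity score.

    One fit per candidate; exact ties go to the smaller penalty.
    """
    reports = []
    best_lam, best_score = None, -np.inf
    for lam in sorted(candidates):
        model, _ = factorization.fit(data, K=K, K_j=K_j, lambda1=lam,
                                     lambda2=lam, seed=seed,
                                     max_iter=max_iter, tol=tol)
        score, A = specificity_score(model, data, top_g=top_g, return_terms=True)
        reports.append(SpecificityReport(lam, A, score))
        logger.info("lambda=%g: specificity %.4f", lam, score)
        if score > best_score:
            best_lam, best_score = lam, score
    return float(best_lam), reports
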