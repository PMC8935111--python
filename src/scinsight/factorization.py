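"""Joint NMF of multi-condition studies by block coordinate descent.

The model decomposes each sample's expression matrix into a
condition-specific part and a common part,

    X_l = W_l1 H_{j_l} + W_l2 V + E_l ,

with all factors non-negative. Rows of V are *common gene modules*
(shared by all samples); rows of H_j are *condition-specific gene
modules* (shared by the samples of condition j); W_l2 and W_l1 hold each
cell's expression of those modules. The objective

    sum_l (1/m_l) ||X_l - W_l1 H_{j_l} - W_l2 V||_F^2
    + lambda1 sum_l (1/m_l) ||W_l1 H_{j_l}||_F^2
    + lambda2 sum_{j<j'} ||H_j H_{j'}^T||_1

penalizes the scale of the condition-specific component (lambda1) and
the overlap between condition-specific modules of different conditions
(lambda2); rows of V and H_j are constrained to unit L2 norm. The solver
performs HALS-style block coordinate descent: each factor row/column is
updated in closed form with a non-negative projection, with the residual
refreshed after every row/column so later blocks see the current state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .study import ProcessedStudy, StudyData

logger = logging.getLogger("scinsight")

_EPS = 1e-12  # denominator guard: blocks with smaller curvature are skipped

DEFAULT_LAMBDA = 0.01
DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-5
DEFAULT_UPDATE_ORDER = ("W2", "V", "W1", "H")


def _study_of(data) -> StudyData:
    return data.study if isinstance(data, ProcessedStudy) else data


@dataclass
class FactorModel:
    """All factor matrices and hyperparameters of a (possibly unfitted) model.

    ``V`` is K x n, ``H[j]`` is K_j x n, ``W1[l]`` is m_l x K_{j_l} and
    ``W2[l]`` is m_l x K. The residual E_l = X_l - W1[l] H[j_l] - W2[l] V
    is derived on demand, never stored.
    """

    V: np.ndarray
    H: list[np.ndarray]
    W1: list[np.ndarray]
    W2: list[np.ndarray]
    K: int
    K_j: list[int]
    lambda1: float
    lambda2: float
    condition_of: list[int]
    genes: list[str] | None = None
    sample_ids: list[str] = field(default_factory=list)
    condition_labels: list[str] = field(default_factory=list)
    cell_ids: list[list[str]] | None = None
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return len(self.W2)

    @property
    def n_conditions(self) -> int:
        return len(self.H)

    def reconstruction(self, ell: int) -> np.ndarray:
        j = self.condition_of[ell]
        return self.W1[ell] @ self.H[j] + self.W2[ell] @ self.V

    def residuals(self, data) -> list[np.ndarray]:
        X = _study_of(data).matrices()
        return [X[ell] - self.reconstruction(ell) for ell in range(self.n_samples)]

    def copy(self) -> "FactorModel":
        return FactorModel(
            self.V.copy(), [h.copy() for h in self.H],
            [w.copy() for w in self.W1], [w.copy() for w in self.W2],
            self.K, list(self.K_j), self.lambda1, self.lambda2,
            list(self.condition_of), self.genes,
            list(self.sample_ids), list(self.condition_labels),
            self.cell_ids, self.seed)


@dataclass
class FitReport:
    """Objective trace and convergence status of one solver run."""

    objective_trace: list[float]
    n_iter: int
    converged: bool
    seed: int | None
    tol: float


def _check_shapes(model: FactorModel, study: StudyData) -> None:
    n = study.n_genes
    if model.V.shape != (model.K, n):
        raise ValueError(f"V has shape {model.V.shape}, expected ({model.K}, {n})")
    if len(model.H) != study.n_conditions:
        raise ValueError("number of H matrices does not match conditions")
    for j, h in enumerate(model.H):
        if h.shape != (model.K_j[j], n):
            raise ValueError(f"H[{j}] has shape {h.shape}, expected ({model.K_j[j]}, {n})")
    for ell, s in enumerate(study.samples):
        j = model.condition_of[ell]
        if model.W1[ell].shape != (s.n_cells, model.K_j[j]):
            raise ValueError(f"W1[{ell}] shape mismatch")
        if model.W2[ell].shape != (s.n_cells, model.K):
            raise ValueError(f"W2[{ell}] shape mismatch")


def objective(model: FactorModel, data) -> float:
    """Evaluate the penalized factorization objective on ``data``."""
    study = _study_of(data)
    _check_shapes(model, study)
    total = 0.0
    for ell, s in enumerate(study.samples):
        j = model.condition_of[ell]
        cond_part = model.W1[ell] @ model.H[j]
        resid = s.values - cond_part - model.W2[ell] @ model.V
        m = s.n_cells
        total += (resid * resid).sum() / m
        total += model.lambda1 * (cond_part * cond_part).sum() / m
    J = model.n_conditions
    for j in range(J - 1):
        for jp in range(j + 1, J):
            total += model.lambda2 * float((model.H[j] @ model.H[jp].T).sum())
    return float(total)


def initialize(data, K: int, K_j: int | list[int] = 2, seed: int | None = 0,
               lambda1: float = DEFAULT_LAMBDA,
               lambda2: float = DEFAULT_LAMBDA) -> FactorModel:
    """Random non-negative initialization scaled to the data's magnitude.

    All matrices are filled with uniform(0, 1) draws; W matrices are then
    scaled so that the initial reconstruction matches the mean of the data
    entries, and rows of V and H are L2-normalized. Fully reproducible
    from ``seed``.
    """
    study = _study_of(data)
    n = study.n_genes
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of genes ({n})")
    J = study.n_conditions
    if isinstance(K_j, int):
        K_j = [K_j] * J
    K_j = [int(k) for k in K_j]
    if len(K_j) != J or any(k < 1 for k in K_j):
        raise ValueError("K_j must be a positive integer per condition")

    rng = np.random.default_rng(seed)
    V = rng.uniform(size=(K, n))
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    H = []
    for j in range(J):
        h = rng.uniform(size=(K_j[j], n))
        h /= np.linalg.norm(h, axis=1, keepdims=True)
        H.append(h)

    data_mean = np.mean([s.values.mean() for s in study.samples])
    # E[u]=1/2 and E[v] ~ mean of a normalized uniform row, so scale W such
    # that the initial common reconstruction W2 V matches the data magnitude.
    v_mean = V.mean()
    with np.errstate(over="ignore"):  # absurd inputs fail later with a clear error
        w_scale = data_mean / max(K * 0.5 * v_mean, _EPS)
    W1, W2 = [], []
    for ell, s in enumerate(study.samples):
        j = study.condition_of[ell]
        W1.append(rng.uniform(size=(s.n_cells, K_j[j])) * w_scale)
        W2.append(rng.uniform(size=(s.n_cells, K)) * w_scale)

    return FactorModel(V, H, W1, W2, K, K_j, lambda1, lambda2,
                       list(study.condition_of), list(study.genes),
                       [s.sample_id for s in study.samples],
                       list(study.conditions),
                       [list(s.cells) for s in study.samples],
                       seed)


# ---------------------------------------------------------------------------
# HALS block updates. Each processes rows/columns sequentially, refreshing
# the residual list R (R[l] = X_l - W1[l] H[j_l] - W2[l] V) in place.
# ---------------------------------------------------------------------------

def _residuals(model: FactorModel, data) -> list[np.ndarray]:
    study = _study_of(data)
    _check_shapes(model, study)
    return model.residuals(study)


def update_V(model: FactorModel, data, residuals: list[np.ndarray] | None = None,
             skipped: list | None = None) -> np.ndarray:
    """One HALS pass over the rows of V (in place). Returns V."""
    R = residuals if residuals is not None else _residuals(model, data)
    m = [w.shape[0] for w in model.W2]
    L = model.n_samples
    for k in range(model.K):
        den = sum(float(model.W2[ell][:, k] @ model.W2[ell][:, k]) / m[ell]
                  for ell in range(L))
        if den <= _EPS:
            logger.warning("update_V: module %d has zero expression in all "
                           "samples; row skipped", k)
            if skipped is not None:
                skipped.append(("V", k))
            continue
        num = np.zeros(model.V.shape[1])
        for ell in range(L):
            num += (R[ell].T @ model.W2[ell][:, k]) / m[ell]
        new_row = np.maximum(model.V[k] + num / den, 0.0)
        delta = new_row - model.V[k]
        if np.any(delta):
            for ell in range(L):
                R[ell] -= np.outer(model.W2[ell][:, k], delta)
            model.V[k] = new_row
    return model.V


def update_W2(model: FactorModel, data, residuals: list[np.ndarray] | None = None,
              skipped: list | None = None) -> list[np.ndarray]:
    """One HALS pass over the columns of every W_l2 (in place)."""
    R = residuals if residuals is not None else _residuals(model, data)
    for ell in range(model.n_samples):
        W = model.W2[ell]
        for k in range(model.K):
            den = float(model.V[k] @ model.V[k])
            if den <= _EPS:
                logger.warning("update_W2: V row %d is zero; column skipped", k)
                if skipped is not None:
                    skipped.append(("W2", ell, k))
                continue
            new_col = np.maximum(W[:, k] + (R[ell] @ model.V[k]) / den, 0.0)
            delta = new_col - W[:, k]
            if np.any(delta):
                R[ell] -= np.outer(delta, model.V[k])
                W[:, k] = new_col
    return model.W2


def update_W1(model: FactorModel, data, residuals: list[np.ndarray] | None = None,
              skipped: list | None = None) -> list[np.ndarray]:
    """One HALS pass over the columns of every W_l1 (in place).

    The effective residual for this block is X - (1+lambda1) W1 H - W2 V,
    computed from the plain residual as R - lambda1 * W1 H; the lambda1
    factor comes from the scale penalty on the condition-specific part.
    """
    R = residuals if residuals is not None else _residuals(model, data)
    lam1 = model.lambda1
    for ell in range(model.n_samples):
        j = model.condition_of[ell]
        Hj = model.H[j]
        W = model.W1[ell]
        for k in range(W.shape[1]):
            h = Hj[k]
            den = (1.0 + lam1) * float(h @ h)
            if den <= _EPS:
                logger.warning("update_W1: H row %d of condition %d is zero; "
                               "column skipped", k, j)
                if skipped is not None:
                    skipped.append(("W1", ell, k))
                continue
            num = R[ell] @ h - lam1 * (W @ (Hj @ h))
            new_col = np.maximum(W[:, k] + num / den, 0.0)
            delta = new_col - W[:, k]
            if np.any(delta):
                R[ell] -= np.outer(delta, h)
                W[:, k] = new_col
    return model.W1


def update_H(model: FactorModel, data, residuals: list[np.ndarray] | None = None,
             skipped: list | None = None) -> list[np.ndarray]:
    """One HALS pass over the rows of every H_j (in place).

    The lambda2 cross-condition term contributes a linear penalty equal to
    (lambda2/4) times the sum of all module rows of the other conditions,
    pushing overlapping support toward zero.
    """
    R = residuals if residuals is not None else _residuals(model, data)
    lam1, lam2 = model.lambda1, model.lambda2
    m = [w.shape[0] for w in model.W1]
    J = model.n_conditions
    for j in range(J):
        members = [ell for ell in range(model.n_samples) if model.condition_of[ell] == j]
        Hj = model.H[j]
        if J > 1 and lam2 > 0:
            cross = (lam2 / 4.0) * np.sum(
                [model.H[jp].sum(axis=0) for jp in range(J) if jp != j], axis=0)
        else:
            cross = 0.0
        for k in range(Hj.shape[0]):
            den = sum((1.0 + lam1) / m[ell] * float(model.W1[ell][:, k] @ model.W1[ell][:, k])
                      for ell in members)
            if den <= _EPS:
                logger.warning("update_H: module %d of condition %d has zero "
                               "expression; row skipped", k, j)
                if skipped is not None:
                    skipped.append(("H", j, k))
                continue
            num = np.zeros(Hj.shape[1]) - cross
            for ell in members:
                wcol = model.W1[ell][:, k]
                num += (R[ell].T @ wcol
                        - lam1 * (Hj.T @ (model.W1[ell].T @ wcol))) / m[ell]
            new_row = np.maximum(Hj[k] + num / den, 0.0)
            delta = new_row - Hj[k]
            if np.any(delta):
                for ell in members:
                    R[ell] -= np.outer(model.W1[ell][:, k], delta)
                Hj[k] = new_row
    return model.H


def renormalize(model: FactorModel) -> FactorModel:
    """Rescale rows of V and H_j to unit L2 norm, preserving reconstructions.

    The inverse scale is absorbed into the matching column of every W_l2
    (for V) or W_l1 (for H), so W1 H + W2 V is unchanged. Zero rows are
    left as is.
    """
    for k in range(model.K):
        s = float(np.linalg.norm(model.V[k]))
        if s > 0:
            model.V[k] /= s
            for W in model.W2:
                W[:, k] *= s
    for j, Hj in enumerate(model.H):
        for k in range(Hj.shape[0]):
            s = float(np.linalg.norm(Hj[k]))
            if s > 0:
                Hj[k] /= s
                for ell in range(model.n_samples):
                    if model.condition_of[ell] == j:
                        model.W1[ell][:, k] *= s
    return model


_UPDATES = {"V": update_V, "W2": update_W2, "W1": update_W1, "H": update_H}


def fit(data, K: int, K_j: int | list[int] = 2,
        lambda1: float = DEFAULT_LAMBDA, lambda2: float = DEFAULT_LAMBDA,
        seed: int | None = 0, max_iter: int = DEFAULT_MAX_ITER,
        tol: float = DEFAULT_TOL,
        update_order: tuple[str, ...] = DEFAULT_UPDATE_ORDER,
        init: FactorModel | None = None) -> tuple[FactorModel, FitReport]:
    """Solve the joint factorization by cyclic block coordinate descent.

    Each cycle applies one HALS pass per block in ``update_order``, records
    the objective, then rescales V/H rows to unit norm (absorbing the scale
    into the W columns, which leaves reconstructions unchanged). Stops when
    the relative objective change falls below ``tol`` or after ``max_iter``
    cycles. Blocks whose curvature stays zero for 5 consecutive cycles are
    reseeded from uniform(0, 1e-4) to revive dead modules.
    """
    study = _study_of(data)
    if set(update_order) != set(_UPDATES):
        raise ValueError(f"update_order must be a permutation of {sorted(_UPDATES)}")
    model = init.copy() if init is not None else \
        initialize(study, K, K_j, seed=seed, lambda1=lambda1, lambda2=lambda2)
    rng = np.random.default_rng(None if seed is None else seed + 1)

    R = model.residuals(study)
    trace = [objective(model, study)]
    if not np.isfinite(trace[0]):
        raise RuntimeError("non-finite objective at initialization")
    dead_count: dict[tuple, int] = {}
    converged = False
    n_iter = 0
    for it in range(max_iter):
        skipped: list[tuple] = []
        for name in update_order:
            _UPDATES[name](model, study, residuals=R, skipped=skipped)
        obj = objective(model, study)
        if not np.isfinite(obj):
            raise RuntimeError(f"non-finite objective at cycle {it + 1}; "
                               "check input scale and hyperparameters")
        trace.append(obj)
        n_iter = it + 1

        # revive blocks that stayed dead for 5 consecutive cycles
        for key in list(dead_count):
            if key not in skipped:
                del dead_count[key]
        for key in skipped:
            dead_count[key] = dead_count.get(key, 0) + 1
            if dead_count[key] >= 5:
                kind = key[0]
                if kind == "V":
                    model.V[key[1]] = rng.uniform(0, 1e-4, model.V.shape[1])
                elif kind == "W2":
                    model.W2[key[1]][:, key[2]] = rng.uniform(
                        0, 1e-4, model.W2[key[1]].shape[0])
                elif kind == "W1":
                    model.W1[key[1]][:, key[2]] = rng.uniform(
                        0, 1e-4, model.W1[key[1]].shape[0])
                else:
                    model.H[key[1]][key[2]] = rng.uniform(0, 1e-4, model.V.shape[1])
                logger.warning("reinitialized dead block %s", key)
                dead_count[key] = 0
                R = model.residuals(study)

        renormalize(model)
        R = model.residuals(study)
        prev = trace[-2]
        if prev > 0 and abs(prev - obj) / prev < tol:
            converged = True
            break

    report = FitReport(trace, n_iter, converged, seed, tol)
    return model, report


class SCInsight(BaseEstimator):
    """Joint NMF estimator for multi-sample, multi-condition expression data.

    Decomposes pooled cells x genes data into K common gene modules shared
    by all samples and K_j condition-specific modules per condition, by
    block coordinate descent on a penalized non-negative factorization.

    Parameters
    ----------
    K : int, default 13
        Number of common gene modules.
    K_j : int, default 2
        Number of condition-specific modules per condition (kept small
        relative to K to ease interpretation).
    lambda1 : float, default 0.01
        Scale penalty on the condition-specific component.
    lambda2 : float, default 0.01
        Overlap penalty between condition-specific modules of different
        conditions.
    max_iter, tol
        Stopping rule: at most ``max_iter`` BCD cycles, or relative
        objective change below ``tol``.
    random_state : int or None
        Seed for the random initialization.

    Attributes
    ----------
    V_ : ndarray of shape (K, n_genes)
        Common gene module memberships (unit-norm rows).
    H_ : list of ndarray
        Condition-specific module memberships, one (K_j, n_genes) matrix
        per condition (unit-norm rows).
    W1_, W2_ : list of ndarray
        Per-sample module expression (cells x modules).
    embedding_ : ndarray of shape (n_cells, K)
        Pooled common-module expression (rows of W2_, samples stacked in
        study order); the representation used for clustering.
    objective_trace_ : list of float
    """

    def __init__(self, K: int = 13, K_j: int = 2,
                 lambda1: float = DEFAULT_LAMBDA, lambda2: float = DEFAULT_LAMBDA,
                 max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL,
                 update_order: tuple[str, ...] = DEFAULT_UPDATE_ORDER,
                 random_state: int | None = 0):
        self.K = K
        self.K_j = K_j
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.max_iter = max_iter
        self.tol = tol
        self.update_order = update_order
        self.random_state = random_state

    def _as_study(self, X, sample_labels, condition_labels) -> StudyData:
        if isinstance(X, (StudyData, ProcessedStudy)):
            return _study_of(X)
        X = np.asarray(X, dtype=np.float64)
        if sample_labels is None or condition_labels is None:
            raise ValueError("array input requires sample_labels and "
                             "condition_labels (one entry per cell)")
        sample_labels = np.asarray(sample_labels)
        condition_labels = np.asarray(condition_labels)
        if len(sample_labels) != X.shape[0] or len(condition_labels) != X.shape[0]:
            raise ValueError("labels must have one entry per row of X")
        from .study import SampleMatrix
        samples = []
        seen: list = []
        for sid in sample_labels:
            if sid not in seen:
                seen.append(sid)
        genes = [f"gene{i + 1}" for i in range(X.shape[1])]
        for sid in seen:
            mask = sample_labels == sid
            conds = set(condition_labels[mask])
            if len(conds) != 1:
                raise ValueError(f"sample {sid!r} maps to several conditions: {conds}")
            cells = [f"{sid}:{i}" for i in np.flatnonzero(mask)]
            samples.append(SampleMatrix(str(sid), str(conds.pop()), cells,
                                        genes, X[mask]))
        return StudyData(samples)

    def fit(self, X, y=None, *, sample_labels=None, condition_labels=None):
        """Fit the factorization.

        ``X`` may be a :class:`StudyData`/:class:`ProcessedStudy`, or a
        pooled cells x genes array together with per-cell ``sample_labels``
        and ``condition_labels``.
        """
        study = self._as_study(X, sample_labels, condition_labels)
        model, report = fit(
            study, K=self.K, K_j=self.K_j, lambda1=self.lambda1,
            lambda2=self.lambda2, seed=self.random_state,
            max_iter=self.max_iter, tol=self.tol, update_order=self.update_order)
        self.model_ = model
        self.report_ = report
        self.V_ = model.V
        self.H_ = model.H
        self.W1_ = model.W1
        self.W2_ = model.W2
        self.K_j_ = model.K_j
        self.genes_ = model.genes
        self.sample_ids_ = model.sample_ids
        self.condition_labels_ = model.condition_labels
        self.objective_trace_ = report.objective_trace
        self.n_iter_ = report.n_iter
        self.converged_ = report.converged
        self.embedding_ = np.vstack(model.W2)
        return self

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        """Fit and return the pooled common-module expression (cells x K)."""
        return self.fit(X, y, **fit_params).embedding_
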