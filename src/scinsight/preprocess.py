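"""Count normalization and highly variable gene selection.

Raw counts are processed in three steps before factorization: (1) each
cell's counts are scaled to a fixed library size (1e5 by default), (2)
the scaled values are transformed by ln(1 + x), and (3) genes are ranked
by a standardized dispersion statistic and the top ``n_genes`` retained.
Users who prefer their own normalization can wrap already-processed
matrices with :func:`accept_preprocessed`.
"""

from __future__ import annotations

import logging

import numpy as np

from .study import ProcessedStudy, SampleMatrix, StudyData

logger = logging.getLogger("scinsight")

DEFAULT_TARGET = 1e5
DEFAULT_N_HVGS = 2000


def normalize_and_log(study: StudyData, target: float = DEFAULT_TARGET) -> StudyData:
    """Scale each cell to ``target`` total counts, then apply ln(1 + x).

    All-zero cells cannot be scaled; they are left all-zero and a warning
    is logged (they are retained so that cell metadata stays aligned).
    """
    if target <= 0:
        raise ValueError("target must be positive")
    out = []
    for s in study.samples:
        if (s.values < 0).any():
            raise ValueError(f"sample '{s.sample_id}': negative counts")
        totals = s.values.sum(axis=1)
        zero = totals == 0
        if zero.any():
            logger.warning("sample '%s': %d all-zero cells left unscaled",
                           s.sample_id, int(zero.sum()))
        scale = np.where(zero, 0.0, target / np.where(zero, 1.0, totals))
        values = np.log1p(s.values * scale[:, None])
        out.append(SampleMatrix(s.sample_id, s.condition_id, list(s.cells),
                                list(s.genes), values))
    return StudyData(out, list(study.conditions), list(study.condition_of))


def dispersion_statistic(values: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Standardized dispersion per gene for one normalized, logged sample.

    Computes mean and dispersion (variance/mean) of exp(x) - 1 per gene,
    then z-scores the dispersion within ``n_bins`` equal-frequency bins of
    the mean, so that dispersion is judged relative to genes of similar
    abundance. Genes with zero mean get statistic 0.
    """
    expm = np.expm1(values)
    mean = expm.mean(axis=0)
    var = expm.var(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    n = mean.size
    # keep bins populated: z-scores within singleton bins are meaningless
    n_bins = max(1, min(n_bins, n // 5))
    order = np.argsort(mean, kind="stable")
    bins = np.empty(n, dtype=int)
    bins[order] = np.minimum((np.arange(n) * n_bins) // n, n_bins - 1)
    z = np.zeros(n)
    for b in range(n_bins):
        mask = bins == b
        if not mask.any():
            continue
        mu, sd = disp[mask].mean(), disp[mask].std(ddof=0)
        if sd > 0:
            z[mask] = (disp[mask] - mu) / sd
    z[mean == 0] = 0.0
    return z


def select_hvgs(study: StudyData, n_genes: int = DEFAULT_N_HVGS,
                n_bins: int = 20) -> list[str]:
    """Select the ``n_genes`` most variable genes across samples.

    The standardized dispersion statistic is computed per sample on
    normalized log values, genes are ranked within each sample (rank 0 =
    most variable), and samples are combined by the median rank; the
    combination is robust to a single aberrant sample. Returns the
    selected genes ordered from most to least variable; deterministic.
    """
    n = study.n_genes
    if n_genes > n:
        raise ValueError(f"n_genes={n_genes} exceeds the {n} genes in the study")
    ranks = np.empty((study.n_samples, n))
    for i, s in enumerate(study.samples):
        z = dispersion_statistic(s.values, n_bins=n_bins)
        order = np.argsort(-z, kind="stable")
        r = np.empty(n)
        r[order] = np.arange(n)
        ranks[i] = r
    median_rank = np.median(ranks, axis=0)
    chosen = np.argsort(median_rank, kind="stable")[:n_genes]
    genes = study.genes
    return [genes[i] for i in chosen]


def accept_preprocessed(study: StudyData,
                        normalization_target: float = DEFAULT_TARGET) -> ProcessedStudy:
    """Wrap user-supplied normalized and filtered matrices, unchanged.

    Only invariants are checked (non-negativity and a shared gene list,
    both enforced by :class:`StudyData`); values pass through bit-identically.
    """
    for s in study.samples:
        if (s.values < 0).any():
            raise ValueError(f"sample '{s.sample_id}': negative values")
    return ProcessedStudy(study, list(study.genes), normalization_target)


def preprocess(study: StudyData, target: float = DEFAULT_TARGET,
               n_hvgs: int = DEFAULT_N_HVGS) -> ProcessedStudy:
    """Full pipeline: normalize, log-transform, select HVGs, subset genes.

    The selected genes are re-ordered to the study's original gene order
    so that factor matrices align with upstream annotation.
    """
    normed = normalize_and_log(study, target=target)
    n_hvgs = min(n_hvgs, study.n_genes)
    hvgs = set(select_hvgs(normed, n_genes=n_hvgs))
    keep = [g for g in study.genes if g in hvgs]
    return ProcessedStudy(normed.subset_genes(keep), keep, target)
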