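"""Containers for multi-sample, multi-condition expression studies.

A *study* is an ordered collection of single-cell expression samples
(cells x genes, non-negative), each assigned to one biological condition
(a phenotype, treatment arm, disease phase or time point). All samples
must share one gene list in one order; cell identifiers are globally
unique because loaders namespace them as ``<sample_id>:<barcode>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("scinsight")


def _as_dense(values) -> np.ndarray:
    if sp.issparse(values):
        values = values.toarray()
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expression matrix must be 2-D, got shape {arr.shape}")
    return arr


@dataclass
class SampleMatrix:
    """One sample: a cells x genes matrix of non-negative expression values."""

    sample_id: str
    condition_id: str
    cells: list[str]
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_dense(self.values)
        m, n = self.values.shape
        if m == 0 or n == 0:
            raise ValueError(f"sample '{self.sample_id}' is empty (shape {m}x{n})")
        if m != len(self.cells):
            raise ValueError(
                f"sample '{self.sample_id}': {m} rows but {len(self.cells)} cell IDs"
            )
        if n != len(self.genes):
            raise ValueError(
                f"sample '{self.sample_id}': {n} columns but {len(self.genes)} genes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"sample '{self.sample_id}': duplicate gene names")
        if not np.isfinite(self.values).all():
            raise ValueError(f"sample '{self.sample_id}': non-finite expression values")
        if (self.values < 0).any():
            raise ValueError(f"sample '{self.sample_id}': negative expression values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class StudyData:
    """An ordered list of samples sharing one gene list, grouped into conditions.

    Attributes
    ----------
    samples
        The L :class:`SampleMatrix` objects, in study order.
    conditions
        The J distinct condition labels, in order of first appearance.
    condition_of
        Per sample, the index into ``conditions`` of its condition.
    """

    samples: list[SampleMatrix]
    conditions: list[str] = field(default_factory=list)
    condition_of: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("a study needs at least one sample")
        if not self.conditions:
            seen: list[str] = []
            for s in self.samples:
                if s.condition_id not in seen:
                    seen.append(s.condition_id)
            self.conditions = seen
            self.condition_of = [self.conditions.index(s.condition_id) for s in self.samples]
        ref = self.samples[0].genes
        for s in self.samples[1:]:
            if s.genes != ref:
                raise ValueError(
                    f"sample '{s.sample_id}' does not share the gene list of "
                    f"sample '{self.samples[0].sample_id}' (same genes, same order, required)"
                )

    # -- shape accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def genes(self) -> list[str]:
        return self.samples[0].genes

    @property
    def n_genes(self) -> int:
        return self.samples[0].n_genes

    @property
    def n_cells(self) -> int:
        return sum(s.n_cells for s in self.samples)

    @property
    def cells_per_sample(self) -> list[int]:
        return [s.n_cells for s in self.samples]

    def matrices(self) -> list[np.ndarray]:
        return [s.values for s in self.samples]

    def sample_index_of_cells(self) -> np.ndarray:
        """Per pooled cell (samples concatenated in order), its sample index."""
        return np.repeat(np.arange(self.n_samples), self.cells_per_sample)

    def subset_genes(self, genes: list[str]) -> "StudyData":
        """Return a new study restricted to ``genes``, in the given order."""
        idx = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValueError(f"genes not present in study: {missing[:5]}")
        cols = np.array([idx[g] for g in genes])
        new_samples = [
            SampleMatrix(s.sample_id, s.condition_id, list(s.cells), list(genes),
                         s.values[:, cols])
            for s in self.samples
        ]
        return StudyData(new_samples, list(self.conditions), list(self.condition_of))


@dataclass
class ProcessedStudy:
    """A study after library-size normalization, log transform and gene selection."""

    study: StudyData
    selected_genes: list[str]
    normalization_target: float = 1e5

    def __post_init__(self) -> None:
        if self.normalization_target <= 0:
            raise ValueError("normalization_target must be positive")
        if self.selected_genes != self.study.genes:
            raise ValueError("selected_genes must equal the study's gene list")
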