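"""Synthetic multi-sample, multi-condition scRNA-seq count data.

The generator emulates a study of six samples from three time points
(two samples each) with six cell types, where three types are shared by
all conditions and each condition lacks one of the other three:

==========  ======  ====  ====  ====  ====  ====  ====
Condition   Sample  C1    C2    C3    C4    C5    C6
==========  ======  ====  ====  ====  ====  ====  ====
T1          S1/S2   100   100   100   0     100   100
T2          S3/S4   100   100   100   100   0     100
T3          S5/S6   100   100   100   100   100   0
==========  ======  ====  ====  ====  ====  ====  ====

Each cell type and each condition carries a disjoint block of marker
genes that is upregulated on the log scale. A cell's log mean expression
is the weighted combination 0.9 * type effect + 0.1 * condition effect;
counts are drawn negative-binomially around library-size-scaled means
and thinned by uniform dropout, giving the sparsity and overdispersion
typical of UMI data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .study import SampleMatrix, StudyData

logger = logging.getLogger("scinsight")

DEFAULT_CONDITIONS = ("T1", "T2", "T3")
DEFAULT_CELL_TYPES = ("C1", "C2", "C3", "C4", "C5", "C6")
# each condition lacks one condition-specific cell type
DEFAULT_ABSENT = {"T1": ("C4",), "T2": ("C5",), "T3": ("C6",)}


def _default_composition(conditions, samples_per_condition, cell_types,
                         cells_per_type, absent,
                         overrides: dict[str, int] | None = None
                         ) -> dict[str, dict[str, int]]:
    comp: dict[str, dict[str, int]] = {}
    s = 0
    for cond in conditions:
        for _ in range(samples_per_condition):
            s += 1
            sid = f"S{s}"
            comp[sid] = {
                ct: 0 if ct in absent.get(cond, ()) else
                (overrides or {}).get(ct, cells_per_type)
                for ct in cell_types
            }
    return comp


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study generator.

    ``type_weight`` and ``condition_weight`` must sum to 1; the per-cell
    log mean is their weighted combination of the type and condition
    effect vectors. Effects are block-structured: each type (condition)
    upregulates its own disjoint marker-gene block by ``type_effect``
    (``condition_effect``) natural-log units.
    """

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    samples_per_condition: int = 2
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    cells_per_type: int = 100
    absent: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ABSENT))
    composition: dict[str, dict[str, int]] | None = None
    n_genes: int = 1500
    type_weight: float = 0.9
    condition_weight: float = 0.1
    markers_per_type: int = 150
    markers_per_condition: int = 100
    type_effect: float = 2.5
    condition_effect: float = 2.0
    baseline_sigma: float = 0.4
    effect_jitter: float = 0.1
    library_size: float = 800.0
    libsize_sigma: float = 0.3
    sample_effect_sigma: float = 0.2  # per-sample gene-wise technical effect
    nb_dispersion: float | None = 2.0  # NB size parameter; None = Poisson
    dropout: float = 0.3
    seed: int | None = 0

    def __post_init__(self) -> None:
        if abs(self.type_weight + self.condition_weight - 1.0) > 1e-12:
            raise ValueError("type_weight + condition_weight must equal 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.composition is None:
            self.composition = _default_composition(
                self.conditions, self.samples_per_condition, self.cell_types,
                self.cells_per_type, self.absent)
        n_blocks = (len(self.cell_types) * self.markers_per_type
                    + len(self.conditions) * self.markers_per_condition)
        if n_blocks > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_blocks} marker genes")
        for sid, counts in self.composition.items():
            if any(c < 0 for c in counts.values()):
                raise ValueError(f"negative cell count in sample {sid}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.composition)

    def condition_of_sample(self, sid: str) -> str:
        i = self.sample_ids.index(sid)
        return self.conditions[i // self.samples_per_condition]


def preset_config(name: str = "original", seed: int | None = 0,
                  **overrides) -> SimulationConfig:
    """Named study designs.

    ``original``
        The default six-sample, three-condition design above.
    ``variant1``
        Only C1 shared by all samples (C2 and C3 removed everywhere).
    ``variant2``
        A rare shared type: C2 reduced to 20 cells per sample.
    ``variant3``
        A rare condition-specific type: C4 reduced to 20 cells.
    """
    cfg = SimulationConfig(seed=seed, **overrides)
    if name == "original":
        return cfg
    if name == "variant1":
        comp = {sid: {ct: (0 if ct in ("C2", "C3") else c)
                      for ct, c in counts.items()}
                for sid, counts in cfg.composition.items()}
        return replace(cfg, composition=comp)
    if name == "variant2":
        comp = {sid: {ct: (min(c, 20) if ct == "C2" else c)
                      for ct, c in counts.items()}
                for sid, counts in cfg.composition.items()}
        return replace(cfg, composition=comp)
    if name == "variant3":
        comp = {sid: {ct: (min(c, 20) if ct == "C4" else c)
                      for ct, c in counts.items()}
                for sid, counts in cfg.composition.items()}
        return replace(cfg, composition=comp)
    raise ValueError(f"unknown preset {name!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth labels and generative effect vectors of a synthetic study."""

    type_labels: np.ndarray       # per pooled cell, in study order
    condition_labels: np.ndarray  # per pooled cell
    sample_labels: np.ndarray     # per pooled cell
    type_effects: dict[str, np.ndarray]       # linear scale, per gene
    condition_effects: dict[str, np.ndarray]  # linear scale, per gene
    genes: list[str]


def make_effects(config: SimulationConfig
                 ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Draw per-type and per-condition log-mean effect vectors.

    Marker blocks occupy fixed, disjoint gene ranges (types first, then
    conditions), so the block layout is stable across seeds while the
    baseline and jitter are seed-dependent. Returns natural-log means.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    base = rng.normal(0.0, config.baseline_sigma, n)
    type_lm: dict[str, np.ndarray] = {}
    pos = 0
    for ct in config.cell_types:
        v = base + rng.normal(0.0, config.effect_jitter, n)
        v[pos:pos + config.markers_per_type] += config.type_effect
        type_lm[ct] = v
        pos += config.markers_per_type
    cond_lm: dict[str, np.ndarray] = {}
    for cond in config.conditions:
        v = base + rng.normal(0.0, config.effect_jitter, n)
        v[pos:pos + config.markers_per_condition] += config.condition_effect
        cond_lm[cond] = v
        pos += config.markers_per_condition
    return type_lm, cond_lm


def expected_mean_counts(config: SimulationConfig, cell_type: str,
                         condition: str,
                         effects=None) -> np.ndarray:
    """Expected counts per gene for one (type, condition) at unit library scale."""
    if effects is None:
        effects = make_effects(config)
    type_lm, cond_lm = effects
    lm = (config.type_weight * type_lm[cell_type]
          + config.condition_weight * cond_lm[condition])
    rel = np.exp(lm)
    return rel / rel.sum() * config.library_size


def simulate_study(config: SimulationConfig | None = None
                   ) -> tuple[StudyData, SyntheticTruth]:
    """Generate a full synthetic study of counts with known ground truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    type_lm, cond_lm = make_effects(config)
    genes = [f"gene{i + 1}" for i in range(config.n_genes)]

    samples = []
    all_types, all_conds, all_sids = [], [], []
    for sid in config.sample_ids:
        cond = config.condition_of_sample(sid)
        # gene-wise per-sample technical (batch) effect, shared by all cells
        # of the sample; this is what integration must remove
        batch = (rng.normal(0.0, config.sample_effect_sigma, config.n_genes)
                 if config.sample_effect_sigma > 0 else 0.0)
        rows, cells, cell_types = [], [], []
        i = 0
        for ct, count in config.composition[sid].items():
            if count == 0:
                continue
            lm = (config.type_weight * type_lm[ct]
                  + config.condition_weight * cond_lm[cond] + batch)
            rel = np.exp(lm)
            rel = rel / rel.sum()
            for _ in range(count):
                lib = config.library_size
                if config.libsize_sigma > 0:
                    lib *= float(np.exp(rng.normal(0.0, config.libsize_sigma)))
                mu = rel * lib
                if config.nb_dispersion is None:
                    counts = rng.poisson(mu)
                else:
                    theta = config.nb_dispersion
                    counts = rng.negative_binomial(theta, theta / (theta + mu))
                if config.dropout > 0:
                    counts = counts * (rng.random(config.n_genes) >= config.dropout)
                rows.append(counts.astype(np.float64))
                i += 1
                cells.append(f"{sid}:cell{i:04d}")
                cell_types.append(ct)
        if not rows:
            raise ValueError(f"sample {sid} has no cells under this composition")
        samples.append(SampleMatrix(sid, cond, cells, list(genes), np.vstack(rows)))
        all_types.extend(cell_types)
        all_conds.extend([cond] * len(cells))
        all_sids.extend([sid] * len(cells))

    study = StudyData(samples)
    truth = SyntheticTruth(
        np.asarray(all_types), np.asarray(all_conds), np.asarray(all_sids),
        {ct: np.exp(v) for ct, v in type_lm.items()},
        {c: np.exp(v) for c, v in cond_lm.items()},
        list(genes))
    return study, truth


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def truth_cosine_check(model, truth: SyntheticTruth) -> dict[str, float]:
    """Best cosine match between true condition effects and inferred H rows.

    For each condition, returns the maximum over its module rows of the
    cosine similarity between the row of H_j and the true condition
    effect vector, restricted to the genes the model was fitted on.
    """
    if model.genes is None:
        raise ValueError("model carries no gene names")
    idx = {g: i for i, g in enumerate(truth.genes)}
    missing = [g for g in model.genes if g not in idx]
    if missing:
        raise ValueError(f"model genes absent from truth: {missing[:5]}")
    cols = np.array([idx[g] for g in model.genes])
    out: dict[str, float] = {}
    for j, cond in enumerate(model.condition_labels):
        true_vec = truth.condition_effects[cond][cols]
        out[cond] = max(_cosine(model.H[j][k], true_vec)
                        for k in range(model.H[j].shape[0]))
    return out
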