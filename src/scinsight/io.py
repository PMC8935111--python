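"""Reading studies from standard on-disk formats and writing factor matrices.

Supported input formats
-----------------------
``mtx``
    A Matrix Market file per sample with ``genes.tsv`` / ``barcodes.tsv``
    next to it (10x convention: genes as matrix rows; transposed on load
    to cells x genes).
``tenx_dir``
    A 10x-style directory containing ``matrix.mtx``, ``genes.tsv`` (or
    ``features.tsv``) and ``barcodes.tsv``.
``csv``
    A dense cells x genes table with a header row of gene names and a
    first column of cell IDs; comma- or tab-separated by extension.

A *manifest* (CSV/TSV with columns ``sample_id``, ``condition_id``,
``path``) lists the samples of a study in order. Cell IDs are namespaced
as ``<sample_id>:<barcode>`` so that barcodes reused across runs stay
globally unique.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .study import SampleMatrix, StudyData

logger = logging.getLogger("scinsight")

_FORMATS = ("mtx", "tenx_dir", "csv")


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _load_mtx_sample(mtx_path: Path) -> tuple[list[str], list[str], np.ndarray]:
    """Load one Matrix Market sample (genes x cells on disk) as cells x genes."""
    genes = _read_lines(mtx_path.parent / "genes.tsv")
    barcodes = _read_lines(mtx_path.parent / "barcodes.tsv")
    mat = scipy.io.mmread(mtx_path)
    if sp.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64).T  # -> cells x genes
    return barcodes, genes, mat


def _load_tenx_dir(dir_path: Path) -> tuple[list[str], list[str], np.ndarray]:
    gene_file = dir_path / "genes.tsv"
    if not gene_file.exists():
        gene_file = dir_path / "features.tsv"
    genes = _read_lines(gene_file)
    barcodes = _read_lines(dir_path / "barcodes.tsv")
    mat = scipy.io.mmread(dir_path / "matrix.mtx")
    if sp.issparse(mat):
        mat = mat.toarray()
    return barcodes, genes, np.asarray(mat, dtype=np.float64).T


def _load_csv(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return [str(c) for c in df.index], [str(g) for g in df.columns], df.to_numpy(np.float64)


def read_study(manifest: str | Path, format: str = "mtx",
               intersect_genes: bool = False) -> StudyData:
    """Read a multi-sample study described by a design-table manifest.

    Parameters
    ----------
    manifest
        CSV/TSV design table with columns ``sample_id``, ``condition_id``
        and ``path`` (matrix location, relative paths resolved against the
        manifest's directory).
    format
        One of ``mtx``, ``tenx_dir``, ``csv``.
    intersect_genes
        If True, samples with differing gene sets are restricted to the
        ordered intersection instead of raising. Off by default: the model
        requires one shared gene list, and silent intersection hides
        upstream mistakes.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    manifest = Path(manifest)
    sep = "\t" if manifest.suffix.lower() in (".tsv", ".txt") else ","
    design = pd.read_csv(manifest, sep=sep)
    required = {"sample_id", "condition_id", "path"}
    if not required.issubset(design.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    loaders = {"mtx": _load_mtx_sample, "tenx_dir": _load_tenx_dir, "csv": _load_csv}
    raw = []
    for row in design.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest.parent / path
        barcodes, genes, values = loaders[format](path)
        raw.append((str(row.sample_id), str(row.condition_id), barcodes, genes, values))

    ref_genes = raw[0][3]
    if intersect_genes:
        shared = set(ref_genes)
        for _, _, _, genes, _ in raw[1:]:
            shared &= set(genes)
        keep = [g for g in ref_genes if g in shared]
        if not keep:
            raise ValueError("gene intersection across samples is empty")
        if len(keep) < len(ref_genes):
            logger.warning("intersect_genes: restricting to %d shared genes", len(keep))
        resolved = []
        for sid, cid, barcodes, genes, values in raw:
            idx = {g: i for i, g in enumerate(genes)}
            cols = np.array([idx[g] for g in keep])
            resolved.append((sid, cid, barcodes, keep, values[:, cols]))
        raw = resolved
    else:
        for sid, _, _, genes, _ in raw[1:]:
            if genes != ref_genes:
                raise ValueError(
                    f"sample '{sid}' has a different gene list than sample "
                    f"'{raw[0][0]}'; pass intersect_genes=True to take the intersection"
                )

    samples = [
        SampleMatrix(sid, cid, [f"{sid}:{b}" for b in barcodes], list(genes), values)
        for sid, cid, barcodes, genes, values in raw
    ]
    return StudyData(samples)


def write_study(study: StudyData, out_dir: str | Path) -> Path:
    """Write a study as per-sample MTX directories plus a ``manifest.csv``.

    Returns the manifest path. The written layout round-trips through
    :func:`read_study` with ``format='mtx'``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in study.samples:
        sdir = out_dir / s.sample_id
        sdir.mkdir(exist_ok=True)
        scipy.io.mmwrite(str(sdir / "matrix.mtx"), sp.csr_matrix(s.values.T))
        (sdir / "genes.tsv").write_text("".join(f"{g}\n" for g in s.genes))
        barcodes = [c.split(":", 1)[1] if c.startswith(f"{s.sample_id}:") else c
                    for c in s.cells]
        (sdir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in barcodes))
        rows.append({"sample_id": s.sample_id, "condition_id": s.condition_id,
                     "path": f"{s.sample_id}/matrix.mtx"})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _write_tsv(path: Path, matrix: np.ndarray, index: list[str], columns: list[str],
               index_name: str) -> None:
    df = pd.DataFrame(matrix, index=index, columns=columns)
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_factors(model, out_dir: str | Path) -> dict[str, str]:
    """Write all factor matrices of a fitted model as headered TSV files.

    Writes ``V.tsv`` (common-module memberships, modules x genes), one
    ``H_<condition>.tsv`` per condition, and ``W1_<sample>.tsv`` /
    ``W2_<sample>.tsv`` per sample (cells x modules), plus
    ``metadata.json`` recording K, K_j, lambda1, lambda2 and the seed.
    Returns a manifest mapping logical names to written file names.
    """
    if not str(out_dir):
        raise ValueError("out_dir must be a non-empty path")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genes = model.genes if model.genes is not None else [
        f"gene{i+1}" for i in range(model.V.shape[1])]
    conditions = model.condition_labels
    sample_ids = model.sample_ids
    cell_ids = model.cell_ids

    manifest: dict[str, str] = {}
    _write_tsv(out_dir / "V.tsv", model.V,
               [f"module{k+1}" for k in range(model.K)], genes, "module")
    manifest["V"] = "V.tsv"
    for j, cond in enumerate(conditions):
        name = f"H_{cond}.tsv"
        _write_tsv(out_dir / name, model.H[j],
                   [f"module{k+1}" for k in range(model.K_j[j])], genes, "module")
        manifest[f"H:{cond}"] = name
    for ell, sid in enumerate(sample_ids):
        cells = cell_ids[ell] if cell_ids is not None else [
            f"{sid}:cell{i+1}" for i in range(model.W2[ell].shape[0])]
        j = model.condition_of[ell]
        name1, name2 = f"W1_{sid}.tsv", f"W2_{sid}.tsv"
        _write_tsv(out_dir / name1, model.W1[ell], cells,
                   [f"module{k+1}" for k in range(model.K_j[j])], "cell")
        _write_tsv(out_dir / name2, model.W2[ell], cells,
                   [f"module{k+1}" for k in range(model.K)], "cell")
        manifest[f"W1:{sid}"] = name1
        manifest[f"W2:{sid}"] = name2

    meta = {"K": int(model.K), "K_j": [int(k) for k in model.K_j],
            "lambda1": float(model.lambda1), "lambda2": float(model.lambda2),
            "seed": model.seed, "conditions": list(conditions),
            "sample_ids": list(sample_ids),
            "condition_of": [int(j) for j in model.condition_of]}
    (out_dir / "metadata.json").write_text(json.dumps(meta, indent=1))
    manifest["metadata"] = "metadata.json"
    return manifest


def read_factor_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a factor matrix written by :func:`write_factors`."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_factors(factor_dir: str | Path):
    """Reassemble a :class:`~scinsight.factorization.FactorModel` from a
    directory written by :func:`write_factors`."""
    from .factorization import FactorModel

    factor_dir = Path(factor_dir)
    meta = json.loads((factor_dir / "metadata.json").read_text())
    V_df = read_factor_tsv(factor_dir / "V.tsv")
    genes = [str(g) for g in V_df.columns]
    conditions = meta["conditions"]
    sample_ids = meta["sample_ids"]
    H = [read_factor_tsv(factor_dir / f"H_{c}.tsv").to_numpy(np.float64)
         for c in conditions]
    W1, W2, cell_ids = [], [], []
    for sid in sample_ids:
        w1 = read_factor_tsv(factor_dir / f"W1_{sid}.tsv")
        w2 = read_factor_tsv(factor_dir / f"W2_{sid}.tsv")
        W1.append(w1.to_numpy(np.float64))
        W2.append(w2.to_numpy(np.float64))
        cell_ids.append([str(c) for c in w2.index])
    condition_of = [int(j) for j in meta["condition_of"]]
    return FactorModel(
        V_df.to_numpy(np.float64), H, W1, W2, int(meta["K"]),
        [int(k) for k in meta["K_j"]], float(meta["lambda1"]),
        float(meta["lambda2"]), condition_of, genes, sample_ids,
        conditions, cell_ids, meta.get("seed"))
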