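"""Readers and writers for the pipeline's plain-text formats.

* Expression matrix: TSV, rows = genes (index column ``gene``), columns =
  sample ids, numeric entries (NaN allowed; correlations use pairwise
  complete samples).
* Clinical table: TSV with columns ``sample_id``, ``time``, ``event`` and an
  optional ``response`` label.
* Cell matrix: MatrixMarket triplet ``matrix.mtx`` (genes x cells) with
  ``genes.tsv`` (one gene per line) and ``barcodes.tsv`` (barcode plus
  ``cell_type`` / ``patient`` / ``response`` annotations); a dense TSV
  alternative is supported.
* DE table: TSV with ``gene``, ``log2fc``, ``pval`` and optional ``padj``.

Validation failures raise :class:`~nrscreen.exceptions.ValidationError` with
the offending identifiers in the message.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .exceptions import ValidationError

__all__ = [
    "read_expression", "write_expression",
    "read_clinical", "write_clinical",
    "read_cells", "write_cells", "read_cells_dense",
    "read_de", "write_de",
    "write_manifest",
]


def _check_unique(index, what: str, where) -> None:
    if index.duplicated().any():
        dupes = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated {what} in {where}: {dupes[:10]}")


def read_expression(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValidationError(f"empty expression matrix: {path}")
    _check_unique(df.index, "gene ids", path)
    _check_unique(df.columns, "sample ids", path)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric expression values in {path}: {exc}") from exc
    df.index.name = "gene"
    return df


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"clinical table {path} lacks columns: {sorted(missing)}")
    df = df.set_index("sample_id")
    _check_unique(df.index, "sample ids", path)
    try:
        df["time"] = df["time"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric survival times in {path}: {exc}") from exc
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0].tolist()
        raise ValidationError(f"non-positive survival times in {path}: {bad[:10]}")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError(f"event flags outside {{0,1}} in {path}")
    df["event"] = df["event"].astype(int)
    if "response" in df.columns:
        labels = set(df["response"].dropna().unique())
        bad = labels - {"responder", "nonresponder"}
        if bad:
            raise ValidationError(f"unknown response labels in {path}: {sorted(bad)}")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")


def write_cells(cells, directory) -> None:
    """Write an AnnData as matrix.mtx (genes x cells) + genes.tsv + barcodes.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = cells.X
    if not hasattr(X, "tocoo"):
        X = csr_matrix(np.asarray(X))
    mmwrite(str(directory / "matrix.mtx"), X.T.tocoo())
    (directory / "genes.tsv").write_text("\n".join(cells.var_names) + "\n")
    obs = cells.obs.copy()
    obs.insert(0, "barcode", cells.obs_names)
    obs.to_csv(directory / "barcodes.tsv", sep="\t", index=False)


def read_cells(directory):
    """Read the MTX triplet layout written by :func:`write_cells` into AnnData."""
    import anndata as ad

    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    try:
        m = mmread(str(mtx))
    except Exception as exc:  # malformed header, out-of-shape coordinate, ...
        raise ValidationError(f"malformed MTX file {mtx}: {exc}") from exc
    genes = [ln for ln in (directory / "genes.tsv").read_text().splitlines() if ln]
    obs = pd.read_csv(directory / "barcodes.tsv", sep="\t")
    required = {"barcode", "cell_type", "patient", "response"}
    missing = required - set(obs.columns)
    if missing:
        raise ValidationError(f"barcodes.tsv lacks columns: {sorted(missing)}")
    if m.shape[0] != len(genes):
        raise ValidationError(
            f"dimension mismatch in {directory}: {m.shape[0]} matrix rows vs "
            f"{len(genes)} genes"
        )
    if m.shape[1] != len(obs):
        raise ValidationError(
            f"dimension mismatch in {directory}: {m.shape[1]} matrix columns vs "
            f"{len(obs)} barcodes"
        )
    gene_index = pd.Index(genes, name="gene")
    _check_unique(gene_index, "gene ids", directory / "genes.tsv")
    obs = obs.set_index("barcode")
    _check_unique(obs.index, "barcodes", directory / "barcodes.tsv")
    return ad.AnnData(X=csr_matrix(m.T), obs=obs, var=pd.DataFrame(index=gene_index))


def read_cells_dense(expression_path, annotations_path):
    """Dense alternative: genes x cells TSV plus a barcode annotation TSV."""
    import anndata as ad

    expr = read_expression(expression_path)
    obs = pd.read_csv(annotations_path, sep="\t")
    required = {"barcode", "cell_type", "patient", "response"}
    missing = required - set(obs.columns)
    if missing:
        raise ValidationError(f"{annotations_path} lacks columns: {sorted(missing)}")
    obs = obs.set_index("barcode")
    _check_unique(obs.index, "barcodes", annotations_path)
    if list(obs.index) != list(expr.columns):
        raise ValidationError(
            "barcode annotations do not match expression columns "
            f"({annotations_path} vs {expression_path})"
        )
    return ad.AnnData(
        X=csr_matrix(expr.to_numpy().T),
        obs=obs,
        var=pd.DataFrame(index=expr.index),
    )


def read_de(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "pval"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"DE table {path} lacks columns: {sorted(missing)}")
    _check_unique(pd.Index(df["gene"]), "gene ids", path)
    for col in ("log2fc", "pval") + (("padj",) if "padj" in df.columns else ()):
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric {col} values in {path}: {exc}") from exc
    for col in ("pval",) + (("padj",) if "padj" in df.columns else ()):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValidationError(f"{col} outside [0,1] in {path}")
    if "padj" in df.columns and (df["padj"] < df["pval"] - 1e-12).any():
        raise ValidationError(f"padj smaller than raw p in {path}")
    return df


def write_de(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_manifest(path, *, seed: int, config: dict, truth_roles: dict,
                   extra: dict | None = None) -> None:
    """Record generator config, seed, and planted truth next to the data."""
    payload = {"seed": seed, "config": config, "truth_roles": truth_roles}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
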