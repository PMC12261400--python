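"""Reading and writing expression matrices, proportions and run configuration.

Expression tables are plain :class:`pandas.DataFrame` objects in the
genes x samples orientation with unique string ids on both axes and no
negative entries. Delimited dialects (TSV default, CSV) carry the sample ids
in the header row and the gene ids in the first column; MatrixMarket
triplets use two sidecar id lists (``<stem>.genes.txt``,
``<stem>.samples.txt``).

Also implements the cross-platform gene-wise bulk re-scaling: per-gene
factors equal to the mean expression in the single-cell training
pseudo-bulks divided by the mean expression in a set of control bulks, so
that applying them to the controls equalizes gene means with the training
data.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("hideconv")

__all__ = [
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "validate_expression",
    "compute_rescale_factors",
    "apply_rescale",
    "load_config",
]


class MatrixFormatError(ValueError):
    """Malformed expression matrix file or invalid matrix content."""


_SEPARATORS = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "txt"):
        return "tsv"
    if suffix == "csv":
        return "csv"
    if suffix == "mtx":
        return "mtx"
    raise MatrixFormatError(f"cannot infer format from {path.name!r}; pass format=")


def validate_expression(table: pd.DataFrame, *, where: str = "matrix") -> pd.DataFrame:
    """Check the expression-table contract; returns the table unchanged."""
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise MatrixFormatError(f"{where}: duplicate gene id {dup!r}")
    if table.columns.has_duplicates:
        dup = table.columns[table.columns.duplicated()][0]
        raise MatrixFormatError(f"{where}: duplicate sample id {dup!r}")
    values = table.to_numpy()
    if not np.isfinite(values).all():
        raise MatrixFormatError(f"{where}: non-finite entries")
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise MatrixFormatError(
            f"{where}: negative value for gene {table.index[g]!r}, "
            f"sample {table.columns[s]!r}"
        )
    return table


def read_matrix(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a genes x samples expression table (``tsv``, ``csv`` or ``mtx``)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt in _SEPARATORS:
        try:
            table = pd.read_csv(
                path, sep=_SEPARATORS[fmt], index_col=0, float_precision="round_trip"
            )
        except pd.errors.ParserError as err:  # ragged rows etc.; pandas names the line
            raise MatrixFormatError(f"{path.name}: {err}") from err
        table.index = table.index.astype(str)
        table.columns = table.columns.astype(str)
    elif fmt == "mtx":
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().splitlines()
        samples = Path(f"{stem}.samples.txt").read_text().splitlines()
        values = np.asarray(scipy.io.mmread(path).todense(), dtype=float)
        if values.shape != (len(genes), len(samples)):
            raise MatrixFormatError(
                f"{path.name}: triplet shape {values.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        table = pd.DataFrame(values, index=genes, columns=samples)
    else:
        raise MatrixFormatError(f"unknown format {fmt!r}")
    return validate_expression(table.astype(float), where=path.name)


def write_matrix(table: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write a genes x samples table; delimited dialects round-trip bit-identically."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt in _SEPARATORS:
        # Default pandas float formatting is shortest round-trip repr.
        table.to_csv(path, sep=_SEPARATORS[fmt])
    elif fmt == "mtx":
        stem = path.with_suffix("")
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(table.to_numpy()))
        Path(f"{stem}.genes.txt").write_text("\n".join(map(str, table.index)) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(map(str, table.columns)) + "\n")
    else:
        raise MatrixFormatError(f"unknown format {fmt!r}")


def compute_rescale_factors(
    train_pseudobulks: pd.DataFrame, control_bulks: pd.DataFrame
) -> pd.Series:
    """Per-gene factors: mean expression in training pseudo-bulks / mean in controls.

    Restricted to the gene ids shared by both tables (exact string match).
    Genes whose control mean is zero get factor 1.0 and are logged, keeping
    the gene instead of injecting infinities.
    """
    shared = [g for g in train_pseudobulks.index if g in set(control_bulks.index)]
    if not shared:
        raise MatrixFormatError("no shared genes between training and control bulks")
    mean_train = train_pseudobulks.loc[shared].mean(axis=1)
    mean_control = control_bulks.loc[shared].mean(axis=1)
    zero = (mean_control.to_numpy() == 0) | (mean_train.to_numpy() == 0)
    if zero.any():
        flagged = list(mean_train.index[zero][:20])
        logger.warning(
            "%d gene(s) have a zero train or control mean; factor set to 1.0 (e.g. %s)",
            int(zero.sum()),
            flagged,
        )
    factors = np.where(zero, 1.0, mean_train.to_numpy() / np.where(zero, 1.0, mean_control.to_numpy()))
    factors = pd.Series(factors, index=mean_train.index, name="factor")
    if not np.isfinite(factors.to_numpy()).all() or (factors.to_numpy() <= 0).any():
        bad = factors.index[~np.isfinite(factors.to_numpy()) | (factors.to_numpy() <= 0)][0]
        raise MatrixFormatError(f"non-positive or non-finite rescale factor for gene {bad!r}")
    return factors


def apply_rescale(bulks: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Multiply each gene row by its factor; genes without a factor are dropped."""
    keep = [g for g in factors.index if g in set(bulks.index)]
    return bulks.loc[keep].mul(factors.loc[keep], axis=0)


def load_config(path: str | Path) -> dict:
    """Read a YAML/JSON key-value configuration file."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
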