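"""Readers/writers for the tab-separated formats the pipeline touches.

Conventions
-----------
* Expression matrices are :class:`pandas.DataFrame` objects with gene
  identifiers on the row index and sample identifiers on the columns;
  values are log-scale (and typically z-scored) expression.
* Sample annotations are a DataFrame indexed by ``sample_id`` with a
  ``response`` column holding ``CR`` (chemo-sensitive) or ``NOCR``
  (chemo-resistant), plus optional ``subtype``, ``cohort`` and
  ``dss_years`` columns.
* Pathway collections are ``dict[str, set[str]]`` (GMT files).
* Interaction tables are ``set[tuple[str, str]]`` of unordered,
  lexicographically sorted gene pairs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError, InputError

logger = logging.getLogger(__name__)

#: Tokens treated as missing values in expression matrices.
MISSING_TOKENS = {"", "NA", "NaN", "nan", "null", "NULL"}

RESPONSE_VALUES = {"CR", "NOCR", ""}


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples TSV (first row sample ids, first column gene ids).

    Rows containing missing entries are dropped (count logged); duplicate
    gene rows are collapsed by their mean (warning logged).  A non-numeric,
    non-missing cell raises :class:`DataFormatError` naming the gene and
    sample.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty expression file") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise InputError(f"{path}: expression file has no data rows/columns")
    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].tolist()
        raise DataFormatError(f"{path}: duplicate sample ids {dups}")

    num = raw.apply(lambda col: pd.to_numeric(col.str.strip(), errors="coerce"))
    missing = raw.apply(lambda col: col.str.strip().isin(MISSING_TOKENS))
    bad = num.isna() & ~missing
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at gene "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )

    has_missing = missing.any(axis=1)
    if has_missing.any():
        logger.info("%s: dropped %d gene rows with missing entries", path, int(has_missing.sum()))
        num = num.loc[~has_missing]
    if num.shape[0] == 0:
        raise InputError(f"{path}: no complete gene rows after dropping missing entries")

    if num.index.duplicated().any():
        n_dup = int(num.index.duplicated().sum())
        logger.warning("%s: collapsed %d duplicate gene rows by mean", path, n_dup)
        num = num.groupby(level=0, sort=False).mean()

    num.index.name = "gene_id"
    return num.astype(float)


def write_expression_matrix(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", index_label="gene_id")


def zscore_normalize(m: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score each gene row across all samples (sample sd, ``n-1`` denominator).

    Genes with zero standard deviation are dropped; their count is logged.
    """
    if m.shape[1] < 2:
        raise InputError("z-scoring requires at least 2 samples")
    mu = m.mean(axis=1)
    sd = m.std(axis=1, ddof=ddof)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("z-score: dropped %d zero-variance genes", n_dropped)
    z = m.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return z


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation TSV (columns sample_id, response[, subtype, cohort, dss_years])."""
    path = Path(path)
    try:
        ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty annotation file") from exc
    for col in ("sample_id", "response"):
        if col not in ann.columns:
            raise DataFormatError(f"{path}: missing required column {col!r}")
    if ann["sample_id"].duplicated().any():
        dups = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataFormatError(f"{path}: duplicate sample ids {dups}")
    bad = sorted(set(ann["response"]) - RESPONSE_VALUES)
    if bad:
        raise DataFormatError(f"{path}: invalid response values {bad}; expected CR or NOCR")
    ann = ann.set_index("sample_id")
    if "dss_years" in ann.columns:
        dss = pd.to_numeric(ann["dss_years"].replace("", np.nan), errors="coerce")
        ann["dss_years"] = dss
    return ann


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name, description, then tab-separated gene ids per line."""
    path = Path(path)
    pathways: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataFormatError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name = parts[0]
            if name in pathways:
                raise DataFormatError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            genes = {g.strip() for g in parts[2:] if g.strip()}
            if not genes:
                raise DataFormatError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            pathways[name] = genes
    if not pathways:
        raise InputError(f"{path}: empty gene-set file")
    return pathways


def write_gene_sets(pathways: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in pathways:
            genes = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_interactions(path: str | Path, header: bool = False) -> set[tuple[str, str]]:
    """Read a two-column TSV of gene pairs into an undirected edge set.

    Self-loops are removed and duplicates (either orientation) collapsed.
    An empty file yields an empty edge set.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno == 1 and header:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataFormatError(f"{path}: line {lineno}: expected exactly 2 fields")
            a, b = parts[0].strip(), parts[1].strip()
            if not a or not b:
                raise DataFormatError(f"{path}: line {lineno}: empty gene id")
            if a == b:
                n_self += 1
                continue
            edges.add((a, b) if a < b else (b, a))
    if n_self:
        logger.info("%s: removed %d self-loop(s)", path, n_self)
    return edges


def write_interactions(edges: set[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")
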