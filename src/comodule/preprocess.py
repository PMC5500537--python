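"""Loading and preparing expression data for network construction.

Covers reading plain TSV and GEO series-matrix dialects, collapsing
multiple probes per gene, the two-stage gene filter (mean in the top
half, then above-average variance among the survivors), and flagging
outlier samples by hierarchical average-linkage clustering.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

DIALECTS = ("tsv", "geo_series_matrix")


class ExpressionError(ValueError):
    """Malformed or degenerate expression input."""


def read_expression(
    path: str | Path,
    dialect: str = "tsv",
    *,
    impute_missing: bool = False,
) -> pd.DataFrame:
    """Read a genes x samples log2 expression matrix.

    ``geo_series_matrix`` strips the "!"-prefixed metadata lines and the
    series-matrix table delimiters, yielding the same matrix as the plain
    TSV twin.  Missing values are rejected unless ``impute_missing`` is
    set, in which case each gene's mean fills its gaps.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    if dialect == "geo_series_matrix":
        lines = [
            ln
            for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("!")
        ]
        if not lines:
            raise ExpressionError(f"{path}: no table found in series-matrix file")
        from io import StringIO

        df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=0)
        df.columns = [str(c).strip('"') for c in df.columns]
        df.index = [str(i).strip('"') for i in df.index]
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)

    if df.empty:
        raise ExpressionError(f"{path}: empty expression matrix")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ExpressionError(f"{path}: duplicate sample IDs {dupes}")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ExpressionError(
            f"{path}: duplicate gene/probe row IDs {dupes}; supply a probe map "
            "and collapse instead"
        )
    try:
        df = df.astype(float)
    except ValueError as exc:  # ragged rows surface as non-numeric cells
        raise ExpressionError(f"{path}: non-numeric or ragged rows ({exc})") from exc
    if df.isna().any().any():
        if impute_missing:
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
        else:
            n_missing = int(df.isna().sum().sum())
            raise ExpressionError(
                f"{path}: {n_missing} missing values (set impute_missing to fill "
                "with per-gene means)"
            )
    df.index.name = "gene"
    return df


def read_trait(path: str | Path) -> pd.Series:
    """Read a two-column (sample, code) trait table with a 0/1 code."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    code = df.iloc[:, 0].astype(int)
    if not set(code.unique()) <= {0, 1}:
        raise ValueError(f"{path}: trait codes must be 0 (mild) or 1 (advanced)")
    code.name = "code"
    return code


def read_probe_map(path: str | Path) -> pd.Series:
    """Read a two-column (probe, gene) TSV into a probe -> gene Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(str)


def collapse_probes(expr: pd.DataFrame, probe_map: pd.Series | dict) -> pd.DataFrame:
    """Collapse probes to genes, keeping the probe with highest mean expression.

    Unmapped probes are dropped (with a logged count).  Ties on the mean
    break toward the lexicographically first probe ID.
    """
    probe_map = pd.Series(probe_map)
    mapped = expr.index.intersection(probe_map.index)
    if mapped.empty:
        raise ExpressionError("no expression rows are covered by the probe map")
    n_dropped = expr.shape[0] - mapped.size
    if n_dropped:
        logger.info("collapse_probes: dropping %d unmapped probe rows", n_dropped)

    sub = expr.loc[mapped]
    means = sub.mean(axis=1)
    frame = pd.DataFrame(
        {"gene": probe_map.loc[mapped].to_numpy(), "mean": means.to_numpy()},
        index=mapped,
    )
    # highest mean first, lexicographically-smallest probe ID on ties
    frame = frame.iloc[
        np.lexsort((np.asarray(frame.index, dtype=str), -frame["mean"].to_numpy()))
    ]
    keep = frame.drop_duplicates("gene", keep="first")
    out = sub.loc[keep.index]
    out.index = keep["gene"].to_numpy()
    out.index.name = "gene"
    return out.sort_index()


def filter_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Two-stage filter: mean in the top half, then above-average variance.

    Keeps genes whose mean is >= the median gene mean; among those keeps
    genes with variance strictly greater than the survivors' mean
    variance.  If the strict variance filter removes everything (all
    variances equal), the mean-filter survivors are kept and a warning is
    logged.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ExpressionError("filter_genes requires >= 2 genes and >= 2 samples")
    means = expr.mean(axis=1)
    survivors = expr.loc[means >= means.median()]
    if survivors.empty:
        raise ExpressionError("mean filter removed every gene")
    variances = survivors.var(axis=1, ddof=1)
    kept = survivors.loc[variances > variances.mean()]
    if kept.empty:
        logger.warning(
            "variance filter removed every gene (all variances equal?); "
            "keeping all %d mean-filter survivors",
            survivors.shape[0],
        )
        return survivors
    return kept


def detect_outlier_samples(expr: pd.DataFrame, cut_z: float = 2.5) -> list[str]:
    """Flag outlier samples by average-linkage clustering of standardised data.

    Samples are clustered on Euclidean distance of per-gene standardised
    expression; a sample is flagged when the height at which it (as a
    singleton leaf) joins the tree exceeds mean + ``cut_z`` * sd of all
    merge heights.  Returns the flagged sample IDs (possibly empty).
    """
    n = expr.shape[1]
    if n < 3:
        raise ExpressionError("outlier detection requires >= 3 samples")
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd
    d = pdist(z.T, metric="euclidean")
    merges = linkage(d, method="average")
    heights = merges[:, 2]
    cutoff = heights.mean() + cut_z * heights.std(ddof=1)

    leaf_height = np.full(n, np.nan)
    for a, b, h, _ in merges:
        for child in (int(a), int(b)):
            if child < n:
                leaf_height[child] = h
    flagged = [
        expr.columns[i] for i in range(n) if leaf_height[i] > cutoff
    ]
    return flagged
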