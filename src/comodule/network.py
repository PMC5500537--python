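"""Weighted co-expression network construction.

Pearson correlation -> soft-thresholded adjacency -> topological overlap
matrix (TOM).  The soft-threshold power beta is chosen as the smallest
power whose network degree distribution satisfies the scale-free
topology criterion (signed R^2 of the log-log degree regression above a
cut, 0.9 by default).

Unsigned networks (a_ij = |r_ij|^beta) are the default; signed networks
(a_ij = ((1 + r_ij)/2)^beta) are available via ``network_type``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

NETWORK_TYPES = ("unsigned", "signed")


class ConstantGeneError(ValueError):
    """A gene with zero variance cannot enter a correlation network."""


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of genes across samples.

    Symmetric with unit diagonal; constant genes are rejected by name.
    """
    if expr.shape[1] < 3:
        raise ValueError("correlation needs >= 3 samples")
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0].tolist()
        raise ConstantGeneError(f"constant gene(s): {bad[:10]}")
    cor = np.corrcoef(vals)
    cor = np.clip((cor + cor.T) / 2, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def adjacency(
    cor: pd.DataFrame, beta: int, network_type: str = "unsigned"
) -> pd.DataFrame:
    """Soft-thresholded adjacency from a correlation matrix."""
    if network_type not in NETWORK_TYPES:
        raise ValueError(f"network_type must be one of {NETWORK_TYPES}")
    if not float(beta).is_integer() or beta < 1:
        raise ValueError("beta must be an integer >= 1")
    beta = int(beta)
    if network_type == "signed":
        a = ((1.0 + cor.to_numpy()) / 2.0) ** beta
    else:
        a = np.abs(cor.to_numpy()) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    a = adj.to_numpy()
    k = a.sum(axis=1) - np.diag(a)
    return pd.Series(k, index=adj.index, name="k")


@dataclass(frozen=True)
class ScaleFreeFit:
    """Scale-free topology fit of one adjacency matrix."""

    power: int
    r_squared_signed: float
    slope: float
    mean_connectivity: float


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10, power: int = 0) -> ScaleFreeFit:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned into ``n_bins`` equal-width bins; the log10
    bin frequency is regressed on the log10 bin-mean connectivity over
    non-empty bins.  The fit index is -sign(slope) * R^2, so only
    decaying degree distributions score positively.
    """
    k = connectivity(adj).to_numpy()
    if np.allclose(k, k[0]):
        raise ValueError("degenerate degree distribution: all connectivities equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    nonempty = freq > 0
    if nonempty.sum() < 2:
        raise ValueError("fewer than 2 non-empty connectivity bins")
    bin_mean_k = np.array(
        [k[which == b].mean() if freq[b] else np.nan for b in range(n_bins)]
    )
    x = np.log10(bin_mean_k[nonempty])
    y = np.log10(freq[nonempty] / k.size)
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    return ScaleFreeFit(
        power=int(power),
        r_squared_signed=float(-np.sign(fit.slope) * r2),
        slope=float(fit.slope),
        mean_connectivity=float(k.mean()),
    )


@dataclass(frozen=True)
class SoftThresholdResult:
    beta: int
    table: pd.DataFrame  # per-power fit statistics
    reached_cut: bool  # False -> fell back to the max-R^2 power


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers=tuple(range(1, 21)),
    fit_cut: float = 0.9,
    n_bins: int = 10,
    network_type: str = "unsigned",
    cor: pd.DataFrame | None = None,
) -> SoftThresholdResult:
    """Choose the smallest power meeting the scale-free criterion.

    If no power reaches ``fit_cut``, the power maximising the signed R^2
    is returned with ``reached_cut=False``.  A precomputed correlation
    matrix can be passed to avoid recomputation.
    """
    powers = list(powers)
    if not powers or sorted(powers) != powers:
        raise ValueError("powers must be a nonempty ascending sequence")
    if cor is None:
        cor = correlation_matrix(expr)
    rows = []
    for p in powers:
        adj = adjacency(cor, p, network_type)
        fit = scale_free_fit(adj, n_bins=n_bins, power=p)
        rows.append(
            {
                "power": p,
                "r_squared_signed": fit.r_squared_signed,
                "slope": fit.slope,
                "mean_connectivity": fit.mean_connectivity,
            }
        )
    table = pd.DataFrame(rows).set_index("power")
    qualifying = table.index[table["r_squared_signed"] >= fit_cut]
    if len(qualifying):
        return SoftThresholdResult(int(qualifying[0]), table, True)
    best = int(table["r_squared_signed"].idxmax())
    return SoftThresholdResult(best, table, False)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu * a_uj and unit diagonal.  Off-diagonal
    entries combine the direct connection strength with the weight of
    shared neighbours.
    """
    a = np.array(adj.to_numpy(dtype=float), copy=True)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 1.0)
    # with unit diagonal, (A @ A)_ij counts u = i and u = j as a_ij each
    l = a @ a - 2.0 * a  # noqa: E741
    k = a.sum(axis=1) - np.diag(a)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2, 0.0, 1.0)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def tom_dissimilarity(tom_matrix: pd.DataFrame) -> pd.DataFrame:
    """Clustering dissimilarity d = 1 - TOM (zero diagonal)."""
    d = 1.0 - tom_matrix.to_numpy()
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=tom_matrix.index, columns=tom_matrix.columns)
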