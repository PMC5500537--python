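"""Relating genes and modules to the sample trait.

Gene significance (GS) is the signed Pearson correlation of a gene with
the binary severity code (point-biserial).  Modules are related to the
trait through their eigengenes; module significance is the mean |GS| of
a module's genes.  Hub genes combine high GS, high module membership
(kME) and high intramodular connectivity (K.in).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree

from .palette import GREY


def _corr_with_vector(mat: pd.DataFrame, vec: np.ndarray) -> np.ndarray:
    x = mat.to_numpy(dtype=float)
    xz = x - x.mean(axis=1, keepdims=True)
    vz = vec - vec.mean()
    denom = np.sqrt((xz**2).sum(axis=1) * (vz**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = xz @ vz / denom
    return np.clip(r, -1.0, 1.0)


def correlation_p_value(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation via the Student-t transform."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def gene_significance(expr: pd.DataFrame, trait: pd.Series) -> pd.Series:
    """Signed Pearson correlation of each gene with the 0/1 trait."""
    trait = trait.loc[expr.columns]
    gs = _corr_with_vector(expr, trait.to_numpy(dtype=float))
    return pd.Series(gs, index=expr.index, name="GS")


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: pd.Series
) -> pd.DataFrame:
    """Eigengene-trait Pearson r with two-sided t-based p per module."""
    me = eigengenes
    trait = trait.loc[me.columns]
    r = _corr_with_vector(me, trait.to_numpy(dtype=float))
    p = correlation_p_value(r, me.shape[1])
    return pd.DataFrame({"correlation": r, "p_value": p}, index=me.index)


def module_significance(gs: pd.Series, assignment: pd.Series) -> pd.Series:
    """Mean |GS| per module (grey included as its own row)."""
    return (
        gs.abs().groupby(assignment).mean().rename("module_significance")
    )


def meta_modules(
    eigengenes: pd.DataFrame,
    trait: pd.Series | None = None,
    cor_cut: float = 0.5,
) -> tuple[pd.Series, np.ndarray, pd.DataFrame]:
    """Group modules whose eigengenes are mutually correlated above a cut.

    The trait (standardised) is appended as a pseudo-eigengene; the
    eigengenes are clustered by average linkage on 1 - cor, and
    meta-modules are the maximal subtrees whose internal pairwise
    correlations all exceed ``cor_cut``.

    Returns (label -> meta-module id, linkage matrix, eigengene
    correlation matrix).
    """
    me = eigengenes.copy()
    if trait is not None:
        t = trait.loc[me.columns].astype(float)
        me.loc["trait"] = (t - t.mean()) / t.std(ddof=1)
    if me.shape[0] < 2:
        raise ValueError("meta-modules need at least 2 eigengenes")
    cor = pd.DataFrame(
        np.corrcoef(me.to_numpy()), index=me.index, columns=me.index
    )
    d = 1.0 - cor.to_numpy()
    np.fill_diagonal(d, 0.0)
    from scipy.spatial.distance import squareform

    merges = linkage(squareform(d, checks=False), method="average")

    labels = list(me.index)
    c = cor.to_numpy()
    groups = np.full(len(labels), -1)
    next_group = 0

    def assign(node):
        nonlocal next_group
        leaves = node.pre_order(lambda leaf: leaf.id)
        sub = c[np.ix_(leaves, leaves)]
        iu = np.triu_indices(len(leaves), k=1)
        if len(leaves) == 1 or (sub[iu] > cor_cut).all():
            groups[leaves] = next_group
            next_group += 1
        else:
            assign(node.left)
            assign(node.right)

    assign(to_tree(merges))
    grouping = pd.Series(groups, index=labels, name="meta_module")
    return grouping, merges, cor


def intramodular_connectivity(
    adjacency: pd.DataFrame, assignment: pd.Series
) -> pd.Series:
    """K.in(i) = sum of adjacency from gene i to other genes of its module.

    Grey genes get K.in over the grey set — reported, but not a
    meaningful connectivity.
    """
    kin = pd.Series(0.0, index=assignment.index, name="K.in")
    a = adjacency
    for module, genes in assignment.groupby(assignment).groups.items():
        genes = a.index.intersection(genes)
        sub = a.loc[genes, genes].to_numpy()
        kin.loc[genes] = sub.sum(axis=1) - np.diag(sub)
    return kin


def gene_network_stats(
    expr: pd.DataFrame,
    trait: pd.Series,
    adjacency: pd.DataFrame,
    assignment: pd.Series,
    kme_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene feature table: GS, MM (own-module kME), K.in, module, ranks.

    Ranks are 1-based dense within each module, ranking GS and K.in in
    decreasing order (rank 1 = highest).
    """
    gs = gene_significance(expr, trait)
    kin = intramodular_connectivity(adjacency, assignment)
    mm = pd.Series(
        [
            kme_matrix.at[g, m] if m in kme_matrix.columns else np.nan
            for g, m in assignment.items()
        ],
        index=assignment.index,
        name="MM",
    )
    df = pd.DataFrame(
        {"module": assignment, "GS": gs, "MM": mm, "K.in": kin}
    )
    df["GS_rank"] = (
        df.groupby("module")["GS"].rank(ascending=False, method="dense").astype(int)
    )
    df["K.in_rank"] = (
        df.groupby("module")["K.in"].rank(ascending=False, method="dense").astype(int)
    )
    return df


def gs_mm_kin_correlations(
    stats_table: pd.DataFrame, module: str, absolute: bool = False
) -> dict[str, float]:
    """Within-module correlation of GS with MM and of GS with K.in.

    Signed GS/MM by default; ``absolute`` correlates |GS| with |MM| (and
    |GS| with K.in) instead.
    """
    sub = stats_table[stats_table["module"] == module]
    if sub.empty:
        raise ValueError(f"no genes in module {module!r}")
    gs = sub["GS"].abs() if absolute else sub["GS"]
    mm = sub["MM"].abs() if absolute else sub["MM"]
    kin = sub["K.in"]
    out = {}
    for name, x, y in (("GS_MM", gs, mm), ("GS_Kin", gs, kin)):
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"zero variance in {name} inputs for {module!r}")
        r = float(np.corrcoef(x, y)[0, 1])
        out[f"r_{name}"] = r
        out[f"p_{name}"] = float(correlation_p_value(np.array([r]), len(sub))[0])
    return out


def hub_genes(
    stats_table: pd.DataFrame, module: str, top_n: int = 10
) -> pd.DataFrame:
    """Top genes of a module by K.in and by GS, with consensus flags.

    Ties in K.in break by GS, then by gene ID.  The returned table holds
    the union of both top lists with GS, GS rank, K.in, K.in rank, the
    ranking(s) that selected each gene, and a consensus flag for genes
    in both top lists.
    """
    sub = stats_table[stats_table["module"] == module].copy()
    if sub.empty:
        raise ValueError(f"no genes in module {module!r}")
    ids = np.asarray(sub.index, dtype=str)
    by_kin = sub.iloc[
        np.lexsort((ids, -sub["GS"].to_numpy(), -sub["K.in"].to_numpy()))
    ]
    by_gs = sub.iloc[
        np.lexsort((ids, -sub["K.in"].to_numpy(), -sub["GS"].to_numpy()))
    ]
    top_kin = list(by_kin.index[:top_n])
    top_gs = list(by_gs.index[:top_n])
    consensus = set(top_kin) & set(top_gs)
    keep = list(dict.fromkeys(top_kin + top_gs))
    out = sub.loc[keep, ["GS", "GS_rank", "K.in", "K.in_rank"]].copy()
    out["in_top_kin"] = out.index.isin(top_kin)
    out["in_top_gs"] = out.index.isin(top_gs)
    out["consensus_hub"] = out.index.isin(consensus)
    return out


def export_edge_list(
    tom_matrix: pd.DataFrame,
    assignment: pd.Series,
    module: str,
    tom_cut: float = 0.1,
    node_attributes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Cytoscape-style edge list of a module's TOM graph.

    Emits each within-module pair once (gene1 < gene2 lexicographically)
    with TOM weight >= ``tom_cut``.  ``node_attributes`` (e.g. log2 fold
    change and DEG q-value for styling) is subset to the module's genes.
    """
    genes = sorted(assignment.index[assignment == module])
    sub = tom_matrix.loc[genes, genes].to_numpy()
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            w = sub[i, j]
            if w >= tom_cut:
                rows.append({"source": genes[i], "target": genes[j], "weight": w})
    edges = pd.DataFrame(rows, columns=["source", "target", "weight"])
    nodes = None
    if node_attributes is not None:
        nodes = node_attributes.loc[node_attributes.index.intersection(genes)].copy()
    return edges, nodes
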