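"""Module detection on the TOM dendrogram.

Genes are clustered by average linkage on 1 - TOM; modules are cut out
of the dendrogram with a simplified hybrid dynamic tree cut (adaptive
static cut, minimum branch size, a core-scatter branch quality test
keyed to ``deep_split``, and an optional PAM-like assignment of loose
genes).  Modules are named by decreasing size through the conventional
colour palette, represented by their eigengene (first principal
component of the standardised module expression), and pruned by the
|kME| membership rule: genes weakly correlated with their own module
eigengene are returned to grey.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .palette import GREY, palette_color

# core-scatter stringency per deep_split level (fraction of the height
# range below the cut that a branch's mean internal dissimilarity may
# occupy; looser values split deeper)
_MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


def hierarchical_cluster(dissimilarity: pd.DataFrame) -> np.ndarray:
    """Average-linkage merge tree on a symmetric zero-diagonal dissimilarity."""
    d = dissimilarity.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("dissimilarity must have a zero diagonal")
    condensed = squareform(d, checks=False)
    return linkage(condensed, method="average")


def dynamic_tree_cut(
    merges: np.ndarray,
    dissimilarity: pd.DataFrame,
    min_cluster_size: int = 30,
    deep_split: int = 2,
    cut_height: float | None = None,
    pam_stage: bool = False,
) -> pd.Series:
    """Cut the dendrogram into modules; undersized or loose branches go grey.

    The static cut height defaults to 99% of the span between the 5th
    percentile and the maximum of the merge heights.  A flat cluster
    becomes a module when it has at least ``min_cluster_size`` members
    and its mean internal dissimilarity stays below a ``deep_split``-
    dependent fraction of that span (branches as diffuse as the cut
    itself are background, not modules).  With ``pam_stage`` set, grey
    genes closer (in average dissimilarity) to some module than that
    module's own radius are pulled in.

    Returns gene -> provisional label ("c1", "c2", ..., or "grey").
    """
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    genes = dissimilarity.index
    d = dissimilarity.to_numpy(dtype=float)
    heights = merges[:, 2]
    h_max = heights.max()
    h_lo = np.percentile(heights, 5)
    if cut_height is None:
        cut_height = h_lo + 0.99 * (h_max - h_lo)
    scatter_cap = h_lo + _MAX_CORE_SCATTER[deep_split] * (cut_height - h_lo)

    flat = fcluster(merges, t=cut_height, criterion="distance")
    labels = np.full(len(genes), GREY, dtype=object)
    next_id = 1
    for cl in np.unique(flat):
        members = np.flatnonzero(flat == cl)
        if members.size < min_cluster_size:
            continue
        sub = d[np.ix_(members, members)]
        m = members.size
        core_scatter = sub.sum() / (m * (m - 1))
        if core_scatter > scatter_cap:
            continue
        labels[members] = f"c{next_id}"
        next_id += 1

    if pam_stage and next_id > 1:
        module_names = [f"c{i}" for i in range(1, next_id)]
        idx_by_mod = {name: np.flatnonzero(labels == name) for name in module_names}
        radius = {}
        for name, idx in idx_by_mod.items():
            sub = d[np.ix_(idx, idx)]
            # a member's average dissimilarity to its own module
            per_gene = sub.sum(axis=1) / (idx.size - 1)
            radius[name] = per_gene.max()
        for g in np.flatnonzero(labels == GREY):
            avg = {
                name: d[g, idx].mean() for name, idx in idx_by_mod.items()
            }
            best = min(avg, key=avg.get)
            if avg[best] <= radius[best]:
                labels[g] = best

    return pd.Series(labels, index=genes, name="module")


def label_modules(assignment: pd.Series) -> pd.Series:
    """Rename modules by decreasing size through the colour palette.

    Ties on size give the earlier colour to the module containing the
    lexicographically smallest gene ID; "grey" is never reassigned.
    """
    sizes = assignment[assignment != GREY].value_counts()
    order = sorted(
        sizes.index,
        key=lambda m: (-sizes[m], min(assignment.index[assignment == m])),
    )
    mapping = {m: palette_color(i) for i, m in enumerate(order)}
    mapping[GREY] = GREY
    return assignment.map(mapping).rename("module")


@dataclass
class Eigengenes:
    """Module eigengenes (first PCs) and their explained-variance shares."""

    values: pd.DataFrame  # module x sample, unit variance
    var_explained: pd.Series  # module -> proportion of variance explained

    @property
    def modules(self) -> list[str]:
        return list(self.values.index)


def _standardize_rows(vals: np.ndarray) -> np.ndarray:
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant gene in module")
    return (vals - mean) / sd


def module_eigengene(
    expr: pd.DataFrame, assignment: pd.Series, include_grey: bool = False
) -> Eigengenes:
    """First principal component of each module's standardised expression.

    Eigengenes are standardised to unit variance and oriented so the
    mean correlation of the module's genes with the eigengene is
    positive (exact-zero ties break toward the first gene positive).
    """
    modules = [m for m in assignment.unique() if include_grey or m != GREY]
    if not modules:
        raise ValueError("no modules to summarise")
    n = expr.shape[1]
    rows = {}
    var_exp = {}
    for m in sorted(modules):
        genes = assignment.index[assignment == m]
        z = _standardize_rows(expr.loc[genes].to_numpy(dtype=float))
        # right singular vector of the standardised genes x samples block
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        scores = vt[0]
        scores = scores / scores.std(ddof=1)
        kme_own = z @ scores / ((n - 1) * 1.0)  # genes are unit variance
        orient = np.sign(kme_own.mean())
        if orient == 0:
            orient = np.sign(kme_own[0]) or 1.0
        rows[m] = orient * scores
        var_exp[m] = float(s[0] ** 2 / (s**2).sum())
    values = pd.DataFrame(rows, index=expr.columns).T
    return Eigengenes(values=values, var_explained=pd.Series(var_exp))


def kme(expr: pd.DataFrame, eigengenes: Eigengenes | pd.DataFrame) -> pd.DataFrame:
    """Gene x module matrix of gene-eigengene Pearson correlations."""
    me = eigengenes.values if isinstance(eigengenes, Eigengenes) else eigengenes
    x = expr.to_numpy(dtype=float)
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    e = me.to_numpy(dtype=float)
    ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, keepdims=True)
    r = xz @ ez.T / x.shape[1]
    return pd.DataFrame(
        np.clip(r, -1.0, 1.0), index=expr.index, columns=me.index
    )


def reassign_grey(
    assignment: pd.Series, kme_matrix: pd.DataFrame, threshold: float = 0.7
) -> pd.Series:
    """Return to grey every gene with own-module |kME| below ``threshold``.

    Single pass: eigengenes are not recomputed afterwards.  A gene whose
    |kME| equals the threshold exactly is retained.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    out = assignment.copy()
    for gene, module in assignment.items():
        if module == GREY:
            continue
        if abs(kme_matrix.at[gene, module]) < threshold:
            out[gene] = GREY
    return out


def detect_modules(
    expr: pd.DataFrame,
    dissimilarity: pd.DataFrame,
    min_cluster_size: int = 30,
    deep_split: int = 2,
    kme_threshold: float = 0.7,
    pam_stage: bool = False,
):
    """Cluster -> cut -> label -> eigengenes -> kME -> grey rule.

    Returns (initial_assignment, final_assignment, eigengenes, kme_matrix).
    The initial assignment is the size-ordered labelling straight from
    the tree cut; the final one additionally applies the |kME| rule.
    """
    merges = hierarchical_cluster(dissimilarity)
    raw = dynamic_tree_cut(
        merges,
        dissimilarity,
        min_cluster_size=min_cluster_size,
        deep_split=deep_split,
        pam_stage=pam_stage,
    )
    initial = label_modules(raw)
    if (initial == GREY).all():
        return initial, initial, None, None
    egs = module_eigengene(expr, initial)
    km = kme(expr, egs)
    final = reassign_grey(initial, km, threshold=kme_threshold)
    return initial, final, egs, km


def module_stability(
    expr: pd.DataFrame,
    reference: pd.Series,
    beta: int,
    n_resamples: int = 20,
    fraction: float = 1.0,
    seed: int | None = None,
    min_cluster_size: int = 30,
    deep_split: int = 2,
    network_type: str = "unsigned",
) -> pd.DataFrame:
    """Stability of module detection under sample resampling.

    Each resample draws ``fraction`` * n samples with replacement,
    re-runs network construction at the fixed ``beta`` and module
    detection, and scores agreement with the reference assignment by the
    adjusted Rand index and by mean pairwise co-clustering agreement
    among reference non-grey genes.  Genes constant in a resample are
    dropped for that resample (logged by the network layer's error
    handling here as exclusion).
    """
    from . import network

    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = expr.shape[1]
    n_draw = max(3, int(round(fraction * n)))
    ref_nongrey = reference.index[reference != GREY]

    rows = []
    for b in range(n_resamples):
        cols = rng.integers(0, n, size=n_draw)
        sub = expr.iloc[:, cols]
        sub.columns = [f"r{j}" for j in range(n_draw)]
        sd = sub.to_numpy().std(axis=1)
        keep = sub.index[sd > 0]
        sub = sub.loc[keep]
        cor = network.correlation_matrix(sub)
        adj = network.adjacency(cor, beta, network_type)
        dis = network.tom_dissimilarity(network.tom(adj))
        merges = hierarchical_cluster(dis)
        raw = dynamic_tree_cut(
            merges, dis, min_cluster_size=min_cluster_size, deep_split=deep_split
        )
        common = keep.intersection(ref_nongrey)
        ari = adjusted_rand_score(reference.loc[common], raw.loc[common])
        co = _coclustering_agreement(reference.loc[common], raw.loc[common])
        rows.append({"resample": b, "ari": ari, "coclustering": co})
    return pd.DataFrame(rows).set_index("resample")


def _coclustering_agreement(ref: pd.Series, other: pd.Series) -> float:
    """Fraction of same-module reference pairs kept together."""
    a = ref.to_numpy()
    b = other.to_numpy()
    same_ref = a[:, None] == a[None, :]
    same_other = b[:, None] == b[None, :]
    iu = np.triu_indices(len(a), k=1)
    ref_pairs = same_ref[iu]
    if not ref_pairs.any():
        return float("nan")
    return float(same_other[iu][ref_pairs].mean())
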