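"""Permutation-based module preservation between two expression datasets.

Asks whether modules defined in a reference dataset replicate in a test
dataset.  Seven statistics are computed per module on the gene overlap:

density (in the test data, on the reference-defined gene set)
    meanCor.in        mean off-diagonal within-module correlation
    meanAdj.in        mean off-diagonal within-module adjacency
    propVarExplained  variance share of the test-data module eigengene
    meanSignedKME     mean signed kME to the test-data module eigengene

connectivity (agreement of gene roles between reference and test)
    cor.kIM   correlation of intramodular connectivity profiles
    cor.kME   correlation of kME profiles
    cor.cor   correlation of the vectorised within-module correlations

Each observed statistic is standardised against a permutation null of
random same-size gene sets, giving per-statistic Z scores.  Zdensity and
Zconnectivity are the medians within each family, Zsummary their mean;
medianRank is the analogous rank-based composite (large = poorly
preserved).  Zsummary below 2 means no evidence of preservation, 2-10
weak-to-moderate, above 10 strong.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DENSITY_STATS = ("meanCor.in", "meanAdj.in", "propVarExplained", "meanSignedKME")
CONNECTIVITY_STATS = ("cor.kIM", "cor.kME", "cor.cor")
ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS


def classify_preservation(zsummary: float) -> str:
    """Qualitative preservation class from Zsummary (2/10 bands).

    Boundary values 2 and 10 fall in the middle band.
    """
    if zsummary < 2:
        return "none"
    if zsummary <= 10:
        return "weak_to_moderate"
    return "strong"


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)


def _eigengene_scores(z: np.ndarray) -> tuple[np.ndarray, float]:
    """First-PC scores (unit variance, majority-positive kME) and var share."""
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0] / vt[0].std(ddof=1)
    kme = z @ scores / ((z.shape[1] - 1))
    if kme.mean() < 0 or (kme.mean() == 0 and kme[0] < 0):
        scores = -scores
    return scores, float(s[0] ** 2 / (s**2).sum())


def _set_stats(
    idx: np.ndarray,
    ref_cor: np.ndarray,
    test_cor: np.ndarray,
    ref_z: np.ndarray,
    test_z: np.ndarray,
    beta: int,
) -> dict[str, float]:
    """The seven preservation statistics for one gene index set."""
    rc = ref_cor[np.ix_(idx, idx)]
    tc = test_cor[np.ix_(idx, idx)]
    m = idx.size
    iu = np.triu_indices(m, k=1)

    t_adj = np.abs(tc) ** beta
    mean_cor_in = float(tc[iu].mean())
    mean_adj_in = float(t_adj[iu].mean())

    zt = test_z[idx]
    n = zt.shape[1]
    scores, pve = _eigengene_scores(zt)
    kme_test = zt @ scores / (n - 1)
    mean_signed_kme = float(kme_test.mean())

    # connectivity agreement between the two datasets
    r_adj = np.abs(rc) ** beta
    kim_ref = r_adj.sum(axis=1) - 1.0
    kim_test = t_adj.sum(axis=1) - 1.0

    zr = ref_z[idx]
    scores_ref, _ = _eigengene_scores(zr)
    kme_ref = zr @ scores_ref / (zr.shape[1] - 1)

    def _cor(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    return {
        "meanCor.in": mean_cor_in,
        "meanAdj.in": mean_adj_in,
        "propVarExplained": pve,
        "meanSignedKME": mean_signed_kme,
        "cor.kIM": _cor(kim_ref, kim_test),
        "cor.kME": _cor(kme_ref, kme_test),
        "cor.cor": _cor(rc[iu], tc[iu]),
    }


def _prepare(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    assignment: pd.Series,
):
    genes = ref_expr.index.intersection(test_expr.index).intersection(
        assignment.index
    )
    if genes.size < 3:
        raise ValueError("gene overlap between datasets is too small")
    ref = ref_expr.loc[genes].to_numpy(dtype=float)
    test = test_expr.loc[genes].to_numpy(dtype=float)
    for name, mat in (("reference", ref), ("test", test)):
        if (mat.std(axis=1) == 0).any():
            raise ValueError(f"constant gene(s) in the {name} dataset")
    ref_z = _standardize(ref) * np.sqrt(
        ref.shape[1] / (ref.shape[1] - 1)
    )  # unit sample variance (ddof=1)
    test_z = _standardize(test) * np.sqrt(test.shape[1] / (test.shape[1] - 1))
    ref_cor = np.clip(np.corrcoef(ref), -1, 1)
    test_cor = np.clip(np.corrcoef(test), -1, 1)
    return genes, ref_cor, test_cor, ref_z, test_z


def preservation_observed(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    assignment: pd.Series,
    beta: int,
) -> pd.DataFrame:
    """Observed preservation statistics per module (no permutations).

    Modules with fewer than 3 overlapping genes are skipped with a
    warning; grey is excluded.
    """
    genes, ref_cor, test_cor, ref_z, test_z = _prepare(
        ref_expr, test_expr, assignment
    )
    pos = {g: i for i, g in enumerate(genes)}
    rows = {}
    for module in [m for m in assignment.unique() if m != "grey"]:
        members = [pos[g] for g in assignment.index[assignment == module] if g in pos]
        if len(members) < 3:
            logger.warning(
                "module %s has %d overlapping genes (<3); skipped", module, len(members)
            )
            continue
        idx = np.asarray(members)
        rows[module] = _set_stats(idx, ref_cor, test_cor, ref_z, test_z, beta)
    if not rows:
        raise ValueError("no module had enough overlapping genes")
    return pd.DataFrame(rows).T.loc[:, list(ALL_STATS)]


@dataclass
class PreservationResult:
    """Per-module preservation composites and the underlying statistics."""

    observed: pd.DataFrame  # module x statistic
    z_scores: pd.DataFrame  # module x statistic
    summary: pd.DataFrame  # Zdensity/Zconnectivity/Zsummary/medianRanks/class
    n_permutations: int = 0
    notes: list[str] = field(default_factory=list)

    def classes(self) -> pd.Series:
        return self.summary["class"]


def preservation_z(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    assignment: pd.Series,
    beta: int,
    n_perm: int = 200,
    seed: int | None = None,
) -> PreservationResult:
    """Permutation Z scores and composite preservation statistics.

    The null for a module of size s is formed by drawing ``n_perm``
    random s-gene sets from the genes present in the assignment (all
    labels, grey included) and recomputing every statistic.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    genes, ref_cor, test_cor, ref_z, test_z = _prepare(
        ref_expr, test_expr, assignment
    )
    observed = preservation_observed(ref_expr, test_expr, assignment, beta)
    modules = list(observed.index)
    sizes = {
        m: int(
            sum(1 for g in assignment.index[assignment == m] if g in set(genes))
        )
        for m in modules
    }
    rng = np.random.default_rng(seed)
    n_genes = genes.size

    notes: list[str] = []
    z_rows = {}
    # share null draws across modules of equal size
    null_cache: dict[int, pd.DataFrame] = {}
    for m in modules:
        s = sizes[m]
        if s not in null_cache:
            draws = []
            for _ in range(n_perm):
                idx = rng.choice(n_genes, size=s, replace=False)
                draws.append(
                    _set_stats(np.sort(idx), ref_cor, test_cor, ref_z, test_z, beta)
                )
            null_cache[s] = pd.DataFrame(draws)
        null = null_cache[s]
        z = {}
        for stat in ALL_STATS:
            mu = null[stat].mean()
            sd = null[stat].std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                z[stat] = np.inf
                msg = f"zero null sd for {stat} in module {m}; Z set to +inf"
                logger.warning(msg)
                notes.append(msg)
            else:
                z[stat] = (observed.at[m, stat] - mu) / sd
        z_rows[m] = z
    z_df = pd.DataFrame(z_rows).T.loc[:, list(ALL_STATS)]

    def _median_finite(vals: pd.Series) -> float:
        finite = vals[np.isfinite(vals)]
        return float(finite.median()) if len(finite) else float("inf")

    summary = {}
    # ranks: 1 = best (largest observed statistic); medianRank large = poor
    ranks = observed.rank(ascending=False, method="average")
    for m in modules:
        zd = _median_finite(z_df.loc[m, list(DENSITY_STATS)])
        zc = _median_finite(z_df.loc[m, list(CONNECTIVITY_STATS)])
        zs = (zd + zc) / 2.0
        mrd = float(ranks.loc[m, list(DENSITY_STATS)].median())
        mrc = float(ranks.loc[m, list(CONNECTIVITY_STATS)].median())
        summary[m] = {
            "module_size": sizes[m],
            "Zdensity": zd,
            "Zconnectivity": zc,
            "Zsummary": zs,
            "medianRank.density": mrd,
            "medianRank.connectivity": mrc,
            "medianRank": (mrd + mrc) / 2.0,
            "class": classify_preservation(zs),
        }
    summary_df = pd.DataFrame(summary).T
    return PreservationResult(
        observed=observed,
        z_scores=z_df,
        summary=summary_df,
        n_permutations=n_perm,
        notes=notes,
    )
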