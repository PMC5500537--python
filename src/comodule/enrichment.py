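"""Gene-set over-representation with Fisher/EASE p and a combined score.

The one-sided Fisher exact p of the 2x2 overlap table is the
hypergeometric upper tail.  ``mode="ease"`` is the conservative DAVID
variant that removes one gene from the overlap before computing the
tail (so singleton overlaps are never significant).  The combined score
follows the Enrichr construction: a z score capturing the deviation of
a set's rank from its expected rank under size-matched random queries,
multiplied by ln(p), so that strongly enriched sets attain large
positive C = ln(p) * z.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

MODES = ("fisher", "ease")


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT gene-set library: name, description, genes...

    Gene symbols are upper-cased and de-duplicated; blank gene fields
    are dropped; a line with no genes is an error naming the line.
    """
    library: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: gene set {fields[0]!r} has no genes")
        name = fields[0]
        genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        library[name] = genes
    if not library:
        raise ValueError(f"{path}: no gene sets found")
    return library


def fisher_p(overlap: int, query_size: int, set_size: int, background_size: int) -> float:
    """One-sided Fisher exact p = P(X >= overlap), X ~ Hypergeom."""
    return float(
        stats.hypergeom.sf(overlap - 1, background_size, set_size, query_size)
    )


def fisher_enrichment(
    query,
    background,
    library: dict[str, frozenset[str]],
    mode: str = "ease",
) -> pd.DataFrame:
    """Over-representation of ``query`` in each library set.

    Sets are restricted to the background before testing.  ``mode="ease"``
    subtracts one from the overlap (floored at 0) before the tail
    computation.  BH adjustment runs across the library.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    query = {str(g).upper() for g in query}
    background = {str(g).upper() for g in background}
    if not query <= background:
        raise ValueError("query must be a subset of background")
    if len(background) < len(query):
        raise ValueError("background smaller than query")
    n_bg = len(background)
    n_query = len(query)

    rows = []
    for name, genes in library.items():
        in_bg = genes & background
        if not in_bg:
            continue
        overlap = len(query & in_bg)
        k = overlap if mode == "fisher" else max(overlap - 1, 0)
        p = fisher_p(k, n_query, len(in_bg), n_bg)
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "query_size": n_query,
                "set_size": len(in_bg),
                "background_size": n_bg,
                "p_value": p,
            }
        )
    if not rows:
        raise ValueError("no library set intersects the background")
    table = pd.DataFrame(rows).set_index("set")
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return table.sort_values("p_value")


def _ranks(p: pd.Series) -> pd.Series:
    """Rank sets by ascending p (1 = most enriched), mean rank on ties."""
    return p.rank(method="average", ascending=True)


def combined_score(
    query,
    background,
    library: dict[str, frozenset[str]],
    mode: str = "ease",
    n_null: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Enrichment table with rank-deviation z and combined score C.

    For ``n_null`` random queries of the same size, each set's rank
    under the Fisher test is recorded; z = (observed_rank -
    expected_rank) / sd_rank is negative for sets ranking better than
    chance, and C = ln(p) * z is large and positive for enriched sets
    (p = 1 forces C = 0).
    """
    if n_null < 10:
        raise ValueError("n_null must be >= 10")
    table = fisher_enrichment(query, background, library, mode=mode)
    observed_rank = _ranks(table["p_value"])

    bg_list = sorted({str(g).upper() for g in background})
    rng = np.random.default_rng(seed)
    q_size = len({str(g).upper() for g in query})
    null_ranks = np.empty((n_null, len(table)))
    for b in range(n_null):
        null_q = rng.choice(bg_list, size=q_size, replace=False)
        null_table = fisher_enrichment(null_q, bg_list, library, mode=mode)
        null_ranks[b] = _ranks(null_table["p_value"]).reindex(table.index).to_numpy()

    expected = null_ranks.mean(axis=0)
    sd = null_ranks.std(axis=0, ddof=1)
    z = np.zeros(len(table))
    ok = sd > 0
    z[ok] = (observed_rank.to_numpy()[ok] - expected[ok]) / sd[ok]
    if (~ok).any():
        logger.warning(
            "zero rank sd for %d set(s); their z set to 0", int((~ok).sum())
        )
    table = table.copy()
    table["z"] = z
    table["expected_rank"] = expected
    table["observed_rank"] = observed_rank
    with np.errstate(divide="ignore"):
        table["combined_score"] = np.log(table["p_value"].to_numpy()) * z
    table.loc[table["p_value"] == 1.0, "combined_score"] = 0.0
    return table.sort_values("combined_score", ascending=False)
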