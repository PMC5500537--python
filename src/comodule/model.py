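"""Model-style front ends for the co-expression analysis.

:class:`WGCNA` holds an expression matrix (and optionally a binary
trait); ``fit()`` runs soft-threshold selection, network construction,
module detection and trait association, returning a
:class:`WGCNAResults` that carries the estimates and exposes summary,
hub-gene, meta-module, export and plotting helpers.

:class:`ModulePreservation` compares a reference module assignment
against a test dataset; ``fit()`` returns a
:class:`PreservationResults` wrapping the permutation composites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, modules, network, preservation, trait
from .palette import GREY


def _plot_color(module: str) -> str:
    """Module name as a matplotlib colour, grey fallback for exotic names."""
    from matplotlib.colors import is_color_like

    if module == GREY:
        return "lightgrey"
    return module if is_color_like(module) else "tab:blue"


class WGCNA:
    """Weighted gene co-expression network model of one dataset.

    Parameters
    ----------
    expr : DataFrame
        Gene x sample log2 expression (already collapsed and filtered).
    trait : Series, optional
        0/1 severity code per sample; trait statistics are skipped when
        absent.
    network_type : {"unsigned", "signed"}
    powers, fit_cut, n_bins : soft-threshold search grid and criterion.
    min_cluster_size, deep_split, pam_stage : tree-cut parameters.
    kme_threshold : |kME| below which a gene returns to grey.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        trait_vector: pd.Series | None = None,
        *,
        network_type: str = "unsigned",
        powers=tuple(range(1, 21)),
        fit_cut: float = 0.9,
        n_bins: int = 10,
        min_cluster_size: int = 30,
        deep_split: int = 2,
        pam_stage: bool = False,
        kme_threshold: float = 0.7,
    ) -> None:
        if trait_vector is not None:
            missing = set(trait_vector.index) - set(expr.columns)
            if missing:
                raise ValueError(f"trait samples not in expression: {sorted(missing)[:5]}")
            trait_vector = trait_vector.loc[expr.columns]
        self.expr = expr
        self.trait = trait_vector
        self.network_type = network_type
        self.powers = tuple(powers)
        self.fit_cut = fit_cut
        self.n_bins = n_bins
        self.min_cluster_size = min_cluster_size
        self.deep_split = deep_split
        self.pam_stage = pam_stage
        self.kme_threshold = kme_threshold

    @classmethod
    def from_files(
        cls,
        expr_path: str | Path,
        trait_path: str | Path | None = None,
        dialect: str = "tsv",
        **kwargs,
    ) -> "WGCNA":
        from . import preprocess

        expr = preprocess.read_expression(expr_path, dialect=dialect)
        tr = preprocess.read_trait(trait_path) if trait_path else None
        return cls(expr, tr, **kwargs)

    def fit(self, beta: int | None = None) -> "WGCNAResults":
        """Run the full network -> modules -> trait analysis."""
        cor = network.correlation_matrix(self.expr)
        if beta is None:
            st = network.pick_soft_threshold(
                self.expr,
                powers=self.powers,
                fit_cut=self.fit_cut,
                n_bins=self.n_bins,
                network_type=self.network_type,
                cor=cor,
            )
            beta = st.beta
            sft_table, reached = st.table, st.reached_cut
        else:
            sft_table, reached = None, True
        adj = network.adjacency(cor, beta, self.network_type)
        tom_m = network.tom(adj)
        dis = network.tom_dissimilarity(tom_m)
        merges = modules.hierarchical_cluster(dis)
        raw = modules.dynamic_tree_cut(
            merges,
            dis,
            min_cluster_size=self.min_cluster_size,
            deep_split=self.deep_split,
            pam_stage=self.pam_stage,
        )
        initial = modules.label_modules(raw)
        if (initial != GREY).any():
            egs = modules.module_eigengene(self.expr, initial)
            km = modules.kme(self.expr, egs)
            final = modules.reassign_grey(initial, km, threshold=self.kme_threshold)
        else:
            egs, km, final = None, None, initial

        module_trait = gene_stats = module_sig = None
        if self.trait is not None and egs is not None:
            module_trait = trait.module_trait_correlation(egs.values, self.trait)
            gene_stats = trait.gene_network_stats(
                self.expr, self.trait, adj, final, km
            )
            module_sig = trait.module_significance(gene_stats["GS"], final)

        return WGCNAResults(
            model=self,
            beta=int(beta),
            scale_free_table=sft_table,
            reached_fit_cut=reached,
            correlation=cor,
            adjacency=adj,
            tom=tom_m,
            dendrogram=merges,
            modules_initial=initial,
            modules=final,
            eigengenes=egs,
            kme=km,
            module_trait=module_trait,
            gene_stats=gene_stats,
            module_significance=module_sig,
        )


@dataclass
class WGCNAResults:
    """Fitted co-expression network, modules and trait statistics."""

    model: WGCNA
    beta: int
    scale_free_table: pd.DataFrame | None
    reached_fit_cut: bool
    correlation: pd.DataFrame
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    dendrogram: np.ndarray
    modules_initial: pd.Series  # after tree cut + size-ordered labelling
    modules: pd.Series  # after the |kME| grey rule
    eigengenes: modules.Eigengenes | None
    kme: pd.DataFrame | None
    module_trait: pd.DataFrame | None
    gene_stats: pd.DataFrame | None
    module_significance: pd.Series | None

    @property
    def module_sizes(self) -> pd.Series:
        return self.modules.value_counts()

    @property
    def module_labels(self) -> list[str]:
        return [m for m in self.module_sizes.index if m != GREY]

    def n_modules(self, include_grey: bool = False) -> int:
        n = len(self.module_labels)
        return n + 1 if include_grey and (self.modules == GREY).any() else n

    def hub_genes(self, module: str, top_n: int = 10) -> pd.DataFrame:
        if self.gene_stats is None:
            raise ValueError("no trait was supplied; hub ranking unavailable")
        return trait.hub_genes(self.gene_stats, module, top_n=top_n)

    def meta_modules(self, cor_cut: float = 0.5):
        if self.eigengenes is None:
            raise ValueError("no modules were detected")
        return trait.meta_modules(
            self.eigengenes.values, self.model.trait, cor_cut=cor_cut
        )

    def export_edge_list(self, module: str, tom_cut: float = 0.1, node_attributes=None):
        return trait.export_edge_list(
            self.tom, self.modules, module, tom_cut=tom_cut,
            node_attributes=node_attributes,
        )

    def differential_expression(self, method: str = "moderated_t", alpha: float = 0.05):
        if self.model.trait is None:
            raise ValueError("no trait was supplied")
        return diffexpr.two_group_test(
            self.model.expr, self.model.trait, method=method, alpha=alpha
        )

    def summary(self) -> str:
        """Plain-text overview of the fitted network."""
        lines = [
            "Weighted co-expression network fit",
            "==================================",
            f"genes: {self.model.expr.shape[0]}   samples: {self.model.expr.shape[1]}",
            f"network type: {self.model.network_type}   soft threshold beta: {self.beta}"
            + ("" if self.reached_fit_cut else "   (scale-free cut not reached)"),
            f"modules (excl. grey): {self.n_modules()}   "
            f"grey genes: {int((self.modules == GREY).sum())}",
            "",
            "module sizes:",
        ]
        for m, s in self.module_sizes.items():
            lines.append(f"  {m:<14s} {int(s):>6d}")
        if self.module_trait is not None:
            lines += ["", "module-trait correlations:"]
            mt = self.module_trait.sort_values("p_value")
            for m, row in mt.iterrows():
                star = " *" if row["p_value"] < 0.05 else ""
                lines.append(
                    f"  {m:<14s} r = {row['correlation']:+.3f}   "
                    f"p = {row['p_value']:.2e}{star}"
                )
            lines.append("  (* p < 0.05)")
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------
    def plot_scale_free_fit(self, ax=None):
        """Fit index and mean connectivity vs candidate powers."""
        import matplotlib.pyplot as plt

        if self.scale_free_table is None:
            raise ValueError("beta was fixed by hand; no search table to plot")
        if ax is None:
            _, ax = plt.subplots()
        t = self.scale_free_table
        ax.plot(t.index, t["r_squared_signed"], "o-", label="signed $R^2$")
        ax.axhline(self.model.fit_cut, ls="--", c="grey")
        ax.axvline(self.beta, ls=":", c="red", label=f"beta = {self.beta}")
        ax.set_xlabel("soft-threshold power")
        ax.set_ylabel("scale-free fit index")
        ax.legend()
        return ax

    def plot_dendrogram(self, ax=None):
        """Gene dendrogram with the module colour bar."""
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        dd = scipy_dendrogram(self.dendrogram, no_labels=True, ax=ax,
                              color_threshold=0, above_threshold_color="black")
        order = dd["leaves"]
        colors = self.modules_initial.iloc[order]
        for i, c in enumerate(colors):
            ax.bar(5 + i * 10, height=0.02 * self.dendrogram[:, 2].max(),
                   width=10, bottom=-0.03, color=_plot_color(c),
                   align="center")
        ax.set_ylabel("1 - TOM merge height")
        return ax

    def plot_gs_vs_mm(self, module: str, ax=None):
        """Scatter of gene significance vs module membership for one module."""
        import matplotlib.pyplot as plt

        if self.gene_stats is None:
            raise ValueError("no trait was supplied")
        if ax is None:
            _, ax = plt.subplots()
        sub = self.gene_stats[self.gene_stats["module"] == module]
        ax.scatter(sub["MM"], sub["GS"], s=8, alpha=0.6,
                   c=_plot_color(module))
        r = trait.gs_mm_kin_correlations(self.gene_stats, module)
        ax.set_title(f"{module}: r = {r['r_GS_MM']:.2f}, p = {r['p_GS_MM']:.1e}")
        ax.set_xlabel("module membership (kME)")
        ax.set_ylabel("gene significance")
        return ax


class ModulePreservation:
    """Preservation of reference modules in an independent test dataset."""

    def __init__(
        self,
        ref_expr: pd.DataFrame,
        test_expr: pd.DataFrame,
        assignment: pd.Series,
        beta: int,
    ) -> None:
        self.ref_expr = ref_expr
        self.test_expr = test_expr
        self.assignment = assignment
        self.beta = beta

    def fit(self, n_perm: int = 200, seed: int | None = None) -> "PreservationResults":
        result = preservation.preservation_z(
            self.ref_expr,
            self.test_expr,
            self.assignment,
            self.beta,
            n_perm=n_perm,
            seed=seed,
        )
        return PreservationResults(model=self, result=result)


@dataclass
class PreservationResults:
    model: ModulePreservation
    result: preservation.PreservationResult

    @property
    def summary_table(self) -> pd.DataFrame:
        return self.result.summary

    def classes(self) -> pd.Series:
        return self.result.classes()

    def summary(self) -> str:
        lines = [
            "Module preservation",
            "===================",
            f"permutations: {self.result.n_permutations}",
            f"{'module':<14s} {'size':>5s} {'Zsummary':>9s} {'medianRank':>11s}  class",
        ]
        t = self.result.summary.sort_values("Zsummary", ascending=False)
        for m, row in t.iterrows():
            lines.append(
                f"{m:<14s} {int(row['module_size']):>5d} "
                f"{float(row['Zsummary']):>9.2f} {float(row['medianRank']):>11.1f}  "
                f"{row['class']}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Zsummary vs module size with the 2/10 evidence bands."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.result.summary
        for m, row in t.iterrows():
            ax.scatter(row["module_size"], row["Zsummary"],
                       c=_plot_color(m), edgecolors="black")
            ax.annotate(m, (row["module_size"], row["Zsummary"]),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
        ax.axhline(2, ls="--", c="blue")
        ax.axhline(10, ls="--", c="green")
        ax.set_xscale("log")
        ax.set_xlabel("module size")
        ax.set_ylabel("Zsummary")
        return ax
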