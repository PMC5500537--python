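"""End-to-end pipeline behind one YAML config, with a run manifest.

Stage order: preprocess -> differential expression -> network ->
modules -> trait association -> (optional) preservation against test
datasets -> (optional) enrichment against GMT libraries.  Every stage
writes TSV outputs into the run directory; a JSON manifest records the
parameters, the seed and a checksum per output file, so reruns with the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, diffexpr, enrichment, preprocess
from .model import ModulePreservation, WGCNA
from .palette import GREY

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Defaults follow the analysis the pipeline reproduces: |kME| cut 0.7,
    Cytoscape TOM cut 0.1, 200 preservation permutations, DEG alpha
    0.05 and scale-free fit index above 0.9.
    """

    expr: str = ""
    trait: str = ""
    probe_map: str | None = None
    gmt: str | None = None
    test_datasets: dict = field(default_factory=dict)  # name -> expr path
    dialect: str = "tsv"
    powers: tuple = tuple(range(1, 21))
    fit_cut: float = 0.9
    min_cluster_size: int = 30
    deep_split: int = 2
    kme_threshold: float = 0.7
    tom_cut: float = 0.1
    n_perm: int = 200
    alpha: float = 0.05
    seed: int = 0
    network_type: str = "unsigned"
    deg_method: str = "moderated_t"
    enrichment_mode: str = "ease"
    filter_genes: bool = True
    drop_outliers: bool = True
    outlier_cut_z: float = 2.5


def validate_config(raw: dict | RunConfig) -> RunConfig:
    """Normalise and validate a raw config mapping."""
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = RunConfig(**raw)
    if not cfg.expr:
        raise ValueError("config must name an expression matrix (expr)")
    if not 0 < cfg.kme_threshold < 1:
        raise ValueError("kme_threshold must be in (0,1)")
    if not 0 < cfg.alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if cfg.n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    if cfg.tom_cut < 0:
        raise ValueError("tom_cut must be non-negative")
    if cfg.deg_method not in diffexpr.METHODS:
        raise ValueError(f"deg_method must be one of {diffexpr.METHODS}")
    if cfg.enrichment_mode not in enrichment.MODES:
        raise ValueError(f"enrichment_mode must be one of {enrichment.MODES}")
    cfg.powers = tuple(int(p) for p in cfg.powers)
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig | dict, out_dir: str | Path) -> Path:
    """Execute every stage; write outputs, report and manifest.

    Any stage failure aborts with the stage name recorded in the
    manifest.  Returns the run directory.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stages": [],
        "outputs": {},
    }
    report: list[str] = []
    stage = "preprocess"
    try:
        expr = preprocess.read_expression(cfg.expr, dialect=cfg.dialect)
        trait_vec = preprocess.read_trait(cfg.trait) if cfg.trait else None
        if cfg.probe_map:
            expr = preprocess.collapse_probes(
                expr, preprocess.read_probe_map(cfg.probe_map)
            )
        if cfg.drop_outliers and expr.shape[1] >= 3:
            outliers = preprocess.detect_outlier_samples(expr, cut_z=cfg.outlier_cut_z)
            if outliers:
                report.append(f"outlier samples removed: {outliers}")
                expr = expr.drop(columns=outliers)
                if trait_vec is not None:
                    trait_vec = trait_vec.drop(index=outliers, errors="ignore")
        if cfg.filter_genes:
            expr = preprocess.filter_genes(expr)
        if trait_vec is not None:
            trait_vec = trait_vec.loc[[s for s in expr.columns if s in trait_vec.index]]
            expr = expr.loc[:, trait_vec.index]
        expr.to_csv(out / "expression_filtered.tsv", sep="\t")
        manifest["stages"].append(stage)
        report.append(
            f"filtered matrix: {expr.shape[0]} genes x {expr.shape[1]} samples"
        )

        stage = "diffexpr"
        deg_table = None
        if trait_vec is not None:
            deg_table = diffexpr.two_group_test(
                expr, trait_vec, method=cfg.deg_method, alpha=cfg.alpha
            )
            deg_table.to_csv(out / "differential_expression.tsv", sep="\t")
            report.append(f"DEGs (q < {cfg.alpha}): {int(deg_table['is_deg'].sum())}")
        manifest["stages"].append(stage)

        stage = "network+modules"
        model = WGCNA(
            expr,
            trait_vec,
            network_type=cfg.network_type,
            powers=cfg.powers,
            fit_cut=cfg.fit_cut,
            min_cluster_size=cfg.min_cluster_size,
            deep_split=cfg.deep_split,
            kme_threshold=cfg.kme_threshold,
        )
        res = model.fit()
        if res.scale_free_table is not None:
            res.scale_free_table.to_csv(out / "soft_threshold.tsv", sep="\t")
        assign = res.modules.rename("module").to_frame()
        if res.kme is not None:
            own = [
                res.kme.at[g, m] if m != GREY and m in res.kme.columns else float("nan")
                for g, m in res.modules.items()
            ]
            assign["own_module_kME"] = own
        assign.to_csv(out / "module_assignment.tsv", sep="\t")
        if res.eigengenes is not None:
            res.eigengenes.values.to_csv(out / "module_eigengenes.tsv", sep="\t")
        manifest["stages"].append(stage)
        report.append(f"selected beta: {res.beta}")
        sizes = ", ".join(
            f"{m}={int(s)}" for m, s in res.module_sizes.items()
        )
        report.append(
            f"modules (excl. grey): {res.n_modules()}; sizes: {sizes}"
        )

        stage = "trait_association"
        if res.module_trait is not None:
            res.module_trait.to_csv(out / "module_trait.tsv", sep="\t")
            res.gene_stats.to_csv(out / "gene_network_stats.tsv", sep="\t")
            sig = res.module_trait[res.module_trait["p_value"] < 0.05]
            report.append(
                "trait-associated modules (p < 0.05): "
                + (", ".join(sig.index) if len(sig) else "none")
            )
            if res.n_modules() >= 2:
                grouping, _, me_cor = res.meta_modules()
                grouping.to_frame().to_csv(out / "meta_modules.tsv", sep="\t")
                me_cor.to_csv(out / "eigengene_correlation.tsv", sep="\t")
            if deg_table is not None:
                deg_genes = deg_table.index[deg_table["is_deg"]]
                enr = diffexpr.module_deg_enrichment(
                    res.modules, deg_genes, expr.index
                )
                enr.to_csv(out / "module_deg_enrichment.tsv", sep="\t")
            for m in res.module_labels:
                edges, _ = res.export_edge_list(m, tom_cut=cfg.tom_cut)
                edges.to_csv(out / f"edges_{m}.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "preservation"
        for name, test_path in (cfg.test_datasets or {}).items():
            test_expr = preprocess.read_expression(test_path, dialect=cfg.dialect)
            pres = ModulePreservation(
                expr, test_expr, res.modules, res.beta
            ).fit(n_perm=cfg.n_perm, seed=cfg.seed)
            pres.summary_table.to_csv(out / f"preservation_{name}.tsv", sep="\t")
            report.append(
                f"preservation vs {name}: "
                + ", ".join(
                    f"{m}:{c}" for m, c in pres.classes().items()
                )
            )
        manifest["stages"].append(stage)

        stage = "enrichment"
        if cfg.gmt:
            library = enrichment.read_gmt(cfg.gmt)
            for m in res.module_labels:
                genes = res.modules.index[res.modules == m]
                table = enrichment.combined_score(
                    genes, expr.index, library,
                    mode=cfg.enrichment_mode, seed=cfg.seed,
                )
                table.to_csv(out / f"enrichment_{m}.tsv", sep="\t")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (out / "report.txt").write_text("\n".join(report) + "\n")
    for f in sorted(out.glob("*.tsv")) + [out / "report.txt"]:
        manifest["outputs"][f.name] = _checksum(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
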